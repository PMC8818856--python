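"""Model topology and planar multibody dynamics."""

import numpy as np
import pytest
import yaml

from kafogait.skeleton import (
    GRAVITY,
    N_Q_PLANAR,
    PLANAR_DOF_ORDER,
    SEGMENT_ORDER,
    PlanarModel,
    SegmentParams,
    TopologyError,
    build_planar_model,
    default_topology_path,
    forward_kinematics,
    inverse_dynamics,
    load_topology,
)


# ---------------------------------------------------------------------------
# Declarative full-body schema
# ---------------------------------------------------------------------------

class TestTopology:
    def test_shipped_schema_has_31_dofs_with_pelvis_first(self):
        topo = load_topology(default_topology_path())
        assert topo.n_q == 31
        first_six = topo.unlocked_dofs()[:6]
        assert all(d.startswith("pelvis") for d in first_six)

    def test_orthosis_locks_distal_foot_joints(self):
        topo = load_topology(default_topology_path())
        for side in ("r", "l"):
            for j in ("ankle_angle", "subtalar_angle", "mtp_angle"):
                assert f"{j}_{side}" in topo.locked_dofs

    def test_index_map_is_a_bijection(self):
        topo = load_topology(default_topology_path())
        idx = sorted(topo.coordinate_index_map.values())
        assert idx == list(range(1, topo.n_q + 1))

    def test_removing_a_joint_reduces_the_count(self, tmp_path):
        with open(default_topology_path()) as fh:
            raw = yaml.safe_load(fh)
        removed = [j for j in raw["joints"] if j["name"] == "wrist_r"]
        raw["joints"] = [j for j in raw["joints"] if j["name"] != "wrist_r"]
        p = tmp_path / "reduced.yaml"
        p.write_text(yaml.safe_dump(raw))
        topo = load_topology(p)
        assert topo.n_q == 31 - len(removed[0]["dofs"])

    def test_duplicate_dof_rejected(self, tmp_path):
        with open(default_topology_path()) as fh:
            raw = yaml.safe_load(fh)
        raw["joints"][1]["dofs"][0] = "pelvis_tx"
        p = tmp_path / "dup.yaml"
        p.write_text(yaml.safe_dump(raw))
        with pytest.raises(TopologyError, match="duplicate"):
            load_topology(p)

    def test_malformed_joint_names_offender(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("name: x\njoints:\n  - {name: hip_r, parent: pelvis}\n")
        with pytest.raises(TopologyError, match="hip_r"):
            load_topology(p)


# ---------------------------------------------------------------------------
# Subject scaling
# ---------------------------------------------------------------------------

class TestBuildPlanarModel:
    @pytest.mark.parametrize("mass,height", [(54.0, 1.62), (72.0, 1.72)])
    def test_total_mass_is_subject_plus_devices(self, mass, height):
        m = build_planar_model({"mass": mass, "height": height})
        devices = 2 * (1.5 + 1.3 + 0.8)
        assert m.total_mass == pytest.approx(mass + devices)

    def test_zero_device_mass_recovers_subject_mass(self):
        m = build_planar_model(
            {"mass": 60.0, "height": 1.70},
            device_props={k: {"mass": 1e-9, "inertia": 0.0}
                          for k in ("orthosis_thigh", "orthosis_shank", "crutch")})
        assert m.total_mass == pytest.approx(60.0, abs=1e-6)

    def test_lengths_scale_with_height(self):
        m = build_planar_model({"mass": 70.0, "height": 1.80})
        assert m.segments["thigh_r"].length == pytest.approx(0.245 * 1.80)
        assert m.segments["upperarm_l"].length == pytest.approx(0.186 * 1.80)

    def test_invalid_anthropometry_rejected(self):
        with pytest.raises(ValueError):
            build_planar_model({"mass": -3.0, "height": 1.7})

    def test_planar_dof_count_and_order(self, sci_model):
        assert sci_model.n_q == N_Q_PLANAR == 12
        assert sci_model.dof_order == PLANAR_DOF_ORDER
        assert sci_model.dof_order[:3] == ("pelvis_tx", "pelvis_ty", "pelvis_rot")

    def test_segment_invariants_enforced(self):
        with pytest.raises(ValueError):
            SegmentParams("x", mass=-1.0, length=0.4, com_offset=0.2,
                          inertia_about_com=0.1)
        with pytest.raises(ValueError):
            SegmentParams("x", mass=1.0, length=0.4, com_offset=0.5,
                          inertia_about_com=0.1)

    def test_yaml_round_trip(self, sci_model, tmp_path):
        p = tmp_path / "model.yaml"
        sci_model.to_yaml(p)
        again = PlanarModel.from_yaml(p)
        assert again.total_mass == pytest.approx(sci_model.total_mass)
        tbl = again.segment_table()
        assert list(tbl.columns) == ["segment", "mass_kg", "length_m",
                                     "com_offset_m", "inertia_kgm2"]
        assert set(tbl["segment"]) == set(SEGMENT_ORDER)


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

class TestForwardKinematics:
    def test_reference_pose_toe_position(self, sci_model):
        m = sci_model
        fk = forward_kinematics(m, np.zeros(12), np.zeros(12))
        H = m.anthropometry["height"]
        toe = fk["toe_r"]["position"]
        assert toe[0] == pytest.approx(0.75 * 0.152 * H)
        assert toe[1] == pytest.approx(-(0.245 + 0.246 + 0.039) * H)

    def test_rigid_translation_moves_all_points(self, sci_model, rng):
        q = rng.normal(0.0, 0.3, 12)
        q2 = q.copy()
        q2[0] += 0.7
        q2[1] -= 0.2
        fk1 = forward_kinematics(sci_model, q, np.zeros(12))
        fk2 = forward_kinematics(sci_model, q2, np.zeros(12))
        for name in fk1:
            np.testing.assert_allclose(
                fk2[name]["position"] - fk1[name]["position"], [0.7, -0.2],
                atol=1e-12)

    def test_velocity_matches_finite_difference(self, sci_model, rng):
        q = rng.normal(0.0, 0.4, 12)
        qd = rng.normal(0.0, 0.8, 12)
        dt = 1e-6
        pk = sci_model.point_kinematics(q, qd)
        pk1 = sci_model.point_kinematics(q - 0.5 * dt * qd)
        pk2 = sci_model.point_kinematics(q + 0.5 * dt * qd)
        fd = (pk2["pos"] - pk1["pos"]) / dt
        scale = max(1.0, np.abs(pk["vel"]).max())
        assert np.abs(fd - pk["vel"]).max() / scale < 1e-6

    def test_dimension_errors(self, sci_model):
        with pytest.raises(ValueError, match="shape"):
            forward_kinematics(sci_model, np.zeros(11), np.zeros(12))


# ---------------------------------------------------------------------------
# Inverse dynamics
# ---------------------------------------------------------------------------

class TestInverseDynamics:
    def test_zero_state_no_loads_gives_zero(self, sci_model):
        z = np.zeros(12)
        g = sci_model.generalized_forces(z, z, z, gravity=False)
        np.testing.assert_allclose(g, 0.0, atol=1e-14)

    def test_single_hinge_matches_compound_pendulum(self, sci_model):
        """One unlocked hip with thigh+shank rigid: tau = M_g sin(phi) + I qdd."""
        m = sci_model
        th = m.segments["thigh_r"]
        sh = m.segments["shank_r"]
        first_moment = th.total_mass * th.com_offset \
            + sh.total_mass * (th.length + sh.com_offset)
        inertia_hip = th.total_inertia + th.total_mass * th.com_offset ** 2 \
            + sh.total_inertia + sh.total_mass * (th.length + sh.com_offset) ** 2
        phi, phidd = 0.37, 1.9
        q = np.zeros(12)
        qd = np.zeros(12)
        qdd = np.zeros(12)
        q[4] = phi
        qdd[4] = phidd
        out = inverse_dynamics(m, q, qd, qdd)
        tau_hip = out["joint_generalized_forces"][1]  # hip_r
        expected = GRAVITY * first_moment * np.sin(phi) + inertia_hip * phidd
        assert tau_hip == pytest.approx(expected, rel=1e-12)

    def test_static_standing_with_reactions_under_com(self, sci_model):
        """Reactions opposing total weight under the CoM zero the residuals."""
        m = sci_model
        q = np.zeros(12)
        q[1] = m.segments["thigh_r"].length + m.segments["shank_r"].length
        pk = m.point_kinematics(q, np.zeros(12))
        com_idx = [m._pt_index[f"com_{s}"] for s in SEGMENT_ORDER]
        com_x = float((m._mass * pk["pos"][com_idx, 0]).sum() / m.total_mass)
        # split the weight between heel and toe stations to place the
        # resultant exactly under the CoM (per foot)
        W = m.total_mass * m.gravity
        xh = pk["pos"][m._pt_index["heel_r"], 0]
        xt = pk["pos"][m.toe_points["r"], 0]
        a = (xt - com_x) / (xt - xh)   # heel share
        loads = {}
        for side in ("r", "l"):
            loads[f"heel_{side}"] = np.array([0.0, 0.5 * W * a])
            loads[f"toe_{side}"] = np.array([0.0, 0.5 * W * (1 - a)])
        out = inverse_dynamics(m, q, np.zeros(12), np.zeros(12), loads)
        np.testing.assert_allclose(out["residual_loads"], 0.0, atol=1e-6)

    def test_unknown_load_point_named(self, sci_model):
        with pytest.raises(ValueError, match="nonexistent_point"):
            inverse_dynamics(sci_model, np.zeros(12), np.zeros(12),
                             np.zeros(12), {"nonexistent_point": np.zeros(2)})

    def test_output_affine_in_acceleration(self, sci_model, rng):
        q = rng.normal(0.0, 0.3, 12)
        qd = rng.normal(0.0, 0.5, 12)
        a1 = rng.normal(0.0, 1.0, 12)
        a2 = rng.normal(0.0, 1.0, 12)
        g = sci_model.generalized_forces
        # affine: g(q,qd,a) = M a + c; an affine combination (weights sum
        # to one) commutes with g
        lhs = g(q, qd, 0.3 * a1 + 0.7 * a2)
        rhs = 0.3 * g(q, qd, a1) + 0.7 * g(q, qd, a2)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_mass_matrix_symmetric_positive_definite(self, sci_model, rng):
        for _ in range(100):
            q = rng.normal(0.0, 0.6, 12)
            M = sci_model.mass_matrix(q)
            np.testing.assert_allclose(M, M.T, atol=1e-9 * np.abs(M).max())
            assert np.linalg.eigvalsh(M).min() > 0.0

    def test_power_balance_along_trajectory(self, sci_model, rng):
        """d(KE)/dt equals generalized-force power plus gravity and load power."""
        m = sci_model
        q0 = rng.normal(0.0, 0.3, 12)
        A = rng.normal(0.0, 0.4, 12)
        w = rng.uniform(1.0, 3.0, 12)

        def state(t):
            q = q0 + A * np.sin(w * t)
            qd = A * w * np.cos(w * t)
            qdd = -A * w ** 2 * np.sin(w * t)
            return q, qd, qdd

        t0, dt = 0.4, 1e-5
        q, qd, qdd = state(t0)
        load = {"toe_r": np.array([13.0, -41.0])}
        g = m.generalized_forces(q, qd, qdd, ext_forces=load)
        # gravity power and external-load power
        pk = m.point_kinematics(q, qd)
        com_idx = [m._pt_index[f"com_{s}"] for s in SEGMENT_ORDER]
        p_grav = float((-m._mass * m.gravity * pk["vel"][com_idx, 1]).sum())
        p_ext = float(load["toe_r"] @ pk["vel"][m.toe_points["r"]])
        qa, qda, _ = state(t0 - dt)
        qb, qdb, _ = state(t0 + dt)
        dke = (m.kinetic_energy(qb, qdb) - m.kinetic_energy(qa, qda)) / (2 * dt)
        total = float(qd @ g) + p_grav + p_ext
        assert dke == pytest.approx(total, rel=1e-5)
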