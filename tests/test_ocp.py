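"""Transcription structure, validation and derivative correctness."""

import numpy as np
import pytest

from kafogait.costs import CostWeights, ReferenceData
from kafogait.knee_trajectory import KneeTrajectoryParams, eval_knee_trajectory
from kafogait.ocp import (DEFAULT_PHASE_FRACTIONS, GaitFreeParams, OCPConfig,
                          PHASES, _consistent_controls, _Mesh, transcribe)
from kafogait.synthetic_reference import draft_reference


class TestConfigValidation:
    def test_zero_mesh_intervals_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            OCPConfig(n_mesh_swing=0)

    def test_zero_hip_capacity_rejected(self):
        """A vanishing hip-capacity fraction cannot be silently accepted."""
        with pytest.raises(ValueError, match="hip_capacity"):
            OCPConfig(hip_capacity_fraction=0.0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            OCPConfig(scheme="hermite-simpson-adaptive")

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError, match="profile"):
            OCPConfig(profile="canine")


class TestFreeParams:
    def test_fraction_sum_validated_and_normalized(self):
        fr = dict(DEFAULT_PHASE_FRACTIONS)
        gp = GaitFreeParams(4.4, 0.51, fr)
        assert sum(gp.phase_fractions.values()) == pytest.approx(1.0, abs=1e-12)
        fr_bad = {p: v * 1.2 for p, v in fr.items()}
        with pytest.raises(ValueError, match="sum"):
            GaitFreeParams(4.4, 0.51, fr_bad)

    def test_missing_phase_rejected(self):
        fr = dict(DEFAULT_PHASE_FRACTIONS)
        fr.pop("swing_leg_r")
        with pytest.raises(ValueError, match="swing_leg_r"):
            GaitFreeParams(4.4, 0.51, fr)


class TestMesh:
    def test_phase_slices_cover_all_intervals(self):
        mesh = _Mesh(OCPConfig(n_mesh_swing=3, n_mesh_support=2))
        assert mesh.n_intervals == 4 * 3 + 4 * 2
        ends = [mesh.phase_slices[p][1] for p in PHASES]
        starts = [mesh.phase_slices[p][0] for p in PHASES]
        assert starts[0] == 0 and ends[-1] == mesh.n_intervals
        assert starts[1:] == ends[:-1]

    def test_prescribed_knee_matches_trajectory_shape(self):
        mesh = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2))
        knee = KneeTrajectoryParams(k_a=30.0, k_s=0.2, k_w=-0.1)
        theta = mesh.prescribed_knee(knee)
        a, b = mesh.phase_slices["swing_leg_r"]
        for m in range(a, b + 1):
            u = (m - a) / (b - a)
            expected = np.deg2rad(eval_knee_trajectory(
                KneeTrajectoryParams(30.0, 0.2, -0.1, 1.0), u))
            assert theta[m, 0] == pytest.approx(expected, abs=1e-12)
        # locked everywhere else; left knee mirrors in its own window
        outside = [m for m in range(mesh.n_nodes) if not a <= m <= b]
        assert np.all(theta[outside, 0] == 0.0)

    def test_locked_prescription_is_zero(self):
        mesh = _Mesh(OCPConfig())
        assert np.all(mesh.prescribed_knee(None) == 0.0)

    def test_interval_lengths_scale_with_parameters(self):
        mesh = _Mesh(OCPConfig(n_mesh_swing=2, n_mesh_support=1))
        fr = np.array([DEFAULT_PHASE_FRACTIONS[p] for p in PHASES])
        h = mesh.interval_lengths(4.0, fr)
        assert h.sum() == pytest.approx(4.0)
        t = mesh.node_times(4.0, fr)
        assert t[0] == 0.0 and t[-1] == pytest.approx(4.0)


def test_consistent_controls_invert_the_defect_chain(rng):
    h = rng.uniform(0.1, 0.4, 9)
    x = np.cumsum(rng.normal(0, 1, (10, 3)), axis=0)
    u = _consistent_controls(x, h)
    lhs = 0.5 * h[:, None] * (u[:-1] + u[1:])
    np.testing.assert_allclose(lhs, np.diff(x, axis=0), atol=1e-10)


@pytest.fixture(scope="module")
def draft(sci_model, contact_params, gait_spec):
    return draft_reference(gait_spec, sci_model, contact_params)


@pytest.fixture(scope="module")
def nlp(sci_model, contact_params, draft):
    return transcribe(sci_model, contact_params, CostWeights(), draft,
                      "predict", KneeTrajectoryParams(k_a=30.0),
                      OCPConfig(n_mesh_swing=2, n_mesh_support=1))


class TestTranscription:
    def test_variable_and_constraint_counts(self, nlp):
        nn = nlp.nn
        assert nn == 4 * 2 + 4 * 1 + 1
        assert nlp.n_z == nn * (12 * 4 + 9 * 2 + 8) + 10
        assert nlp.n_con >= 45 * (nn - 1) + 12 * nn + 8 * nn

    def test_knee_prescribed_only_in_swing(self, nlp):
        a, b = nlp.mesh.phase_slices["swing_leg_r"]
        assert nlp.theta_knee[(a + b) // 2, 0] > 0.0
        assert nlp.theta_knee[0, 0] == 0.0
        assert nlp.theta_knee[a, 0] == 0.0
        assert nlp.theta_knee[b, 0] == 0.0

    def test_empty_reference_rejected(self, sci_model, contact_params):
        with pytest.raises(ValueError, match="reference"):
            transcribe(sci_model, contact_params, CostWeights(), None,
                       "track", None, OCPConfig())

    def test_infeasible_fraction_tolerance_rejected(self, sci_model,
                                                    contact_params, draft):
        with pytest.raises(ValueError, match="bounds|tolerance"):
            transcribe(sci_model, contact_params, CostWeights(), draft,
                       "track", None,
                       OCPConfig(phase_fraction_abs_tol=-0.01))

    def test_sci_profile_applies_motor_and_capacity_bounds(self, sci_model,
                                                           contact_params,
                                                           draft):
        nlp = transcribe(sci_model, contact_params, CostWeights(), draft,
                         "predict", KneeTrajectoryParams(k_a=20.0),
                         OCPConfig(n_mesh_swing=2, n_mesh_support=1,
                                   profile="sci"))
        # knees bounded by the motor peak torque
        assert nlp.torque_bounds[3] == 34.0
        assert nlp.torque_bounds[4] == 34.0
        # hips bounded by reference max / capacity fraction
        ref_max = np.abs(nlp.tau_ref_nodes[:, 1]).max()
        assert nlp.torque_bounds[1] == pytest.approx(max(ref_max, 1.0) / 0.8)

    def test_constraint_jacobian_matches_finite_differences(self, nlp, rng):
        z0 = nlp.initial_guess() / nlp.var_scale
        J = nlp.jac_z(z0)
        h = 1e-6
        cols = list(rng.choice(nlp.n_z, 12, replace=False))
        cols += list(range(nlp.oP, nlp.oP + 10))
        for j in cols:
            zp = z0.copy()
            zp[j] += h
            zm = z0.copy()
            zm[j] -= h
            fd = (nlp.con_z(zp) - nlp.con_z(zm)) / (2 * h)
            an = np.asarray(J[:, j].todense()).ravel()
            assert np.abs(fd - an).max() <= 1e-5 * max(1.0, np.abs(an).max())

    def test_objective_gradient_matches_finite_differences(self, nlp, rng):
        z0 = nlp.initial_guess() / nlp.var_scale
        g = nlp.grad_z(z0)
        h = 1e-6
        for j in rng.choice(nlp.n_z, 15, replace=False):
            zp = z0.copy()
            zp[j] += h
            zm = z0.copy()
            zm[j] -= h
            fd = (nlp.obj_z(zp) - nlp.obj_z(zm)) / (2 * h)
            assert fd == pytest.approx(g[j], rel=1e-4, abs=1e-7)

    def test_objective_hessian_matches_gradient_differences(self, nlp, rng):
        z0 = nlp.initial_guess() / nlp.var_scale
        H = nlp.hess_z(z0)
        h = 1e-6
        # Gauss-Newton Hessian is exact for the quadratic terms; check a
        # quadratic-term column (a jerk variable)
        j = nlp.off["jerk"] + 5
        zp = z0.copy()
        zp[j] += h
        zm = z0.copy()
        zm[j] -= h
        fd = (nlp.grad_z(zp) - nlp.grad_z(zm)) / (2 * h)
        col = np.asarray(H[:, j].todense()).ravel()
        # the Gauss-Newton Hessian drops the cross terms with the free
        # parameters (quadrature weights); compare the state rows only
        np.testing.assert_allclose(col[:nlp.oP], fd[:nlp.oP],
                                   atol=1e-4 * max(1, col.max()))

    def test_warm_start_chains_are_consistent(self, sci_model,
                                              contact_params, draft):
        """The jerk and torque-rate chains of the initial guess are repaired
        exactly; the kinematic chains keep the (smooth) reference derivative
        seeding, whose defect residuals stay small."""
        nlp = transcribe(sci_model, contact_params, CostWeights(), draft,
                         "track", None,
                         OCPConfig(n_mesh_swing=2, n_mesh_support=1))
        x0 = nlp.initial_guess()
        c = nlp.constraints(x0)
        defects = c[nlp.r_defect:nlp.r_dyn]
        # with an unchanged (locked) prescription every chain is repaired
        assert np.abs(defects).max() < 1e-8
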