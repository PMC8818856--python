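"""Clinical gait measures on analytically constructed trajectories."""

import numpy as np
import pandas as pd
import pytest

from kafogait.costs import ReferenceData
from kafogait.measures import (GaitMeasuresReport, cadence, foot_clearance,
                               gait_measures, hip_flexion_rom, rmse_report,
                               stride_length)
from kafogait.ocp import (DEFAULT_PHASE_FRACTIONS, GaitFreeParams, OCPConfig,
                          PHASES, SolutionTrajectory, _Mesh)


def make_solution(q, T=4.0, L=0.5, n_mesh=(4, 2), reactions=None):
    """Wrap a (n_nodes, 12) coordinate array into a SolutionTrajectory."""
    mesh = _Mesh(OCPConfig(n_mesh_swing=n_mesh[0], n_mesh_support=n_mesh[1]))
    assert q.shape[0] == mesh.n_nodes
    fr = np.array([DEFAULT_PHASE_FRACTIONS[p] for p in PHASES])
    t = mesh.node_times(T, fr)
    n = mesh.n_nodes
    if reactions is None:
        reactions = {d: np.zeros((n, 2)) for d in
                     ("foot_r", "foot_l", "crutch_r", "crutch_l")}
    qdot = np.gradient(q, t, axis=0)
    return SolutionTrajectory(
        time=t, q=q, qdot=qdot, qddot=np.zeros((n, 12)),
        tau=np.zeros((n, 9)), jerk=np.zeros((n, 12)),
        taurate=np.zeros((n, 9)), reactions=reactions,
        free_params=GaitFreeParams(T, L, dict(DEFAULT_PHASE_FRACTIONS)),
        objective=0.0, objective_breakdown={}, status="synthetic",
        converged=True, mode="predict", prescribed_knee=np.zeros((n, 2)),
        phase_slices=dict(mesh.phase_slices))


@pytest.fixture()
def leg_length(sci_model):
    return sci_model.segments["thigh_r"].length \
        + sci_model.segments["shank_r"].length


class TestFootClearance:
    def test_constant_toe_height(self, sci_model, leg_length):
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 1] = leg_length + 0.03
        sol = make_solution(q)
        cl = foot_clearance(sol, sci_model)
        assert cl["r"] == pytest.approx(3.0, abs=1e-9)
        assert cl["l"] == pytest.approx(3.0, abs=1e-9)

    def test_sinusoidal_profile_matches_analytic_minimum(self, sci_model,
                                                         leg_length):
        mesh = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2))
        T = 4.0
        fr = np.array([DEFAULT_PHASE_FRACTIONS[p] for p in PHASES])
        t = mesh.node_times(T, fr)
        q = np.zeros((mesh.n_nodes, 12))
        q[:, 1] = leg_length + 0.02 + 0.01 * np.cos(2 * np.pi * t / T)
        sol = make_solution(q)
        a, b = mesh.phase_slices["swing_leg_r"]
        ta, tb = t[a], t[b]
        span = tb - ta
        td = np.linspace(ta + 0.2 * span, tb - 0.2 * span, 5001)
        expected = (0.02 + 0.01 * np.cos(2 * np.pi * td / T)).min() * 100
        assert foot_clearance(sol, sci_model, "r") == pytest.approx(
            expected, abs=1e-3)

    def test_missing_swing_window_errors(self, sci_model, leg_length):
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 1] = leg_length + 0.03
        sol = make_solution(q)
        sol.phase_slices.pop("swing_leg_r")
        with pytest.raises(ValueError, match="swing window"):
            foot_clearance(sol, sci_model, "r")


class TestStrideAndCadence:
    def test_uniform_advance_gives_that_stride(self, sci_model, leg_length):
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 1] = leg_length + 0.01
        q[:, 0] = np.linspace(0.0, 0.5, n)
        sol = make_solution(q)
        assert stride_length(sol, sci_model) == pytest.approx(0.5)

    def test_mean_over_devices(self, sci_model, leg_length):
        """Arm swing makes crutch tips advance differently from the feet;
        the stride is the arithmetic mean of the four advances."""
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 1] = leg_length + 0.01
        q[:, 0] = np.linspace(0.0, 0.5, n)
        q[-1, 8] = q[-1, 9] = 0.2      # shoulders flexed at cycle end
        sol = make_solution(q)
        pk0 = sci_model.point_kinematics(q[0])
        pk1 = sci_model.point_kinematics(q[-1])
        pts = [sci_model.foot_mid["r"], sci_model.foot_mid["l"],
               sci_model.crutch_tips["r"], sci_model.crutch_tips["l"]]
        expected = np.mean([pk1["pos"][p, 0] - pk0["pos"][p, 0] for p in pts])
        assert stride_length(sol, sci_model) == pytest.approx(expected)
        assert expected != pytest.approx(0.5)

    def test_zero_displacement_cycle(self, sci_model, leg_length):
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 1] = leg_length + 0.01
        assert stride_length(make_solution(q), sci_model) == 0.0

    @pytest.mark.parametrize("T,expected", [(4.4, 120 / 4.4), (2.0, 60.0)])
    def test_cadence_two_steps_per_cycle(self, sci_model, leg_length, T,
                                         expected):
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 1] = leg_length
        sol = make_solution(q, T=T)
        assert cadence(sol) == pytest.approx(expected)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            GaitFreeParams(-1.0, 0.5, dict(DEFAULT_PHASE_FRACTIONS))


class TestHipRom:
    def test_constant_angle_gives_zero(self, sci_model, leg_length):
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 4] = 0.3
        rom = hip_flexion_rom(make_solution(q))
        assert rom["r"] == 0.0

    def test_sinusoid_rom_is_twice_amplitude(self, sci_model):
        mesh = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2))
        t = np.linspace(0, 1, mesh.n_nodes)
        q = np.zeros((mesh.n_nodes, 12))
        A = np.deg2rad(14.0)
        q[:, 5] = A * np.sin(2 * np.pi * t)   # full period sampled at nodes
        rom = hip_flexion_rom(make_solution(q))
        dense = np.rad2deg(A * np.sin(2 * np.pi * t))
        assert rom["l"] == pytest.approx(dense.max() - dense.min())

    def test_arbitrary_profile_max_minus_min(self, sci_model, rng):
        mesh = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2))
        q = np.zeros((mesh.n_nodes, 12))
        vals = rng.normal(0.0, 0.3, mesh.n_nodes)
        q[:, 4] = vals
        rom = hip_flexion_rom(make_solution(q))
        assert rom["r"] == pytest.approx(
            np.rad2deg(vals.max() - vals.min()))


class TestRmseReport:
    def _ref_from(self, sol):
        return ReferenceData(
            time=sol.time, q_exp=sol.q, tau_exp=sol.tau,
            reactions_exp={d: sol.reactions[d] for d in sol.reactions},
            gait_params_exp={"cycle_duration": sol.free_params.cycle_duration,
                             "stride_length": sol.free_params.stride_length,
                             "phase_fractions": sol.free_params.phase_fractions})

    def test_identical_trajectories_give_zero(self, sci_model, leg_length):
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 1] = leg_length
        sol = make_solution(q)
        table = rmse_report(sol, self._ref_from(sol))
        assert (table["rmse"] == 0).all()

    def test_constant_offset_single_channel(self, sci_model, leg_length):
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q = np.zeros((n, 12))
        q[:, 1] = leg_length
        sol = make_solution(q)
        ref = self._ref_from(sol)
        q2 = q.copy()
        q2[:, 4] += np.deg2rad(5.0)   # hip_r offset by 5 deg
        sol2 = make_solution(q2)
        table = rmse_report(sol2, ref).set_index(["group", "quantity"])
        assert table.loc[("lower_limbs", "angle_deg"), "rmse"] == \
            pytest.approx(5.0 / 4)     # one of four lower-limb channels
        assert table.loc[("all", "angle_deg"), "rmse"] == \
            pytest.approx(5.0 / 10)

    def test_random_pair_matches_hand_oracle(self, sci_model, leg_length, rng):
        from kafogait.measures import ANGULAR_DOFS
        from kafogait.skeleton import PLANAR_DOF_ORDER
        n = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2)).n_nodes
        q1 = rng.normal(0.0, 0.2, (n, 12))
        q2 = rng.normal(0.0, 0.2, (n, 12))
        sol1 = make_solution(q1)
        ref = self._ref_from(sol1)
        sol2 = make_solution(q2)
        table = rmse_report(sol2, ref).set_index(["group", "quantity"])
        per_chan = [np.sqrt(np.mean(np.rad2deg(
            q2[:, PLANAR_DOF_ORDER.index(c)] - q1[:, PLANAR_DOF_ORDER.index(c)]
        ) ** 2)) for c in ANGULAR_DOFS]
        assert table.loc[("all", "angle_deg"), "rmse"] == \
            pytest.approx(np.mean(per_chan))


class TestNormalization:
    def test_baseline_against_itself_is_one(self, sci_model, leg_length):
        mesh = _Mesh(OCPConfig(n_mesh_swing=4, n_mesh_support=2))
        t = np.linspace(0, 1, mesh.n_nodes)
        q = np.zeros((mesh.n_nodes, 12))
        q[:, 0] = 0.5 * t
        q[:, 1] = leg_length + 0.02 + 0.005 * np.cos(2 * np.pi * t)
        q[:, 4] = 0.2 * np.sin(2 * np.pi * t)
        q[:, 5] = 0.2 * np.sin(2 * np.pi * t + 1.0)
        sol = make_solution(q)
        base = gait_measures(sol, sci_model)
        rep = gait_measures(sol, sci_model, baseline=base)
        for k, v in rep.normalized.items():
            assert v == pytest.approx(1.0), k

    def test_negative_clearance_rejected(self):
        with pytest.raises(ValueError, match="clearance"):
            GaitMeasuresReport(foot_clearance_cm={"r": -1.0, "l": 2.0},
                               stride_length_m=0.5, cadence_spm=30.0,
                               hip_flexion_rom_deg={"r": 10.0, "l": 10.0})
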