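"""Clinical gait measures and RMSE evaluation of predicted gaits.

The four physiotherapist-facing measures used to rank assistive knee
trajectories are per-side foot clearance (minimum toe height during that
foot's swing, cm), stride length (mean anterior advance of feet and
crutch tips over one cycle, m), cadence (two foot steps per cycle,
steps/min), and per-side hip flexion range of motion (deg).  Measures
can be normalized to a designated locked-knee baseline, which is how the
knee-flexion sweep is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from kafogait.skeleton import PLANAR_DOF_ORDER

#: Angular-coordinate groups of the RMSE table (planar DOF names).
RMSE_GROUPS = {
    "pelvis_torso": ("pelvis_rot", "lumbar"),
    "upper_limbs": ("shoulder_r", "shoulder_l", "elbow_r", "elbow_l"),
    "lower_limbs": ("hip_r", "hip_l", "knee_r", "knee_l"),
}
ANGULAR_DOFS = RMSE_GROUPS["pelvis_torso"] + RMSE_GROUPS["upper_limbs"] \
    + RMSE_GROUPS["lower_limbs"]

_SWING_PHASE = {"r": "swing_leg_r", "l": "swing_leg_l"}


@dataclass
class GaitMeasuresReport:
    """Clinical measures of one predicted gait (optionally vs a baseline)."""

    foot_clearance_cm: dict          # side -> cm
    stride_length_m: float
    cadence_spm: float
    hip_flexion_rom_deg: dict        # side -> deg
    rmse_table: pd.DataFrame | None = None
    normalized: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cadence_spm <= 0:
            raise ValueError("cadence must be > 0")
        for side, v in self.foot_clearance_cm.items():
            if v < 0:
                raise ValueError(f"negative foot clearance on side {side!r}")
        for side, v in self.hip_flexion_rom_deg.items():
            if v < 0:
                raise ValueError(f"negative hip ROM on side {side!r}")

    def flat(self) -> dict:
        out = {"stride_length_m": self.stride_length_m,
               "cadence_spm": self.cadence_spm}
        for side in ("r", "l"):
            out[f"foot_clearance_{side}_cm"] = self.foot_clearance_cm[side]
            out[f"hip_flexion_rom_{side}_deg"] = self.hip_flexion_rom_deg[side]
        return out


def _dense_toe_height(solution, model, side, n_dense=200, trim=0.2):
    """Toe height on a dense grid inside the foot's swing window.

    The window is trimmed by ``trim`` (fraction) at each end: at the
    lift-off and touch-down instants the toe is at ground level by
    definition, so clearance is measured over the central part of swing
    (as a gait-event detector would delimit it).
    """
    phase = _SWING_PHASE[side]
    if phase not in solution.phase_slices:
        raise ValueError(f"solution has no swing window for side {side!r}")
    a, b = solution.phase_slices[phase]
    if b <= a:
        raise ValueError(f"zero-length swing window for side {side!r}")
    t = solution.time
    # interpolate with the solution's own states (cubic Hermite from q and
    # qdot), the same representation whose ground clearance the optimal
    # control problem constrains
    spline = CubicHermiteSpline(t, solution.q, solution.qdot, axis=0)
    span = t[b] - t[a]
    td = np.linspace(t[a] + trim * span, t[b] - trim * span, n_dense)
    qd = spline(td)
    pk = model.point_kinematics(qd)
    return pk["pos"][:, model.toe_points[side], 1]


def foot_clearance(solution, model, side=None) -> dict | float:
    """Minimum toe height above ground during swing, per side (cm)."""
    if side is not None:
        return float(_dense_toe_height(solution, model, side).min() * 100.0)
    return {s: float(_dense_toe_height(solution, model, s).min() * 100.0)
            for s in ("r", "l")}


def stride_length(solution, model) -> float:
    """Mean anterior displacement of feet and crutch tips over the cycle."""
    pk0 = model.point_kinematics(solution.q[0])
    pk1 = model.point_kinematics(solution.q[-1])
    pts = [model.foot_mid["r"], model.foot_mid["l"],
           model.crutch_tips["r"], model.crutch_tips["l"]]
    adv = [pk1["pos"][p, 0] - pk0["pos"][p, 0] for p in pts]
    return float(np.mean(adv))


def cadence(solution) -> float:
    """Steps per minute at two foot steps per cycle."""
    T = solution.free_params.cycle_duration
    if T <= 0:
        raise ValueError("cycle duration must be > 0")
    return 120.0 / T


def hip_flexion_rom(solution) -> dict:
    """Hip flexion range of motion over the whole cycle, per side (deg)."""
    out = {}
    for side, name in (("r", "hip_r"), ("l", "hip_l")):
        i = PLANAR_DOF_ORDER.index(name)
        ang = np.rad2deg(solution.q[:, i])
        out[side] = float(ang.max() - ang.min())
    return out


def rmse_report(solution, reference) -> pd.DataFrame:
    """Group-mean angular RMSE (deg) and force RMSE (N) vs a reference.

    Trajectories are compared on the reference grid after normalizing both
    cycles to [0, 1]; per-channel RMSEs are averaged (unweighted) within
    each group.
    """
    t_sol = solution.time / solution.time[-1]
    t_ref = np.asarray(reference.time, dtype=float)
    t_ref_n = t_ref / t_ref[-1]
    q_sol = np.stack([np.interp(t_ref_n, t_sol, solution.q[:, j])
                      for j in range(solution.q.shape[1])], axis=1)
    q_ref = np.asarray(reference.q_exp, dtype=float)
    rows = []
    chan_rmse = {}
    for name in ANGULAR_DOFS:
        i = PLANAR_DOF_ORDER.index(name)
        err = np.rad2deg(q_sol[:, i] - q_ref[:, i])
        chan_rmse[name] = float(np.sqrt(np.mean(err ** 2)))
    for group, chans in RMSE_GROUPS.items():
        rows.append({"group": group, "quantity": "angle_deg",
                     "rmse": float(np.mean([chan_rmse[c] for c in chans]))})
    rows.append({"group": "all", "quantity": "angle_deg",
                 "rmse": float(np.mean(list(chan_rmse.values())))})
    # forces: normal (fy) and tangential (fx) across all four devices
    dev_names = list(reference.reactions_exp)
    for comp, label in ((1, "normal_force_N"), (0, "tangential_force_N")):
        errs = []
        for dev in dev_names:
            ref_f = np.asarray(reference.reactions_exp[dev], dtype=float)[:, comp]
            sol_f = np.interp(t_ref_n, t_sol, solution.reactions[dev][:, comp])
            errs.append(np.sqrt(np.mean((sol_f - ref_f) ** 2)))
        rows.append({"group": "all", "quantity": label,
                     "rmse": float(np.mean(errs))})
    return pd.DataFrame(rows)


def gait_measures(solution, model, baseline: GaitMeasuresReport | None = None,
                  reference=None) -> GaitMeasuresReport:
    """Full clinical report; optionally normalized to a locked-knee baseline."""
    rep = GaitMeasuresReport(
        foot_clearance_cm=foot_clearance(solution, model),
        stride_length_m=stride_length(solution, model),
        cadence_spm=cadence(solution),
        hip_flexion_rom_deg=hip_flexion_rom(solution),
        rmse_table=None if reference is None else rmse_report(solution, reference),
    )
    if baseline is not None:
        flat = rep.flat()
        base = baseline.flat()
        rep.normalized = {k: flat[k] / base[k] if base[k] != 0 else np.nan
                          for k in flat}
    return rep
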