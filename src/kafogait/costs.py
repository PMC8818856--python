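"""Objective terms for the gait optimal control problems.

The composite objective is

    J = integral_{t0}^{tf} ( J_track(x, u) + J_opt(x, u) + w_reg * J_reg(u) ) dt

with tracking terms (lumbar + hip flexion torques; upper-limb joint
angles), optimality terms (segment local angular momentum, joint
mechanical power, knee motor torque) and regularization terms (joint jerk
and joint torque change) with a default regularization weight of 0.01.
Every term is evaluable per node so the collocation transcription can
integrate it with trapezoidal quadrature; all terms are non-negative and
vanish on their neutral input.

Term scale factors normalise each term to a similar magnitude; by default
each term is divided by its value on the reference trajectory (fallback 1
when that value is zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kafogait.skeleton import N_BASE, N_Q_PLANAR, PLANAR_DOF_ORDER

#: Joint (torque-carrying) DOFs, in tau-vector order.
JOINT_DOFS = PLANAR_DOF_ORDER[N_BASE:]

#: tau-vector indices of tracked torques: lumbar + both hip flexions.
TRACKED_TORQUE_IDX = tuple(JOINT_DOFS.index(n) for n in ("lumbar", "hip_r", "hip_l"))
#: q-vector indices of the upper-limb angle coordinates.
UPPER_ANGLE_IDX = tuple(PLANAR_DOF_ORDER.index(n)
                        for n in ("shoulder_r", "shoulder_l", "elbow_r", "elbow_l"))
#: tau-vector indices of the knee motor torques.
KNEE_TORQUE_IDX = tuple(JOINT_DOFS.index(n) for n in ("knee_r", "knee_l"))
#: tau-vector index of the lumbar joint (the "lumbar mechanical power" variant).
LUMBAR_TORQUE_IDX = (JOINT_DOFS.index("lumbar"),)

#: Term set of the selected predictive cost: lumbar mechanical power, all
#: segment angular momentum, knee motor torque, plus the two regularizers.
DEFAULT_COST_TERMS = ("lumbar_mech_power", "angular_momentum", "motor_torque",
                      "jerk", "torque_change")

#: Which weight field applies to each named term.
TERM_WEIGHT_FIELD = {
    "track_torque": "w_track_torque",
    "track_upper_angles": "w_track_upper_angles",
    "angular_momentum": "w_ang_momentum",
    "mech_power": "w_mech_power",
    "lumbar_mech_power": "w_mech_power",
    "motor_torque": "w_motor_torque",
    "jerk": "w_reg",
    "torque_change": "w_reg",
}


@dataclass
class CostWeights:
    """Weights and per-term normalisation constants of the composite cost."""

    w_track_torque: float = 1.0
    w_track_upper_angles: float = 1.0
    w_ang_momentum: float = 1.0
    w_mech_power: float = 1.0
    w_motor_torque: float = 1.0
    w_reg: float = 0.01
    scale_factors: dict = field(default_factory=dict)

    def __post_init__(self):
        for f in ("w_track_torque", "w_track_upper_angles", "w_ang_momentum",
                  "w_mech_power", "w_motor_torque", "w_reg"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for name, s in self.scale_factors.items():
            if s <= 0:
                raise ValueError(f"scale factor for {name!r} must be > 0")

    def weight(self, term: str) -> float:
        return getattr(self, TERM_WEIGHT_FIELD[term])

    def scale(self, term: str) -> float:
        return float(self.scale_factors.get(term, 1.0))


@dataclass
class ReferenceData:
    """Reference gait used for tracking, initial guessing and calibration."""

    time: np.ndarray            # (N,) s, strictly increasing
    q_exp: np.ndarray           # (N, 12) rad / m
    tau_exp: np.ndarray         # (N, 9) N m
    reactions_exp: dict         # device -> (N, 2) ground-frame forces, N
    gait_params_exp: dict       # cycle_duration, stride_length, phase_fractions
    qd_exp: np.ndarray | None = None
    qdd_exp: np.ndarray | None = None
    jerk_exp: np.ndarray | None = None
    taurate_exp: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.q_exp = np.asarray(self.q_exp, dtype=float)
        self.tau_exp = np.asarray(self.tau_exp, dtype=float)
        n = self.time.shape[0]
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("reference time grid must be strictly increasing")
        if self.q_exp.shape != (n, N_Q_PLANAR):
            raise ValueError(f"q_exp must have shape ({n}, {N_Q_PLANAR})")
        if self.tau_exp.shape != (n, N_Q_PLANAR - N_BASE):
            raise ValueError(f"tau_exp must have shape ({n}, {N_Q_PLANAR - N_BASE})")
        for dev, arr in self.reactions_exp.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 2):
                raise ValueError(f"reactions_exp[{dev!r}] must have shape ({n}, 2)")
            self.reactions_exp[dev] = arr

    def periodicity_residual(self):
        """Max endpoint mismatch of angles (excl. forward translation)."""
        dq = np.abs(self.q_exp[-1] - self.q_exp[0])
        dq[0] = 0.0
        return float(dq.max())


def _missing(arrs, channels, what):
    raise ValueError(f"missing reference channel(s) {channels} for {what}")


# ---------------------------------------------------------------------------
# Individual integrand terms.  Each accepts a single state (trailing axis) or
# a trajectory with a leading node axis and returns scalar / per-node values.
# ---------------------------------------------------------------------------

def term_track_torque(tau, tau_ref, indices=TRACKED_TORQUE_IDX):
    """Sum over tracked joints (lumbar, hip flexion L/R) of (tau_exp - tau)^2."""
    tau = np.asarray(tau)
    tau_ref = np.asarray(tau_ref)
    idx = np.asarray(indices, dtype=int)
    if tau.shape[-1] <= idx.max() or tau_ref.shape[-1] <= idx.max():
        _missing((tau, tau_ref), [JOINT_DOFS[i] for i in idx], "torque tracking")
    d = tau[..., idx] - tau_ref[..., idx]
    return (d * d).sum(-1)


def term_track_upper_angles(q, q_ref, indices=UPPER_ANGLE_IDX):
    """Sum over shoulder/elbow coordinates of (q_exp - q)^2."""
    q = np.asarray(q)
    q_ref = np.asarray(q_ref)
    idx = np.asarray(indices, dtype=int)
    if q.shape[-1] <= idx.max() or q_ref.shape[-1] <= idx.max():
        _missing((q, q_ref), [PLANAR_DOF_ORDER[i] for i in idx], "angle tracking")
    d = q[..., idx] - q_ref[..., idx]
    return (d * d).sum(-1)


def term_angular_momentum(model, qdot):
    """Sum over segments of the squared local angular momentum L_s = I_s w_s."""
    qdot = np.asarray(qdot)
    omega = qdot @ model._ang_sel.T
    L = model._inertia * omega
    return (L * L).sum(-1)


def term_mech_power(qdot, tau, joint_indices=None):
    """Sum over actuated joints of (qdot_i * tau_i)^2.

    ``joint_indices`` (tau-vector indices) restricts the sum; the selected
    predictive cost uses the lumbar-only variant ``LUMBAR_TORQUE_IDX``.
    """
    qdot = np.asarray(qdot)
    tau = np.asarray(tau)
    idx = np.arange(tau.shape[-1]) if joint_indices is None \
        else np.asarray(joint_indices, dtype=int)
    p = qdot[..., N_BASE + idx] * tau[..., idx]
    return (p * p).sum(-1)


def term_motor_torque(tau, indices=KNEE_TORQUE_IDX):
    """Sum over both knees of tau^2 (the orthosis motor effort)."""
    tau = np.asarray(tau)
    t = tau[..., np.asarray(indices, dtype=int)]
    return (t * t).sum(-1)


def term_jerk(jerk):
    """Sum over all DOFs of squared joint jerk."""
    jerk = np.asarray(jerk)
    return (jerk * jerk).sum(-1)


def term_torque_change(taurate):
    """Sum over actuated DOFs of squared torque rate."""
    taurate = np.asarray(taurate)
    return (taurate * taurate).sum(-1)


def composite_objective(weights: CostWeights, term_trajectories: dict,
                        time_grid) -> float:
    """Weighted, scaled trapezoidal integral of the named integrand terms.

    ``term_trajectories`` maps term names (keys of TERM_WEIGHT_FIELD) to
    per-node integrand arrays on the common ``time_grid``.  Regularization
    terms enter with the shared weight ``w_reg`` (default 0.01).
    """
    t = np.asarray(time_grid, dtype=float)
    total = 0.0
    for name, traj in term_trajectories.items():
        if name not in TERM_WEIGHT_FIELD:
            raise ValueError(f"unknown cost term {name!r}")
        w = weights.weight(name)
        traj = np.asarray(traj, dtype=float)
        if traj.shape != t.shape:
            raise ValueError(
                f"term {name!r} not on the common time grid "
                f"({traj.shape} vs {t.shape})")
        total += w / weights.scale(name) * float(np.trapezoid(traj, t))
    return total
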