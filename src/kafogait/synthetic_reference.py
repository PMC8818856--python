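"""Synthetic locked-knee four-point crutch-gait reference generator.

The study-style inputs (motion capture, force plates, instrumented
crutches) are emulated by a two-stage construction:

1. a closed-form kinematic *draft*: smooth periodic joint-angle waveforms
   honouring the four-point swing order (left crutch, right leg, right
   crutch, left leg) with knees locked at 0 deg.  Stance feet and crutch
   tips are planted at fixed ground positions (solved by single-link leg
   and two-link arm inverse kinematics), swing targets advance by one
   stride with a smooth-step profile, swing legs add a hip-flexion bump
   that generates toe clearance of a few centimetres, and the pelvis
   height rides a low-pass consistency correction that keeps the deepest
   planted contact point at a small target penetration;
2. a jerk-minimizing tracking solve (the same optimal control problem
   used for subject data) that refines the draft into a dynamically
   consistent trajectory: residual loads within tolerance, reactions from
   the contact models, and periodic states.

The refined solution doubles as tracking target, initial guess and
calibration input for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from kafogait.costs import ReferenceData
from kafogait.contact import device_resultants, element_contact_forces
from kafogait.ocp import (DEFAULT_PHASE_FRACTIONS, DEVICE_ORDER, PHASES,
                          SWING_DEVICE, OCPConfig, solve_tracking)
from kafogait.skeleton import N_BASE, PlanarModel


@dataclass
class SyntheticGaitSpec:
    """Study conditions of the emulated locked-knee crutch gait."""

    cycle_duration: float = 4.4       # s (slow four-point assisted gait)
    stride_length: float = 0.51       # m
    phase_fractions: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS))
    hip_bump_deg: float = 22.0        # swing-leg hip flexion bump
    torso_lean_deg: float = 7.0       # forward trunk lean
    crutch_lead_m: float = 0.15       # crutch plant ahead of the shoulder
    foot_penetration_m: float = 3.0e-3
    crutch_penetration_m: float = 2.5e-3
    swing_lift_m: float = 0.06        # crutch tip lift at mid swing
    noise_sd: float = 0.0             # deg, optional measurement noise
    seed: int = 42
    n_samples: int = 221

    def __post_init__(self):
        fr = np.array([self.phase_fractions[p] for p in PHASES], dtype=float)
        if np.any(fr <= 0) or np.any(fr >= 1):
            raise ValueError("phase fractions must lie in (0, 1)")
        if abs(fr.sum() - 1.0) > 1e-6:
            raise ValueError("phase fractions must sum to 1")
        order = [p for p in PHASES if p in SWING_DEVICE]
        expected = ["swing_crutch_l", "swing_leg_r", "swing_crutch_r",
                    "swing_leg_l"]
        if order != expected:
            raise ValueError("swing order must be left crutch, right leg, "
                             "right crutch, left leg")


def _smooth_step(u):
    """C2 monotone 0->1 profile with zero end velocity/acceleration."""
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


class _Draft:
    """Closed-form draft kinematics q(t) of one cycle."""

    def __init__(self, spec: SyntheticGaitSpec, model: PlanarModel):
        self.spec = spec
        self.model = model
        self.T = spec.cycle_duration
        self.L = spec.stride_length
        fr = np.array([spec.phase_fractions[p] for p in PHASES])
        edges = np.concatenate([[0.0], np.cumsum(fr)])
        self.windows = {p: (edges[i], edges[i + 1]) for i, p in enumerate(PHASES)}
        self.l_leg = model.segments["thigh_r"].length \
            + model.segments["shank_r"].length
        self.l_pelvis = model.segments["pelvis"].length
        self.l_torso = model.segments["torso"].length
        self.l_ua = model.segments["upperarm_r"].length
        lf = model.length_fractions
        H = model.anthropometry["height"]
        self.l_fa_tip = model.segments["forearm_r"].length \
            + lf["crutch_below_hand"] * H
        # initial plant positions: each device's swing midpoint passes the
        # pelvis (crutches offset forward by the lead)
        self.x0 = {}
        for phase, dev in SWING_DEVICE.items():
            a, b = self.windows[phase]
            centre = 0.5 * (a + b)
            lead = spec.crutch_lead_m if dev.startswith("crutch") else 0.0
            self.x0[dev] = centre * self.L - 0.5 * self.L + lead
        self._solve_pelvis_height()

    # -- device plant/swing target trajectories ----------------------------

    def _target_x(self, dev, u):
        """Anterior ground target of a device at cycle fraction u."""
        phase = next(p for p, d in SWING_DEVICE.items() if d == dev)
        a, b = self.windows[phase]
        s = np.clip((u - a) / (b - a), 0.0, 1.0)
        return self.x0[dev] + self.L * _smooth_step(s)

    def _swing_bump(self, dev, u):
        """Lift profile: quick rise, mid-swing plateau, quick fall (C1)."""
        phase = next(p for p, d in SWING_DEVICE.items() if d == dev)
        a, b = self.windows[phase]
        s = np.clip((u - a) / (b - a), 0.0, 1.0)

        def g(v):
            v = np.clip(v / 0.30, 0.0, 1.0)
            return v * v * (3.0 - 2.0 * v)

        return g(s) * g(1.0 - s)

    # -- pelvis height consistency ----------------------------------------

    def _angles(self, u, y_h):
        """All 12 coordinates at cycle fractions u given pelvis height y_h."""
        spec = self.spec
        T, L = self.T, self.L
        x_h = L * u
        lumbar = -np.deg2rad(spec.torso_lean_deg) * np.ones_like(u)
        q = np.zeros(u.shape + (12,))
        q[..., 0] = x_h
        q[..., 1] = y_h
        q[..., 2] = 0.0
        q[..., 3] = lumbar
        # legs: single rigid link hip -> sole (knee locked)
        for col, dev in ((4, "foot_r"), (5, "foot_l")):
            xt = self._target_x(dev, u)
            arg = np.clip((xt - x_h) / self.l_leg, -0.95, 0.95)
            q[..., col] = np.arcsin(arg) \
                + np.deg2rad(spec.hip_bump_deg) * self._swing_bump(dev, u)
        # knees locked
        q[..., 6] = 0.0
        q[..., 7] = 0.0
        # arms: two-link IK from shoulder to crutch tip target
        alpha_t = lumbar  # torso absolute angle (pelvis_rot = 0)
        lj_x = x_h
        lj_y = y_h + self.l_pelvis
        s_x = lj_x - np.sin(alpha_t) * self.l_torso
        s_y = lj_y + np.cos(alpha_t) * self.l_torso
        for qs, qe, dev in ((8, 10, "crutch_r"), (9, 11, "crutch_l")):
            xt = self._target_x(dev, u)
            yt = -self.spec.crutch_penetration_m \
                + self.spec.swing_lift_m * self._swing_bump(dev, u)
            ux = xt - s_x
            uy = yt - s_y
            d = np.sqrt(ux ** 2 + uy ** 2)
            l1, l2 = self.l_ua, self.l_fa_tip
            d = np.clip(d, abs(l1 - l2) + 1e-3, l1 + l2 - 1e-3)
            psi = np.arctan2(ux, -uy)
            cosb = np.clip((l1 ** 2 + d ** 2 - l2 ** 2) / (2 * l1 * d), -1, 1)
            beta = np.arccos(cosb)
            a1 = psi - beta          # elbow-flexed-forward branch
            e_x = s_x + np.sin(a1) * l1
            e_y = s_y - np.cos(a1) * l1
            a2 = np.arctan2(xt - e_x, -(yt - e_y))
            q[..., qs] = a1 - alpha_t
            q[..., qe] = a2 - a1
        return q

    def _stance_mask(self, dev, u):
        phase = next(p for p, d in SWING_DEVICE.items() if d == dev)
        a, b = self.windows[phase]
        return ~((u > a) & (u < b))

    def _solve_pelvis_height(self):
        """Smooth periodic pelvis height keeping the deepest planted foot
        point near the target penetration."""
        from scipy.interpolate import CubicSpline

        spec = self.spec
        n = 400
        u = np.linspace(0.0, 1.0, n, endpoint=False)
        y = np.full(u.shape, self.l_leg - spec.foot_penetration_m)
        m = self.model
        for _ in range(6):
            q = self._angles(u, y)
            pk = m.point_kinematics(q)
            # deepest planted foot point must sit at -penetration
            lowest = np.full(u.shape, np.inf)
            for side, dev in (("r", "foot_r"), ("l", "foot_l")):
                idx = np.asarray(m.foot_elements[side])
                h = pk["pos"][:, idx, 1].min(axis=1)
                mask = self._stance_mask(dev, u)
                lowest = np.where(mask, np.minimum(lowest, h), lowest)
            y = y - (lowest + spec.foot_penetration_m)
        # one periodic Gaussian smoothing pass keeps accelerations physical
        sigma = 3
        k = np.arange(-3 * sigma, 3 * sigma + 1)
        w = np.exp(-0.5 * (k / sigma) ** 2)
        w /= w.sum()
        y = sum(wi * np.roll(y, ki) for wi, ki in zip(w, k))
        uu = np.concatenate([u, [1.0]])
        yy = np.concatenate([y, [y[0]]])
        self._y_spline = CubicSpline(uu, yy, bc_type="periodic")

    def pelvis_height(self, u):
        return self._y_spline(np.mod(u, 1.0))

    def q(self, t):
        """Draft coordinates at times t (s) within [0, T]."""
        u = np.asarray(t, dtype=float) / self.T
        return self._angles(u, self.pelvis_height(u))

    def q_qd_qdd(self, t):
        dt = 1e-4
        q = self.q(t)
        qp = self.q(np.asarray(t) + dt)
        qm = self.q(np.asarray(t) - dt)
        qd = (qp - qm) / (2 * dt)
        qdd = (qp - 2 * q + qm) / dt ** 2
        return q, qd, qdd


def draft_reference(spec: SyntheticGaitSpec, model: PlanarModel,
                    contact_params) -> ReferenceData:
    """Closed-form draft reference (kinematics + contact-model reactions).

    The draft is smooth and periodic but not yet dynamically consistent;
    :func:`generate_reference` refines it through the tracking solve.
    """
    foot, crutch = contact_params
    draft = _Draft(spec, model)
    t = np.linspace(0.0, spec.cycle_duration, spec.n_samples)
    q, qd, qdd = draft.q_qd_qdd(t)
    forces, pk = element_contact_forces(model, foot, crutch, q, qd)
    g = model.generalized_forces(q, qd, qdd, point_forces=forces)
    reactions = device_resultants(model, foot, crutch, q, qd, forces=forces)
    return ReferenceData(
        time=t, q_exp=q, tau_exp=g[:, N_BASE:],
        reactions_exp={d: reactions[d] for d in DEVICE_ORDER},
        gait_params_exp={"cycle_duration": spec.cycle_duration,
                         "stride_length": spec.stride_length,
                         "phase_fractions": dict(spec.phase_fractions)},
        qd_exp=qd, qdd_exp=qdd)


def generate_reference(spec: SyntheticGaitSpec, model: PlanarModel,
                       contact_params, config: OCPConfig | None = None,
                       refine: bool = True):
    """Generate a dynamically consistent locked-knee reference gait.

    Returns ``(reference, solution)``: the reference data (tracking target /
    initial guess / calibration input) and the tracking solution it came
    from (``None`` when ``refine=False``, which returns the raw draft).
    Output is deterministic for equal spec (including seed).
    """
    draft = draft_reference(spec, model, contact_params)
    if spec.noise_sd > 0:
        draft = add_noise(draft, spec.noise_sd, spec.seed)
    if not refine:
        return draft, None
    config = config or OCPConfig()
    # the draft target is not dynamically consistent: a softer tracking
    # weight lets the refinement prioritise feasibility over reproducing
    # the draft's inconsistencies
    config = replace(config, tracking_weight=min(config.tracking_weight, 1.0e3))
    sol = solve_tracking(model, contact_params, draft, config=config,
                         restarts=2)
    ref = sol.as_reference()
    return ref, sol


def add_noise(ref: ReferenceData, noise_sd: float, seed: int) -> ReferenceData:
    """Add seeded Gaussian measurement noise (deg) to the coordinates only."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    q = np.asarray(ref.q_exp).copy()
    if noise_sd > 0:
        q += np.deg2rad(noise_sd) * rng.standard_normal(q.shape)
    return ReferenceData(time=ref.time.copy(), q_exp=q,
                         tau_exp=np.asarray(ref.tau_exp).copy(),
                         reactions_exp={k: np.asarray(v).copy()
                                        for k, v in ref.reactions_exp.items()},
                         gait_params_exp=dict(ref.gait_params_exp),
                         qd_exp=None if ref.qd_exp is None else np.asarray(ref.qd_exp).copy(),
                         qdd_exp=None if ref.qdd_exp is None else np.asarray(ref.qdd_exp).copy())
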