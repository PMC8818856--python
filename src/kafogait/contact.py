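"""Viscoelastic foot-ground and crutch-ground contact models.

Each foot carries 16 spring-damper elements (8 longitudinal stations x 2
lateral copies; the lateral offset is inert in the sagittal plane but the
element count matches the physical sole grid).  The per-element normal
force is a linear spring with non-linear (velocity-dependent) damping,

    f_n = max(0, k * delta * (1 + c * (-ydot))),    delta = max(0, -y),

and each crutch tip is a Hertzian sphere-on-plane contact with the same
damping structure,

    f_n = max(0, k * delta^(3/2) * (1 + c * (-ydot))).

Tangential forces use a continuous (tanh-regularised) Coulomb friction
model, f_t = -mu * f_n * tanh(v_t / v_s).  The ``smooth=True`` variants
replace the two max() clips by C1 square-root smoothings so the optimal
control transcription stays differentiable (and complex-step safe); the
smoothing scales are config-exposed and small enough that smooth and
exact forces agree to well under the 1 N dynamic-residual tolerance away
from grazing contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

N_FOOT_ELEMENTS = 16

#: Devices in reporting order (2 feet, 2 crutches).
DEVICES = ("foot_r", "foot_l", "crutch_r", "crutch_l")


@dataclass(frozen=True)
class FootContactParams:
    stiffness: float = 3.0e4          # N/m per element
    damping_coeff: float = 1.0        # s/m, multiplicative velocity term
    friction_coeff: float = 0.8       # dynamic mu
    slip_smoothing_velocity: float = 0.05  # m/s, tanh scale
    smoothing_penetration: float = 1.0e-5  # m, C1 clip scale (smooth variant)
    smoothing_damping: float = 1.0e-3      # dimensionless clip scale

    def __post_init__(self):
        for f in ("stiffness", "damping_coeff", "friction_coeff",
                  "slip_smoothing_velocity"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{type(self).__name__}.{f} must be > 0")


@dataclass(frozen=True)
class CrutchContactParams:
    hertz_stiffness: float = 1.0e6    # N/m^(3/2)
    damping_coeff: float = 1.0        # s/m
    friction_coeff: float = 0.8
    slip_smoothing_velocity: float = 0.05
    smoothing_penetration: float = 1.0e-5
    smoothing_damping: float = 1.0e-3

    def __post_init__(self):
        for f in ("hertz_stiffness", "damping_coeff", "friction_coeff",
                  "slip_smoothing_velocity"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{type(self).__name__}.{f} must be > 0")


# ---------------------------------------------------------------------------
# Force laws (vectorised; smooth variants are complex-step safe)
# ---------------------------------------------------------------------------

def _smooth_pos(x, eps):
    """C1 approximation of max(0, x), exact to O(eps) and strictly > 0."""
    return 0.5 * (np.sqrt(x * x + eps * eps) + x)


def normal_force(y, ydot, *, stiffness, damping_coeff, exponent=1.0,
                 smooth=False, eps_pen=2.0e-5, eps_damp=1.0e-2):
    """Normal contact force of one element; never tensile."""
    if smooth:
        delta = _smooth_pos(-np.asarray(y), eps_pen)
        damp = _smooth_pos(1.0 + damping_coeff * (-np.asarray(ydot)), eps_damp)
    else:
        delta = np.maximum(0.0, -np.asarray(y, dtype=float))
        damp = np.maximum(0.0, 1.0 + damping_coeff * (-np.asarray(ydot, dtype=float)))
    if exponent == 1.0:
        dp = delta
    else:
        dp = delta ** exponent
    return stiffness * dp * damp


def friction_force(f_n, v_t, *, friction_coeff, slip_smoothing_velocity):
    """Continuous Coulomb friction; |f_t| < mu*f_n for finite slip speed."""
    return -friction_coeff * f_n * np.tanh(v_t / slip_smoothing_velocity)


def foot_contact_forces(params: FootContactParams, point_kinematics,
                        *, smooth=False):
    """Per-element and resultant foot-ground forces.

    ``point_kinematics`` is a mapping with per-element arrays ``y`` (height,
    m), ``ydot`` (vertical velocity) and ``vt`` (tangential velocity), each
    of length 16, plus optional ``x`` (anterior station position) used for
    the centre of pressure.
    """
    y = np.asarray(point_kinematics["y"], dtype=float)
    ydot = np.asarray(point_kinematics["ydot"], dtype=float)
    vt = np.asarray(point_kinematics["vt"], dtype=float)
    if y.shape[-1] != N_FOOT_ELEMENTS:
        raise ValueError(
            f"foot contact expects {N_FOOT_ELEMENTS} elements, got {y.shape[-1]}")
    f_n = normal_force(y, ydot, stiffness=params.stiffness,
                       damping_coeff=params.damping_coeff, exponent=1.0,
                       smooth=smooth, eps_pen=params.smoothing_penetration,
                       eps_damp=params.smoothing_damping)
    f_t = friction_force(f_n, vt, friction_coeff=params.friction_coeff,
                         slip_smoothing_velocity=params.slip_smoothing_velocity)
    total = np.stack([f_t.sum(-1), f_n.sum(-1)], axis=-1)
    x = np.asarray(point_kinematics.get("x", np.zeros_like(y)), dtype=float)
    fn_sum = f_n.sum(-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = np.where(fn_sum > 0, (f_n * x).sum(-1) / np.where(fn_sum > 0, fn_sum, 1.0),
                       np.nan)
    return {"normal": f_n, "tangential": f_t,
            "resultant": {"force": total, "cop_x": cop}}


def crutch_contact_force(params: CrutchContactParams, tip_kinematics,
                         *, smooth=False):
    """Normal and tangential force at one crutch tip."""
    y = tip_kinematics["y"]
    ydot = tip_kinematics["ydot"]
    vt = tip_kinematics["vt"]
    f_n = normal_force(y, ydot, stiffness=params.hertz_stiffness,
                       damping_coeff=params.damping_coeff, exponent=1.5,
                       smooth=smooth, eps_pen=params.smoothing_penetration,
                       eps_damp=params.smoothing_damping)
    f_t = friction_force(f_n, vt, friction_coeff=params.friction_coeff,
                         slip_smoothing_velocity=params.slip_smoothing_velocity)
    return {"normal": f_n, "tangential": f_t}


# ---------------------------------------------------------------------------
# Whole-model contact evaluation (used by the OCP and the calibration)
# ---------------------------------------------------------------------------

def forces_from_kinematics(model, foot: FootContactParams,
                           crutch: CrutchContactParams, pos, vel, *,
                           smooth=False):
    """Contact forces over all registered points given point kinematics.

    ``pos``/``vel`` are the model's point-kinematics arrays ``(..., P, 2)``;
    the result is zero at non-contact points.  Complex-step safe in the
    smooth variant.
    """
    forces = np.zeros(np.broadcast(pos, vel).shape,
                      dtype=np.result_type(pos, vel))
    for side in ("r", "l"):
        idx = np.asarray(model.foot_elements[side])
        f_n = normal_force(pos[..., idx, 1], vel[..., idx, 1],
                           stiffness=foot.stiffness,
                           damping_coeff=foot.damping_coeff, exponent=1.0,
                           smooth=smooth, eps_pen=foot.smoothing_penetration,
                           eps_damp=foot.smoothing_damping)
        f_t = friction_force(f_n, vel[..., idx, 0],
                             friction_coeff=foot.friction_coeff,
                             slip_smoothing_velocity=foot.slip_smoothing_velocity)
        forces[..., idx, 0] = f_t
        forces[..., idx, 1] = f_n
        ti = model.crutch_tips[side]
        c_n = normal_force(pos[..., ti, 1], vel[..., ti, 1],
                           stiffness=crutch.hertz_stiffness,
                           damping_coeff=crutch.damping_coeff, exponent=1.5,
                           smooth=smooth, eps_pen=crutch.smoothing_penetration,
                           eps_damp=crutch.smoothing_damping)
        c_t = friction_force(c_n, vel[..., ti, 0],
                             friction_coeff=crutch.friction_coeff,
                             slip_smoothing_velocity=crutch.slip_smoothing_velocity)
        forces[..., ti, 0] = c_t
        forces[..., ti, 1] = c_n
    return forces


def element_contact_forces(model, foot: FootContactParams,
                           crutch: CrutchContactParams, q, qd, *, smooth=False):
    """Forces at every foot element and crutch tip for state arrays.

    Returns ``(forces, pk)`` where ``forces`` has shape ``(..., P, 2)`` over
    the model's registered points (zero at non-contact points) and ``pk``
    is the point-kinematics dict.
    """
    pk = model.point_kinematics(q, qd)
    forces = forces_from_kinematics(model, foot, crutch, pk["pos"], pk["vel"],
                                    smooth=smooth)
    return forces, pk


def device_resultants(model, foot, crutch, q, qd, *, smooth=False,
                      forces=None):
    """Resultant ground reaction (fx, fy) per device: 2 feet + 2 crutches."""
    if forces is None:
        forces, _ = element_contact_forces(model, foot, crutch, q, qd,
                                           smooth=smooth)
    out = {}
    for side in ("r", "l"):
        idx = np.asarray(model.foot_elements[side])
        out[f"foot_{side}"] = forces[..., idx, :].sum(-2)
        out[f"crutch_{side}"] = forces[..., model.crutch_tips[side], :]
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_contact(model, reference, initial_params, *, max_nfev=200):
    """Calibrate shared contact parameters by tracking reference reactions.

    The reference kinematic trajectory is tracked exactly (its joint
    coordinates and velocities are held fixed) while {stiffness, damping,
    friction} of the foot grid and the crutch sphere — shared across sides,
    as both feet and both crutches carry identical hardware — are adjusted
    so the modelled ground reactions reproduce the reference reactions in
    the least-squares sense.  The slip-smoothing velocity is poorly
    identifiable and is held fixed.

    ``reference`` must provide ``q``, ``qdot`` arrays on a common time grid
    and a ``reactions`` mapping with per-device (N, 2) force histories.
    Returns a dict with the calibrated parameter sets and the initial/final
    tracking residuals.
    """
    foot0, crutch0 = initial_params
    q = np.asarray(reference.q, dtype=float)
    qd = np.asarray(reference.qdot, dtype=float)
    reactions = {k: np.asarray(v, dtype=float) for k, v in reference.reactions.items()}
    for dev in DEVICES:
        if dev not in reactions:
            raise ValueError(f"reference reactions missing device {dev!r}")
        if reactions[dev].shape[0] != q.shape[0]:
            raise ValueError(
                "reference kinematics and reactions are on different time "
                f"grids ({q.shape[0]} vs {reactions[dev].shape[0]} samples)")
    peak = max(np.abs(reactions[d]).max() for d in DEVICES)
    messages = []
    if peak < 1e-6:
        msg = ("reference contact forces are identically zero: stiffness, "
               "damping and friction are unidentifiable")
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        messages.append(msg)

    def unpack(x):
        kf, cf, mf, kc, cc, mc = (float(v) for v in np.exp(x))
        return (replace(foot0, stiffness=kf, damping_coeff=cf, friction_coeff=mf),
                replace(crutch0, hertz_stiffness=kc, damping_coeff=cc,
                        friction_coeff=mc))

    def residuals(x):
        f, c = unpack(x)
        pred = device_resultants(model, f, c, q, qd)
        return np.concatenate([(pred[d] - reactions[d]).ravel() for d in DEVICES])

    x0 = np.log([foot0.stiffness, foot0.damping_coeff, foot0.friction_coeff,
                 crutch0.hertz_stiffness, crutch0.damping_coeff,
                 crutch0.friction_coeff])
    r0 = residuals(x0)
    cost0 = 0.5 * float(r0 @ r0)
    sol = least_squares(residuals, x0, max_nfev=max_nfev, method="lm")
    foot_cal, crutch_cal = unpack(sol.x)
    if sol.cost > cost0 + 1e-12:
        # never regress past the initial guess
        foot_cal, crutch_cal, final_cost = foot0, crutch0, cost0
    else:
        final_cost = float(sol.cost)
    return {"foot": foot_cal, "crutch": crutch_cal,
            "initial_cost": cost0, "final_cost": final_cost,
            "status": int(sol.status), "messages": messages}
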