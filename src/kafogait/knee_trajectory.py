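"""Pre-defined assistive knee flexion-extension trajectory of the active KAFO.

During swing, the orthosis motor drives the knee along

    theta(t) = (k_a / 2) * [1 - cos(2*pi*t/t_c - k_s*sin(pi*t/t_c)
                                     - k_w*sin(2*pi*t/t_c))],   0 <= t <= t_c

where ``k_a`` is the maximum knee flexion (deg), ``k_s`` the peak
displacement parameter, ``k_w`` the peak width parameter and ``t_c`` the
flexion-extension cycle duration (s).  theta(0) = theta(t_c) = 0 for all
parameter values, so the cycle starts and ends with the knee locked
straight.  In the predictive problems ``t_c`` is set to the (free) swing
duration of the corresponding leg, so the assistive cycle spans exactly
the swing window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KneeTrajectoryParams:
    """Personalization parameters of the assistive knee trajectory."""

    k_a: float          # maximum knee flexion, deg
    k_s: float = 0.0    # peak displacement parameter (flex/ext duration ratio)
    k_w: float = 0.0    # peak width parameter
    t_c: float = 1.0    # flexion-extension cycle duration, s

    def __post_init__(self):
        for name in ("k_a", "k_s", "k_w", "t_c"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.k_a < 0:
            raise ValueError(f"k_a must be >= 0, got {self.k_a}")
        if self.t_c <= 0:
            raise ValueError(f"t_c must be > 0, got {self.t_c}")

    def with_cycle_duration(self, t_c: float) -> "KneeTrajectoryParams":
        """Same shape parameters rescaled to a new cycle duration."""
        return KneeTrajectoryParams(self.k_a, self.k_s, self.k_w, t_c)


def eval_knee_trajectory(params: KneeTrajectoryParams, t):
    """Evaluate the assistive knee angle (deg) at time(s) ``t`` in [0, t_c].

    Raises a domain error outside [0, t_c]: the caller must first map the
    swing-phase time into the cycle window (zero-extension would silently
    hide phase-bookkeeping bugs).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > params.t_c + 1e-12):
        raise ValueError(
            f"t must lie within [0, t_c={params.t_c}]; got range "
            f"[{t.min()}, {t.max()}]")
    u = t / params.t_c
    phase = 2.0 * np.pi * u - params.k_s * np.sin(np.pi * u) \
        - params.k_w * np.sin(2.0 * np.pi * u)
    theta = 0.5 * params.k_a * (1.0 - np.cos(phase))
    return theta if theta.shape else float(theta)


def build_sweep(k_a_values, fixed: dict | None = None):
    """One parameter set per maximum-knee-flexion level.

    All other fields (``k_s``, ``k_w``, ``t_c``) are held identical across
    the sweep, mirroring the clinical procedure of tuning the maximum
    flexion first.
    """
    k_a_values = list(k_a_values)
    if not k_a_values:
        raise ValueError("k_a_values must be non-empty")
    fixed = dict(fixed or {})
    k_s = float(fixed.get("k_s", 0.0))
    k_w = float(fixed.get("k_w", 0.0))
    t_c = float(fixed.get("t_c", 1.0))
    out = []
    for k_a in k_a_values:
        if k_a < 0:
            raise ValueError(f"k_a must be >= 0, got {k_a}")
        out.append(KneeTrajectoryParams(k_a=float(k_a), k_s=k_s, k_w=k_w, t_c=t_c))
    return out
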