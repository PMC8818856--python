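"""Skeletal models for crutch- and active-KAFO-assisted walking.

Two layers live here:

* :class:`ModelTopology` — the declarative full-body schema (31 unlocked
  DOF, ankle/subtalar/MTP locked by the orthosis, crutches and orthosis
  links welded to their host segments).  It is used for conformance and
  documentation only; no dynamics are executed on it.
* :class:`PlanarModel` — the executable sagittal-plane reduction: a
  12-DOF torque-driven multibody chain (3 floating-base DOF + lumbar +
  2 hips + 2 knees + 2 shoulders + 2 elbows) with the orthosis links
  merged into thigh/shank and each crutch welded to its forearm.

All numeric kernels are vectorised over a leading node axis and are
dtype-generic (they accept complex input), which the optimal-control
transcription exploits for complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GRAVITY = 9.80665  # m/s^2

#: Fixed coordinate order of the planar model (spec of PlanarModel).
PLANAR_DOF_ORDER = (
    "pelvis_tx", "pelvis_ty", "pelvis_rot", "lumbar",
    "hip_r", "hip_l", "knee_r", "knee_l",
    "shoulder_r", "shoulder_l", "elbow_r", "elbow_l",
)
N_Q_PLANAR = 12
N_BASE = 3           # floating-base DOFs (tx, ty, rot)
N_JOINT = N_Q_PLANAR - N_BASE

#: Segment order used by every internal array.
SEGMENT_ORDER = (
    "pelvis", "torso", "thigh_r", "thigh_l", "shank_r", "shank_l",
    "upperarm_r", "upperarm_l", "forearm_r", "forearm_l",
)

# ---------------------------------------------------------------------------
# Anthropometric scaling table (standard published regression fractions;
# recorded verbatim in the default config for reproducibility).
# ---------------------------------------------------------------------------

#: Segment length as a fraction of standing height.
LENGTH_FRACTIONS = {
    "pelvis": 0.100,        # hip centre -> lumbosacral joint
    "torso": 0.188,         # lumbosacral joint -> glenohumeral joint
    "thigh": 0.245,
    "shank": 0.246,         # knee -> ankle
    "foot_height": 0.039,   # ankle -> sole
    "foot_length": 0.152,
    "upperarm": 0.186,
    "forearm": 0.146,       # elbow -> hand grip
    "crutch_below_hand": 0.560,  # hand grip -> crutch tip
}

#: Segment mass as a fraction of subject mass (head+neck folded into torso,
#: hand into forearm, foot into shank).
MASS_FRACTIONS = {
    "pelvis": 0.142,
    "torso": 0.436,
    "thigh": 0.100,
    "shank": 0.061,
    "upperarm": 0.028,
    "forearm": 0.022,
}

#: CoM position from the proximal joint as a fraction of segment length.
COM_FRACTIONS = {
    "pelvis": 0.50,
    "torso": 0.50,
    "thigh": 0.433,
    "shank": 0.45,
    "upperarm": 0.436,
    "forearm": 0.43,
}

#: Radius of gyration about the CoM as a fraction of segment length.
GYRATION_FRACTIONS = {
    "pelvis": 0.31,
    "torso": 0.45,
    "thigh": 0.323,
    "shank": 0.416,
    "upperarm": 0.322,
    "forearm": 0.468,
}

#: Default device inertial properties: active-KAFO links and forearm
#: crutches, per side.  Inertia ``None`` means "slender rod about its CoM"
#: computed from the host-segment geometry at build time.
DEFAULT_DEVICE_PROPS = {
    "orthosis_thigh": {"mass": 1.5, "inertia": None},
    "orthosis_shank": {"mass": 1.3, "inertia": None},
    "crutch": {"mass": 0.8, "inertia": None},
}


# ---------------------------------------------------------------------------
# Declarative full-body topology
# ---------------------------------------------------------------------------

class TopologyError(ValueError):
    """Raised for malformed or inconsistent model schemas."""


@dataclass
class ModelTopology:
    """Declarative joint/DOF structure of the full-body model."""

    name: str
    joints: list  # (name, parent, child, [dof names])
    locked_dofs: list
    coordinate_index_map: dict  # dof name -> 1-based coordinate index

    @property
    def n_q(self) -> int:
        return len(self.coordinate_index_map)

    def unlocked_dofs(self) -> list:
        order = sorted(self.coordinate_index_map, key=self.coordinate_index_map.get)
        return order


def load_topology(schema_file) -> ModelTopology:
    """Load a declarative model topology from a YAML schema file.

    The shipped full-body schema has 31 unlocked coordinates with the six
    pelvis-ground DOFs first; ankle, subtalar and MTP DOFs are locked at
    0 deg by the orthosis.
    """
    path = Path(schema_file)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "joints" not in raw:
        raise TopologyError(f"{path}: schema must be a mapping with a 'joints' list")
    joints = []
    locked = []
    seen = set()
    index_map = {}
    idx = 1
    for j in raw["joints"]:
        try:
            name, parent, child = j["name"], j["parent"], j["child"]
            dofs = list(j["dofs"])
        except (KeyError, TypeError) as exc:
            raise TopologyError(
                f"{path}: malformed joint entry {j!r} (missing {exc})"
            ) from None
        jlocked = list(j.get("locked", []))
        for d in dofs:
            if d in seen:
                raise TopologyError(f"{path}: duplicate DOF name {d!r} (joint {name!r})")
            seen.add(d)
            if d in jlocked:
                locked.append(d)
            else:
                index_map[d] = idx
                idx += 1
        unknown = set(jlocked) - set(dofs)
        if unknown:
            raise TopologyError(
                f"{path}: joint {name!r} locks unknown DOFs {sorted(unknown)}"
            )
        joints.append((name, parent, child, dofs))
    return ModelTopology(
        name=raw.get("name", path.stem),
        joints=joints,
        locked_dofs=locked,
        coordinate_index_map=index_map,
    )


def default_topology_path() -> Path:
    """Path of the shipped full-body 31-DOF schema."""
    return Path(resources.files("kafogait").joinpath("data/fullbody_31dof.yaml"))


# ---------------------------------------------------------------------------
# Planar model
# ---------------------------------------------------------------------------

@dataclass
class SegmentParams:
    """Inertial and geometric parameters of one planar segment.

    ``attached_device_mass``/``attached_device_inertia`` hold the welded
    orthosis link or crutch merged into the host segment; the device CoM is
    taken to coincide with the segment CoM.
    """

    name: str
    mass: float            # kg, without device
    length: float          # m, proximal joint -> distal joint
    com_offset: float      # m from the proximal joint
    inertia_about_com: float  # kg m^2, without device
    attached_device_mass: float = 0.0
    attached_device_inertia: float = 0.0

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"segment {self.name!r}: mass must be > 0")
        if self.inertia_about_com < 0 or self.attached_device_inertia < 0:
            raise ValueError(f"segment {self.name!r}: inertia must be >= 0")
        if not 0.0 <= self.com_offset <= self.length + 1e-12:
            raise ValueError(
                f"segment {self.name!r}: com_offset must lie within [0, length]"
            )

    @property
    def total_mass(self) -> float:
        return self.mass + self.attached_device_mass

    @property
    def total_inertia(self) -> float:
        return self.inertia_about_com + self.attached_device_inertia


@dataclass
class PlanarState:
    """One instantaneous state of the planar model."""

    q: np.ndarray       # (12,) generalized coordinates, m / rad
    qdot: np.ndarray    # (12,)
    qddot: np.ndarray   # (12,)
    tau: np.ndarray     # (9,) joint torques for non-base DOFs, N m

    def __post_init__(self):
        for name, vec, n in (("q", self.q, 12), ("qdot", self.qdot, 12),
                             ("qddot", self.qddot, 12), ("tau", self.tau, 9)):
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"PlanarState.{name} must have shape ({n},)")
            setattr(self, name, arr)


# Kinematic tree of the planar model: parent segment index, attachment point
# in the parent frame (filled from the scaled lengths at build time), driving
# DOF index and sign (knee flexion positive bends the shank backwards).
_TREE = {
    #            parent, dof, sign
    "pelvis":    (-1, 2, +1),
    "torso":     (0, 3, +1),
    "thigh_r":   (0, 4, +1),
    "thigh_l":   (0, 5, +1),
    "shank_r":   (2, 6, -1),
    "shank_l":   (3, 7, -1),
    "upperarm_r": (1, 8, +1),
    "upperarm_l": (1, 9, +1),
    "forearm_r": (6, 10, +1),
    "forearm_l": (7, 11, +1),
}


def _rot(alpha, v):
    """Rotate constant local vector v=(x, y) by angle array alpha."""
    c, s = np.cos(alpha), np.sin(alpha)
    return c * v[0] - s * v[1], s * v[0] + c * v[1]


class PlanarModel:
    """Executable 12-DOF planar torque-driven model.

    Coordinates follow :data:`PLANAR_DOF_ORDER`; the first three form the
    floating base.  All heavy kernels broadcast over a leading node axis
    and accept complex dtype for complex-step differentiation.
    """

    dof_order = PLANAR_DOF_ORDER
    n_q = N_Q_PLANAR

    def __init__(self, segments: dict, *, gravity: float = GRAVITY,
                 anthropometry: dict | None = None,
                 length_fractions: dict | None = None):
        missing = [s for s in SEGMENT_ORDER if s not in segments]
        if missing:
            raise ValueError(f"missing segments: {missing}")
        self.segments = {s: segments[s] for s in SEGMENT_ORDER}
        self.gravity = float(gravity)
        self.anthropometry = dict(anthropometry or {})
        self.length_fractions = dict(length_fractions or LENGTH_FRACTIONS)
        self._build_arrays()
        self._build_points()

    # -- construction ------------------------------------------------------

    def _build_arrays(self):
        ns = len(SEGMENT_ORDER)
        self._parent = np.empty(ns, dtype=int)
        self._dof = np.empty(ns, dtype=int)
        self._sign = np.empty(ns)
        for i, name in enumerate(SEGMENT_ORDER):
            p, dof, sign = _TREE[name]
            self._parent[i] = p
            self._dof[i] = dof
            self._sign[i] = sign
        # angle selection matrix: alpha_s = ang_sel[s] @ q
        sel = np.zeros((ns, N_Q_PLANAR))
        for i in range(ns):
            p = self._parent[i]
            if p >= 0:
                sel[i] = sel[p]
            sel[i, self._dof[i]] += self._sign[i]
        self._ang_sel = sel
        # attachment point of each non-root segment in its parent frame
        segs = self.segments
        H = self.anthropometry.get("height", None)
        att = np.zeros((ns, 2))
        att[1] = (0.0, segs["pelvis"].length)          # torso at lumbar joint
        att[2] = att[3] = (0.0, 0.0)                   # thighs at hip centre
        att[4] = (0.0, -segs["thigh_r"].length)        # shanks at knees
        att[5] = (0.0, -segs["thigh_l"].length)
        att[6] = att[7] = (0.0, segs["torso"].length)  # shoulders at torso top
        att[8] = (0.0, -segs["upperarm_r"].length)     # forearms at elbows
        att[9] = (0.0, -segs["upperarm_l"].length)
        self._attach = att
        # CoM location in the segment frame
        com = np.zeros((ns, 2))
        up = {"pelvis", "torso"}
        for i, name in enumerate(SEGMENT_ORDER):
            off = segs[name].com_offset
            com[i] = (0.0, off if name in up else -off)
        self._com_loc = com
        self._mass = np.array([segs[s].total_mass for s in SEGMENT_ORDER])
        self._inertia = np.array([segs[s].total_inertia for s in SEGMENT_ORDER])
        if H is None:
            H = (segs["thigh_r"].length + segs["shank_r"].length) / (
                self.length_fractions["thigh"] + self.length_fractions["shank"])
        self._height = H

    def _build_points(self):
        """Register named material points (contact stations, tips, CoMs)."""
        lf = self.length_fractions
        H = self._height
        # the shank-foot segment spans knee -> sole plane (locked ankle)
        sole_y = -self.segments["shank_r"].length
        l_foot = lf["foot_length"] * H
        heel_x, toe_x = -0.25 * l_foot, 0.75 * l_foot
        xs = np.linspace(heel_x, toe_x, 8)
        l_fa = self.segments["forearm_r"].length
        tip_y = -(l_fa + lf["crutch_below_hand"] * H)

        names, seg_idx, loc = [], [], []

        def add(name, seg, xy):
            names.append(name)
            seg_idx.append(seg)
            loc.append(xy)

        for side, shank_i, fore_i in (("r", 4, 8), ("l", 5, 9)):
            for j, x in enumerate(np.repeat(xs, 2)):   # 8 stations x 2 lateral
                add(f"foot_{side}_e{j:02d}", shank_i, (x, sole_y))
            add(f"toe_{side}", shank_i, (toe_x, sole_y))
            add(f"heel_{side}", shank_i, (heel_x, sole_y))
            add(f"foot_mid_{side}", shank_i, (0.5 * (heel_x + toe_x), sole_y))
            add(f"crutch_tip_{side}", fore_i, (0.0, tip_y))
        for i, s in enumerate(SEGMENT_ORDER):
            add(f"com_{s}", i, tuple(self._com_loc[i]))

        self.point_names = names
        self._pt_seg = np.array(seg_idx, dtype=int)
        self._pt_loc = np.array(loc)
        self._pt_index = {n: i for i, n in enumerate(names)}
        self.foot_elements = {
            "r": [self._pt_index[f"foot_r_e{j:02d}"] for j in range(16)],
            "l": [self._pt_index[f"foot_l_e{j:02d}"] for j in range(16)],
        }
        self._seg_points = [np.nonzero(self._pt_seg == s)[0]
                            for s in range(len(SEGMENT_ORDER))]
        self.crutch_tips = {"r": self._pt_index["crutch_tip_r"],
                            "l": self._pt_index["crutch_tip_l"]}
        self.toe_points = {"r": self._pt_index["toe_r"], "l": self._pt_index["toe_l"]}
        self.foot_mid = {"r": self._pt_index["foot_mid_r"],
                         "l": self._pt_index["foot_mid_l"]}

    # -- kinematics --------------------------------------------------------

    def _check_q(self, q, name="q"):
        q = np.asarray(q)
        if q.shape[-1] != N_Q_PLANAR:
            raise ValueError(f"{name} must have trailing dimension {N_Q_PLANAR}, "
                             f"got shape {q.shape}")
        return q

    def segment_frames(self, q, qd=None, qdd=None):
        """Origin position/velocity/acceleration and angle/rate for all segments.

        Returns a dict of arrays with leading shape of ``q[..., 0]`` and a
        trailing segment axis (and xy axis for vectors).
        """
        q = self._check_q(q)
        alpha = q @ self._ang_sel.T                       # (..., ns)
        omega = (qd @ self._ang_sel.T) if qd is not None else None
        alphadd = (qdd @ self._ang_sel.T) if qdd is not None else None
        ns = len(SEGMENT_ORDER)
        base_shape = q.shape[:-1]
        dtype = np.result_type(q, qd if qd is not None else q)
        pos = np.zeros(base_shape + (ns, 2), dtype=q.dtype)
        pos[..., 0, 0] = q[..., 0]
        pos[..., 0, 1] = q[..., 1]
        vel = acc = None
        if qd is not None:
            vel = np.zeros(base_shape + (ns, 2), dtype=dtype)
            vel[..., 0, 0] = qd[..., 0]
            vel[..., 0, 1] = qd[..., 1]
        if qdd is not None:
            acc = np.zeros(base_shape + (ns, 2), dtype=np.result_type(dtype, qdd))
            acc[..., 0, 0] = qdd[..., 0]
            acc[..., 0, 1] = qdd[..., 1]
        for s in range(1, ns):
            p = self._parent[s]
            rx, ry = _rot(alpha[..., p], self._attach[s])
            pos[..., s, 0] = pos[..., p, 0] + rx
            pos[..., s, 1] = pos[..., p, 1] + ry
            if vel is not None:
                w = omega[..., p]
                vel[..., s, 0] = vel[..., p, 0] - w * ry
                vel[..., s, 1] = vel[..., p, 1] + w * rx
            if acc is not None:
                w = omega[..., p]
                a = alphadd[..., p]
                acc[..., s, 0] = acc[..., p, 0] - a * ry - w * w * rx
                acc[..., s, 1] = acc[..., p, 1] + a * rx - w * w * ry
        return {"alpha": alpha, "omega": omega, "alphadd": alphadd,
                "origin_pos": pos, "origin_vel": vel, "origin_acc": acc}

    def point_kinematics(self, q, qd=None, qdd=None, frames=None):
        """Position (and optional velocity/acceleration) of all registered points."""
        if frames is None:
            frames = self.segment_frames(q, qd, qdd)
        seg = self._pt_seg
        alpha = frames["alpha"][..., seg]
        c, s = np.cos(alpha), np.sin(alpha)
        lx, ly = self._pt_loc[:, 0], self._pt_loc[:, 1]
        rx = c * lx - s * ly
        ry = s * lx + c * ly
        out = {}
        pos = np.stack([frames["origin_pos"][..., seg, 0] + rx,
                        frames["origin_pos"][..., seg, 1] + ry], axis=-1)
        out["pos"] = pos
        if frames["omega"] is not None:
            w = frames["omega"][..., seg]
            vel = np.stack([frames["origin_vel"][..., seg, 0] - w * ry,
                            frames["origin_vel"][..., seg, 1] + w * rx], axis=-1)
            out["vel"] = vel
        if frames["alphadd"] is not None:
            w = frames["omega"][..., seg]
            a = frames["alphadd"][..., seg]
            acc = np.stack(
                [frames["origin_acc"][..., seg, 0] - a * ry - w * w * rx,
                 frames["origin_acc"][..., seg, 1] + a * rx - w * w * ry],
                axis=-1)
            out["acc"] = acc
        return out

    # -- dynamics ----------------------------------------------------------

    def generalized_forces(self, q, qd, qdd, ext_forces=None, gravity=True,
                           frames=None, pk=None, point_forces=None):
        """Required generalized forces g(q, qd, qdd) minus external-load terms.

        ``ext_forces`` maps registered point names to ground-frame force
        vectors with shape ``(..., 2)``; alternatively ``point_forces`` is
        an array ``(..., P, 2)`` of forces over all registered points
        (zeros where nothing acts), which is the fast path used by the
        optimal-control transcription.  The equations of motion read
        ``g[i] = tau_i`` for joint DOFs and ``g[0:3] = residual loads`` on
        the floating base.
        """
        q = self._check_q(q)
        qd = self._check_q(qd, "qdot")
        qdd = self._check_q(qdd, "qddot")
        if frames is None:
            frames = self.segment_frames(q, qd, qdd)
        if pk is None:
            pk = self.point_kinematics(q, qd, qdd, frames=frames)
        dtype = np.result_type(q, qd, qdd, np.float64)
        base_shape = q.shape[:-1]
        g = np.zeros(base_shape + (N_Q_PLANAR,), dtype=dtype)

        # inertial + gravitational wrench of each segment applied at its CoM
        com_idx = np.array([self._pt_index[f"com_{s}"] for s in SEGMENT_ORDER])
        com_pos = pk["pos"][..., com_idx, :]
        com_acc = pk["acc"][..., com_idx, :]
        w = self._mass[:, None] * com_acc
        if gravity:
            w = w + np.array([0.0, 1.0]) * (self._mass[:, None] * self.gravity)
        self._accumulate_jt(g, frames, np.arange(len(SEGMENT_ORDER)),
                            com_pos, w, sign=+1.0)
        # rotational inertia term: I_s * alphadd_s projected through ang_sel
        rot = self._inertia * frames["alphadd"]
        g += rot @ self._ang_sel

        if ext_forces:
            for name, f in ext_forces.items():
                if name not in self._pt_index:
                    raise ValueError(f"unknown load application point {name!r}")
                i = self._pt_index[name]
                f = np.asarray(f)
                pos = pk["pos"][..., i, :]
                self._accumulate_jt_single(g, frames, self._pt_seg[i], pos, f,
                                           sign=-1.0)
        if point_forces is not None:
            g -= self.point_force_generalized(frames, pk, point_forces)
        return g

    def point_force_generalized(self, frames, pk, forces):
        """J^T mapping of ground-frame forces at all registered points.

        ``forces`` has shape ``(..., P, 2)``; forces on the same segment are
        reduced to a resultant + moment before projection, which keeps the
        cost proportional to the segment count.
        """
        pos = pk["pos"]
        opos = frames["origin_pos"]
        base_shape = np.broadcast(pos[..., 0, 0], forces[..., 0, 0]).shape
        g = np.zeros(base_shape + (N_Q_PLANAR,),
                     dtype=np.result_type(pos, forces))
        g[..., 0] = forces[..., 0].sum(-1)
        g[..., 1] = forces[..., 1].sum(-1)
        for s, pts in enumerate(self._seg_points):
            if len(pts) == 0:
                continue
            sel = self._ang_sel[s]
            nz = np.nonzero(sel)[0]
            f = forces[..., pts, :]
            W = (f[..., 0].sum(-1), f[..., 1].sum(-1))
            C = (pos[..., pts, 0] * f[..., 1]
                 - pos[..., pts, 1] * f[..., 0]).sum(-1)
            for j in nz:
                dseg = self._dof_segment[j]
                ox = opos[..., dseg, 0]
                oy = opos[..., dseg, 1]
                g[..., j] += sel[j] * (C - (ox * W[1] - oy * W[0]))
        return g

    def _accumulate_jt(self, g, frames, seg_indices, pos, w, sign):
        """g += sign * J_p^T w for a batch of points (one per segment index)."""
        for k, s in enumerate(seg_indices):
            self._accumulate_jt_single(g, frames, s, pos[..., k, :], w[..., k, :],
                                       sign)

    def _accumulate_jt_single(self, g, frames, seg, pos, w, sign):
        g[..., 0] += sign * w[..., 0]
        g[..., 1] += sign * w[..., 1]
        sel = self._ang_sel[seg]           # (12,)
        opos = frames["origin_pos"]
        for j in np.nonzero(sel)[0]:
            # DOF j drives segment dseg; its pivot is that segment's origin
            dseg = self._dof_segment[j]
            ox = opos[..., dseg, 0]
            oy = opos[..., dseg, 1]
            cross = (pos[..., 0] - ox) * w[..., 1] - (pos[..., 1] - oy) * w[..., 0]
            g[..., j] += sign * sel[j] * cross

    @property
    def _dof_segment(self):
        # DOF index -> segment whose origin is the pivot of that DOF
        try:
            return self.__dof_segment
        except AttributeError:
            m = {2: 0, 3: 1, 4: 2, 5: 3, 6: 4, 7: 5, 8: 6, 9: 7, 10: 8, 11: 9}
            self.__dof_segment = m
            return m

    def mass_matrix(self, q):
        """Joint-space mass matrix via unit-acceleration inverse dynamics."""
        q = np.asarray(q, dtype=float)
        z = np.zeros(N_Q_PLANAR)
        M = np.empty((N_Q_PLANAR, N_Q_PLANAR))
        for i in range(N_Q_PLANAR):
            e = np.zeros(N_Q_PLANAR)
            e[i] = 1.0
            M[:, i] = self.generalized_forces(q, z, e, gravity=False)
        return M

    def kinetic_energy(self, q, qd):
        frames = self.segment_frames(np.asarray(q), np.asarray(qd))
        pk = self.point_kinematics(q, qd, frames=frames)
        com_idx = np.array([self._pt_index[f"com_{s}"] for s in SEGMENT_ORDER])
        v = pk["vel"][..., com_idx, :]
        w = frames["omega"]
        return (0.5 * self._mass * (v ** 2).sum(-1)).sum(-1) \
            + (0.5 * self._inertia * w ** 2).sum(-1)

    @property
    def total_mass(self) -> float:
        return float(self._mass.sum())

    # -- serialization -----------------------------------------------------

    def segment_table(self) -> pd.DataFrame:
        rows = []
        for s in SEGMENT_ORDER:
            p = self.segments[s]
            rows.append({"segment": s, "mass_kg": p.total_mass,
                         "length_m": p.length, "com_offset_m": p.com_offset,
                         "inertia_kgm2": p.total_inertia})
        return pd.DataFrame(rows)

    def to_yaml(self, path):
        data = {
            "dof_order": list(self.dof_order),
            "gravity": self.gravity,
            "anthropometry": self.anthropometry,
            "length_fractions": self.length_fractions,
            "segments": {
                s: {"mass": p.mass, "length": p.length,
                    "com_offset": p.com_offset,
                    "inertia_about_com": p.inertia_about_com,
                    "attached_device_mass": p.attached_device_mass,
                    "attached_device_inertia": p.attached_device_inertia}
                for s, p in self.segments.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PlanarModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        segs = {s: SegmentParams(name=s, **p) for s, p in data["segments"].items()}
        return cls(segs, gravity=data.get("gravity", GRAVITY),
                   anthropometry=data.get("anthropometry"),
                   length_fractions=data.get("length_fractions"))


def build_planar_model(anthropometry: dict, device_props: dict | None = None,
                       *, gravity: float = GRAVITY,
                       fractions: dict | None = None) -> PlanarModel:
    """Scale the planar model to a subject.

    Segment lengths scale with height and masses with subject mass using
    the published anthropometric fractions above; welded device masses and
    inertias (orthosis thigh/shank links, crutches) are merged into their
    host segments, so the model total mass is subject mass + device masses.
    """
    mass = float(anthropometry["mass"])
    height = float(anthropometry["height"])
    if mass <= 0 or height <= 0:
        raise ValueError("anthropometry mass and height must be > 0")
    lf = dict(LENGTH_FRACTIONS)
    if fractions:
        lf.update(fractions)
    devices = {k: dict(v) for k, v in DEFAULT_DEVICE_PROPS.items()}
    if device_props:
        for k, v in device_props.items():
            devices.setdefault(k, {}).update(v)

    def rod_inertia(m, length):
        return m * length ** 2 / 12.0

    seg_len = {
        "pelvis": lf["pelvis"] * height,
        "torso": lf["torso"] * height,
        "thigh": lf["thigh"] * height,
        "shank": lf["shank"] * height + lf["foot_height"] * height,
        "upperarm": lf["upperarm"] * height,
        "forearm": lf["forearm"] * height,
    }
    crutch_len = (lf["forearm"] + lf["crutch_below_hand"]) * height

    device_for = {
        "thigh": ("orthosis_thigh", seg_len["thigh"]),
        "shank": ("orthosis_shank", seg_len["shank"]),
        "forearm": ("crutch", crutch_len),
    }
    segments = {}
    for name in SEGMENT_ORDER:
        base = name.rsplit("_", 1)[0] if name not in ("pelvis", "torso") else name
        L = seg_len[base]
        m = MASS_FRACTIONS[base] * mass
        com = COM_FRACTIONS[base] * L
        inertia = m * (GYRATION_FRACTIONS[base] * L) ** 2
        dmass = dinertia = 0.0
        if base in device_for:
            key, dlen = device_for[base]
            dmass = float(devices[key]["mass"])
            dinertia = devices[key]["inertia"]
            if dinertia is None:
                dinertia = rod_inertia(dmass, dlen)
            dinertia = float(dinertia)
        segments[name] = SegmentParams(
            name=name, mass=m, length=L, com_offset=com,
            inertia_about_com=inertia, attached_device_mass=dmass,
            attached_device_inertia=dinertia)
    return PlanarModel(segments, gravity=gravity,
                       anthropometry={"mass": mass, "height": height},
                       length_fractions=lf)


# ---------------------------------------------------------------------------
# Spec-surface wrappers
# ---------------------------------------------------------------------------

def forward_kinematics(model: PlanarModel, q, qdot):
    """Point kinematics {position, velocity} for every registered point.

    Covers contact stations, crutch tips, toe points and segment CoMs.
    """
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    if q.shape != (N_Q_PLANAR,) or qdot.shape != (N_Q_PLANAR,):
        raise ValueError(f"q and qdot must have shape ({N_Q_PLANAR},)")
    pk = model.point_kinematics(q, qdot)
    return {name: {"position": pk["pos"][i], "velocity": pk["vel"][i]}
            for i, name in enumerate(model.point_names)}


def inverse_dynamics(model: PlanarModel, q, qdot, qddot, external_loads=None):
    """Generalized forces and floating-base residual loads.

    ``external_loads`` maps registered point names to ground-frame forces
    (N).  Returns the 9 joint generalized forces (N m) and the 3 residual
    loads on the base (N, N, N m); the output is affine in ``qddot`` and
    vanishes identically for a zero state with gravity off and no loads.
    """
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    qddot = np.asarray(qddot, dtype=float)
    for name, v in (("q", q), ("qdot", qdot), ("qddot", qddot)):
        if v.shape != (N_Q_PLANAR,):
            raise ValueError(f"{name} must have shape ({N_Q_PLANAR},)")
    g = model.generalized_forces(q, qdot, qddot, ext_forces=external_loads)
    return {"joint_generalized_forces": g[N_BASE:],
            "residual_loads": g[:N_BASE]}
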