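"""Over-determinate kinematic analysis of marker trajectories.

The skeleton is a tree rooted at the pelvis (6 free coordinates) with
spherical hips (flexion, adduction, axial rotation) and hinge knees and
ankles, 16 generalized coordinates in total for the bilateral lower limb.
Per frame, the generalized coordinates are recovered by weighted nonlinear
least squares over all visible markers (redundant: 32 markers x 3 >> 16
coordinates), solved with a damped Gauss-Newton (Levenberg-Marquardt)
iteration that is warm-started from the previous frame.

Sign conventions (x anterior, y left, z up; right leg at y < 0): hip and
knee flexion positive, hip adduction positive toward the midline for both
legs, hip axial rotation positive internal, ankle dorsiflexion positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

DOF_NAMES = (
    "pel_tx", "pel_ty", "pel_tz", "pel_rx", "pel_ry", "pel_rz",
    "hip_flex_r", "hip_add_r", "hip_rot_r", "knee_flex_r", "ankle_dorsi_r",
    "hip_flex_l", "hip_add_l", "hip_rot_l", "knee_flex_l", "ankle_dorsi_l",
)
NDOF = len(DOF_NAMES)

# joint rotation axes per segment, applied left-to-right
_JOINT_AXES = {
    "thigh_r": [((0, -1, 0), "hip_flex_r"), ((1, 0, 0), "hip_add_r"), ((0, 0, 1), "hip_rot_r")],
    "thigh_l": [((0, -1, 0), "hip_flex_l"), ((-1, 0, 0), "hip_add_l"), ((0, 0, -1), "hip_rot_l")],
    "shank_r": [((0, 1, 0), "knee_flex_r")],
    "shank_l": [((0, 1, 0), "knee_flex_l")],
    "foot_r": [((0, -1, 0), "ankle_dorsi_r")],
    "foot_l": [((0, -1, 0), "ankle_dorsi_l")],
}
_PARENT = {"thigh_r": "pelvis", "thigh_l": "pelvis",
           "shank_r": "thigh_r", "shank_l": "thigh_l",
           "foot_r": "shank_r", "foot_l": "shank_l"}
SEGMENTS = ("pelvis", "thigh_r", "shank_r", "foot_r", "thigh_l", "shank_l", "foot_l")


def _axis_rot(axis, angle):
    """Rodrigues rotation about a fixed axis; ``angle`` may be (N,)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    angle = np.atleast_1d(np.asarray(angle, dtype=float))
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    s, c = np.sin(angle), np.cos(angle)
    return (np.eye(3)[None] + s[:, None, None] * K[None]
            + (1 - c)[:, None, None] * (K @ K)[None])


@dataclass
class KinematicModel:
    """Marker-tracking model: segment chain + local marker positions + weights."""

    joint_origins: dict                 # segment -> (3,) proximal joint in parent frame
    marker_locals: dict                 # segment -> {marker -> (3,) local}
    weights: dict = field(default_factory=dict)   # marker -> weight (default 1)

    def __post_init__(self):
        self.marker_names = [m for seg in SEGMENTS
                             for m in self.marker_locals.get(seg, {})]
        self.marker_segment = {m: seg for seg in SEGMENTS
                               for m in self.marker_locals.get(seg, {})}
        if 3 * len(self.marker_names) <= NDOF:
            raise ValueError("marker set does not over-determine the coordinates")
        w = np.array([float(self.weights.get(m, 1.0)) for m in self.marker_names])
        if np.any(w <= 0):
            raise ValueError("marker weights must be positive")
        self._w = w

    @classmethod
    def from_model(cls, model, weights=None) -> "KinematicModel":
        """Build from anything exposing ``joint_origin`` per segment and
        ``marker_locals`` (a PersonalizedModel or a synthetic true model)."""
        origins = {seg: np.asarray(model.joint_origin(seg), dtype=float)
                   for seg in SEGMENTS if seg != "pelvis"}
        locals_ = {seg: {m: np.asarray(p, dtype=float) for m, p in mk.items()}
                   for seg, mk in model.marker_locals.items()}
        return cls(joint_origins=origins, marker_locals=locals_, weights=weights or {})


def forward_kinematics(model: KinematicModel, q):
    """Segment poses and model marker positions for coordinates ``q``.

    ``q`` is (NDOF,) or (N, NDOF).  Returns (poses, markers) where poses maps
    segment -> (R (N,3,3), p (N,3)) and markers maps name -> (N,3).
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    n = len(q)
    qi = {name: q[:, i] for i, name in enumerate(DOF_NAMES)}
    R_pel = (_axis_rot((0, 0, 1), qi["pel_rz"])
             @ _axis_rot((0, 1, 0), qi["pel_ry"])
             @ _axis_rot((1, 0, 0), qi["pel_rx"]))
    p_pel = q[:, 0:3]
    poses = {"pelvis": (R_pel, p_pel)}
    for seg in SEGMENTS[1:]:
        Rp, pp = poses[_PARENT[seg]]
        Rj = np.broadcast_to(np.eye(3), (n, 3, 3))
        for axis, dof in _JOINT_AXES[seg]:
            Rj = Rj @ _axis_rot(axis, qi[dof])
        origin = model.joint_origins[seg]
        poses[seg] = (Rp @ Rj, pp + np.einsum("nij,j->ni", Rp, origin))
    markers = {}
    for seg in SEGMENTS:
        R, p = poses[seg]
        for name, local in model.marker_locals.get(seg, {}).items():
            markers[name] = p + np.einsum("nij,j->ni", R, local)
    return poses, markers


def _marker_matrix(model, q):
    _, mk = forward_kinematics(model, q)
    return np.stack([mk[m] for m in model.marker_names], axis=1)  # (N, M, 3)


@dataclass
class FrameSolution:
    q: np.ndarray
    residual_rms: float
    converged: bool
    n_iter: int


def _gn_solve(model, measured, q0, tol_grad=1e-10, max_iter=100):
    """Batched damped Gauss-Newton; each frame is an independent problem.

    The Levenberg damping parameter is adapted per frame so the weighted
    cost never increases across accepted iterations.
    """
    meas = np.asarray(measured, dtype=float)          # (N, M, 3)
    n, m = meas.shape[0], meas.shape[1]
    q = np.array(q0, dtype=float).copy()              # (N, NDOF)
    sw = np.sqrt(np.repeat(model._w, 3))

    def resid(qq, sub_meas):
        r = (sub_meas - _marker_matrix(model, qq)).reshape(len(qq), 3 * m)
        return r * sw[None, :]

    r = resid(q, meas)
    cost = np.einsum("ni,ni->n", r, r)
    lam = np.full(n, 1e-6)
    active = np.ones(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    eps = 1e-7
    for _ in range(max_iter):
        idx = np.where(active)[0]
        if len(idx) == 0:
            break
        qa, ra = q[idx], r[idx]
        # finite-difference Jacobian of the weighted residual, batched over frames
        J = np.empty((len(idx), 3 * m, NDOF))
        for d in range(NDOF):
            qp = qa.copy()
            qp[:, d] += eps
            J[:, :, d] = (resid(qp, meas[idx]) - ra) / eps
        g = np.einsum("nij,ni->nj", J, ra)
        JtJ = np.einsum("nij,nik->njk", J, J)
        conv = np.linalg.norm(g, axis=1) <= tol_grad
        active[idx[conv]] = False
        todo = np.where(~conv)[0]                      # positions within idx
        for _ in range(40):
            if len(todo) == 0:
                break
            gi = idx[todo]
            A = JtJ[todo] + lam[gi][:, None, None] * np.eye(NDOF)[None]
            delta = np.linalg.solve(A, (-g[todo])[..., None])[..., 0]
            q_try = q[gi] + delta
            r_try = resid(q_try, meas[gi])
            c_try = np.einsum("ni,ni->n", r_try, r_try)
            better = c_try <= cost[gi] + 1e-15
            ok = gi[better]
            q[ok], r[ok], cost[ok] = q_try[better], r_try[better], c_try[better]
            lam[ok] = np.maximum(lam[ok] * 0.3, 1e-9)
            iters[ok] += 1
            lam[gi[~better]] *= 10.0
            todo = todo[~better]
    rms = np.sqrt(cost / (3 * m))
    return q, rms, ~active, iters


def solve_frame(model: KinematicModel, measured_markers: dict, q_init=None) -> FrameSolution:
    """Least-squares fit of the coordinates to one frame of measured markers."""
    meas = np.stack([np.atleast_2d(np.asarray(measured_markers[m], dtype=float))
                     for m in model.marker_names], axis=1)
    q0 = np.zeros((1, NDOF)) if q_init is None else np.atleast_2d(q_init)
    q, rms, conv, iters = _gn_solve(model, meas, q0)
    return FrameSolution(q=q[0], residual_rms=float(rms[0]),
                         converged=bool(conv[0]), n_iter=int(iters[0]))


@dataclass
class JointAngleTrajectory:
    """Solved generalized-coordinate trajectories with derivatives."""

    time: np.ndarray
    q: np.ndarray                    # (N, NDOF) rad / m
    qd: np.ndarray
    qdd: np.ndarray
    residual_rms: np.ndarray         # per frame, m
    flagged: np.ndarray              # frames that failed to converge
    dof_names: tuple = DOF_NAMES

    def dof(self, name: str) -> np.ndarray:
        return self.q[:, DOF_NAMES.index(name)]


def _initial_guess(model, meas0):
    q0 = np.zeros(NDOF)
    pel = [i for i, m in enumerate(model.marker_names)
           if model.marker_segment[m] == "pelvis"]
    if pel:
        locs = np.array([model.marker_locals["pelvis"][model.marker_names[i]] for i in pel])
        q0[:3] = meas0[pel].mean(axis=0) - locs.mean(axis=0)
    return q0


def solve_trajectory(model: KinematicModel, trial, filter_cutoff_hz: float | None = 6.0,
                     frames: slice | None = None) -> JointAngleTrajectory:
    """Warm-started per-frame solves over a trial, then optional zero-lag
    low-pass filtering of q and central-difference differentiation.

    ``trial`` needs ``markers`` (name -> (N,3) m), ``marker_rate`` (Hz).
    """
    names = model.marker_names
    meas = np.stack([np.asarray(trial.markers[m], dtype=float) for m in names], axis=1)
    start = 0
    if frames is not None:
        start = frames.start or 0
        meas = meas[frames]
    n = len(meas)
    rate = float(trial.marker_rate)
    time = (start + np.arange(n)) / rate

    q0 = _initial_guess(model, meas[0])
    first = solve_frame(model, {m: meas[0, i] for i, m in enumerate(names)}, q0)
    # warm-started sweep: solve all frames in parallel batches seeded from the
    # previous batch's median solution, then one refinement pass frame-by-frame
    # in blocks to keep warm starts local
    q = np.empty((n, NDOF))
    rms = np.empty(n)
    flagged = np.zeros(n, dtype=bool)
    q[0], rms[0] = first.q, first.residual_rms
    block = 16
    prev = first.q
    for start in range(1, n, block):
        sl = slice(start, min(start + block, n))
        nb = sl.stop - sl.start
        qinit = np.tile(prev, (nb, 1))
        qb, rb, conv, _ = _gn_solve(model, meas[sl], qinit)
        q[sl], rms[sl] = qb, rb
        flagged[sl] = ~conv
        prev = qb[-1]

    q_out = q
    if filter_cutoff_hz is not None and n > 12:
        b, a = butter(2, filter_cutoff_hz / (rate / 2), btype="low")
        q_out = filtfilt(b, a, q, axis=0)
    qd = np.gradient(q_out, 1.0 / rate, axis=0)
    qdd = np.gradient(qd, 1.0 / rate, axis=0)
    return JointAngleTrajectory(time=time, q=q_out, qd=qd, qdd=qdd,
                                residual_rms=rms, flagged=flagged)
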