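"""Inverse dynamics and static-optimization muscle recruitment.

Per analyzed frame, the Newton-Euler equations of the tested-side chain
(pelvis with lumped head-arms-trunk, thigh, shank, foot) are assembled into
a linear equilibrium system C f = d whose unknowns f are the muscle tensions,
the joint constraint forces/moments and six pelvis residual actuators; d
carries inertia forces, gravity and the measured ground reaction.  Muscle
tensions are bounded below by zero (muscles pull, never push) and above by
the personalized instantaneous strength N_i, and the redundancy is resolved
by minimizing the volume-weighted cubic cost

    G = sum_i v_i (f_i / N_i)^3

subject to C f = d.  The pelvis residual actuators absorb the dynamic
inconsistency between prescribed kinematics and measured (or synthetic)
ground reactions; a high quadratic penalty keeps them minimal, and their
magnitudes are reported so the inconsistency is visible.

The hip is spherical (transmits force only), knee and ankle are hinges
(transmit force plus the two moment components orthogonal to the hinge
axis).  The knee constraint force is the total tibiofemoral contact force;
the constraint moment component about the tibial anterior-posterior axis is
the ab/adduction moment used for medial/lateral force decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import kinematics as kin
from .template import MASS_FRACTIONS, PELVIS_HAT_FRACTION

GRAVITY = np.array([0.0, 0.0, -9.81])


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


@dataclass
class EquilibriumSystem:
    """One frame's linear equilibrium: C f = d."""

    C: np.ndarray
    d: np.ndarray
    n_M: int
    column_names: list
    row_names: list

    def __post_init__(self):
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite right-hand side")
        if self.C.shape != (len(self.row_names), len(self.column_names)):
            raise ValueError("system shape inconsistent with metadata")


@dataclass
class MuscleForceSolution:
    f: np.ndarray
    G: float
    utilization: np.ndarray
    joint_forces: dict           # joint -> (3,) world N (parent-on-child)
    joint_moments: dict          # joint -> (3,) world N*m (constraint moment)
    residuals: np.ndarray        # (6,) pelvis residual force+moment
    converged: bool
    column_names: list


def solve_recruitment(system: EquilibriumSystem, muscles, p: int = 3,
                      residual_weight: float = 1e3,
                      residual_scale: float = 700.0,
                      x0: np.ndarray | None = None,
                      tol: float = 1e-9) -> np.ndarray:
    """Minimize the cubic recruitment cost subject to C f = d and bounds.

    ``muscles`` is the list of MuscleUnit (with ``strength`` set) matching
    the first ``n_M`` columns.  Residual-actuator columns (names starting
    with ``res_``) carry a quadratic penalty ``residual_weight * (r/scale)^2``.
    Returns the full unknown vector f.  The cubic cost is convex on the
    feasible set (f_i >= 0), so the muscle solution is unique.
    """
    C, d, nm = system.C, system.d, system.n_M
    ncol = C.shape[1]
    if len(muscles) != nm:
        raise ValueError("muscle list does not match system metadata")
    N = np.array([mu.strength if mu.strength is not None else mu.template_strength
                  for mu in muscles])
    v = np.array([mu.volume_factor for mu in muscles])
    if p != 3:
        raise NotImplementedError("recruitment cost implemented for p = 3")
    res_cols = np.array([c.startswith("res_") for c in system.column_names])
    wr = residual_weight / residual_scale ** 2

    # variable scaling: muscles in utilization units, the rest in units of
    # the residual scale (body weight); rows normalized for conditioning
    col_scale = np.concatenate([N, np.full(ncol - nm, residual_scale)])
    Cs = C * col_scale[None, :]
    row_scale = np.linalg.norm(Cs, axis=1)
    row_scale[row_scale == 0] = 1.0
    Cs = Cs / row_scale[:, None]
    ds = d / row_scale
    wr_u = wr * residual_scale ** 2          # penalty in scaled units

    def cost(u):
        um = u[:nm]
        g = float(np.sum(v * um ** 3)) + wr_u * float(np.sum(u[res_cols] ** 2))
        grad = np.zeros(ncol)
        grad[:nm] = 3 * v * um ** 2
        grad[res_cols] += 2 * wr_u * u[res_cols]
        return g, grad

    bounds = [(0.0, 1.0)] * nm + [(None, None)] * (ncol - nm)
    u0 = None
    if x0 is not None:
        # project the warm start onto the new frame's equality manifold
        u0 = np.asarray(x0, dtype=float) / col_scale
        gap = ds - Cs @ u0
        try:
            u0 = u0 + Cs.T @ np.linalg.solve(Cs @ Cs.T, gap)
        except np.linalg.LinAlgError:
            u0 = None
        if u0 is not None:
            u0[:nm] = np.clip(u0[:nm], 0.0, 1.0)
            if np.abs(Cs @ u0 - ds).max() > 1e-4:
                u0 = None
    def lp_start():
        # phase-1 feasible start: minimize total utilization subject to the
        # equality rows and bounds (linear program)
        from scipy.optimize import linprog
        cvec = np.zeros(ncol)
        cvec[:nm] = 1.0
        lp = linprog(cvec, A_eq=Cs, b_eq=ds,
                     bounds=[(0, 1)] * nm + [(None, None)] * (ncol - nm),
                     method="highs")
        if not lp.success:
            raise RuntimeError(
                f"recruitment infeasible: no admissible muscle forces "
                f"({lp.message})")
        return lp.x

    cons = {"type": "eq", "fun": lambda u: Cs @ u - ds, "jac": lambda u: Cs}

    def solve_from(uinit):
        res = minimize(cost, uinit, jac=True, bounds=bounds, constraints=[cons],
                       method="SLSQP", options={"maxiter": 400, "ftol": tol})
        return res.x, np.abs(Cs @ res.x - ds).max()

    if u0 is None:
        u0 = lp_start()
        u, viol = solve_from(u0)
    else:
        u, viol = solve_from(u0)
        if viol > 1e-6:
            u, viol = solve_from(lp_start())
    if viol > 1e-6:
        raise RuntimeError(
            f"recruitment solver failed: scaled constraint violation {viol:.3g} "
            f"(worst row {system.row_names[int(np.argmax(np.abs(Cs @ u - ds)))]})")
    u[:nm] = np.clip(u[:nm], 0.0, 1.0)
    return u * col_scale


class InverseDynamics:
    """Assembles and solves the tested-side equilibrium over a trial."""

    def __init__(self, model, side: str | None = None,
                 residual_weight: float = 1e3, mode: str = "muscle"):
        self.model = model
        self.side = (side or model.tested_leg).lower()
        s = self.side
        self.segments = ["pelvis", f"thigh_{s}", f"shank_{s}", f"foot_{s}"]
        self.mode = mode
        self.residual_weight = residual_weight
        self.muscles = [mu for mu in model.muscles if mu.name.endswith(f"_{s}")] \
            if mode == "muscle" else []
        L = model.segment_lengths
        sgn = -1.0 if s == "r" else 1.0
        m = model.mass
        self.mass = {
            "pelvis": PELVIS_HAT_FRACTION * m,
            f"thigh_{s}": MASS_FRACTIONS["thigh"] * m,
            f"shank_{s}": MASS_FRACTIONS["shank"] * m,
            f"foot_{s}": MASS_FRACTIONS["foot"] * m,
        }
        self.com_local = {
            "pelvis": np.array([-0.02, 0.0, 0.28]),
            f"thigh_{s}": np.array([0.0, 0.0, -0.41 * L["thigh"]]),
            f"shank_{s}": np.array([0.0, 0.0, -0.44 * L["shank"]]),
            f"foot_{s}": np.array([0.05, 0.0, -0.05]),
        }
        self.inertia_local = {}
        for seg in self.segments:
            mseg = self.mass[seg]
            if seg == "pelvis":
                I = mseg * 0.30 ** 2 * np.ones(3)
            elif seg.startswith("thigh"):
                I = mseg * np.array([(0.323 * L["thigh"]) ** 2,
                                     (0.323 * L["thigh"]) ** 2, 0.05 ** 2])
            elif seg.startswith("shank"):
                I = mseg * np.array([(0.302 * L["shank"]) ** 2,
                                     (0.302 * L["shank"]) ** 2, 0.04 ** 2])
            else:
                I = mseg * np.array([0.02 ** 2, (0.25 * L["foot"]) ** 2,
                                     (0.25 * L["foot"]) ** 2])
            self.inertia_local[seg] = np.diag(I)
        # joint attachment points in parent/child local frames
        self.joints = {
            "hip": ("pelvis", np.array([0.0, sgn * L["pelvis_width"] / 2, 0.0]),
                    f"thigh_{s}", np.zeros(3)),
            "knee": (f"thigh_{s}", np.array([0.0, 0.0, -L["thigh"]]),
                     f"shank_{s}", np.zeros(3)),
            "ankle": (f"shank_{s}", np.array([0.0, 0.0, -L["shank"]]),
                      f"foot_{s}", np.zeros(3)),
        }
        self.hinge_axis = {"knee": np.array([0.0, 1.0, 0.0]),
                           "ankle": np.array([0.0, -1.0, 0.0])}

    # ------------------------------------------------------------------
    def segment_kinematics(self, km: kin.KinematicModel, q_traj: np.ndarray,
                           rate: float):
        """World poses, CoM accelerations and angular velocity/acceleration."""
        poses, _ = kin.forward_kinematics(km, q_traj)
        dt = 1.0 / rate
        out = {}
        for seg in self.segments:
            R, pp = poses[seg]
            com = pp + np.einsum("nij,j->ni", R, self.com_local[seg])
            vel = np.gradient(com, dt, axis=0)
            acc = np.gradient(vel, dt, axis=0)
            Rd = np.gradient(R, dt, axis=0)
            what = Rd @ np.transpose(R, (0, 2, 1))
            w = np.stack([what[:, 2, 1], what[:, 0, 2], what[:, 1, 0]], axis=1)
            alpha = np.gradient(w, dt, axis=0)
            out[seg] = {"R": R, "p": pp, "com": com, "acc": acc,
                        "omega": w, "alpha": alpha}
        return poses, out

    # ------------------------------------------------------------------
    def _columns(self):
        names = [mu.name for mu in self.muscles]
        for j in ("hip", "knee", "ankle"):
            names += [f"{j}_F{ax}" for ax in "xyz"]
            if self.mode == "torque":
                names += [f"{j}_M{k}" for k in range(3)]
            elif j in ("knee", "ankle"):
                names += [f"{j}_M{k}" for k in range(2)]
        names += [f"res_F{ax}" for ax in "xyz"] + [f"res_M{ax}" for ax in "xyz"]
        return names

    def assemble_frame(self, seg_kin: dict, grf_force, grf_cop, grf_tz,
                       frame: int) -> EquilibriumSystem:
        """Build C f = d for one frame."""
        segs = self.segments
        rows = []
        for seg in segs:
            rows += [f"{seg}_F{ax}" for ax in "xyz"] + [f"{seg}_M{ax}" for ax in "xyz"]
        col_names = self._columns()
        ncol = len(col_names)
        nrow = len(rows)
        C = np.zeros((nrow, ncol))
        d = np.zeros(nrow)
        row_of = {seg: 6 * i for i, seg in enumerate(segs)}
        col_of = {c: i for i, c in enumerate(col_names)}

        com = {seg: seg_kin[seg]["com"][frame] for seg in segs}
        R = {seg: seg_kin[seg]["R"][frame] for seg in segs}
        p = {seg: seg_kin[seg]["p"][frame] for seg in segs}

        # RHS: inertia minus gravity, minus applied external loads
        for seg in segs:
            m = self.mass[seg]
            i0 = row_of[seg]
            d[i0:i0 + 3] = m * seg_kin[seg]["acc"][frame] - m * GRAVITY
            Iw = R[seg] @ self.inertia_local[seg] @ R[seg].T
            w = seg_kin[seg]["omega"][frame]
            d[i0 + 3:i0 + 6] = Iw @ seg_kin[seg]["alpha"][frame] + np.cross(w, Iw @ w)
        foot = segs[3]
        if grf_force is not None:
            F = np.asarray(grf_force, dtype=float)
            cop = np.asarray(grf_cop, dtype=float)
            i0 = row_of[foot]
            d[i0:i0 + 3] -= F
            d[i0 + 3:i0 + 6] -= np.cross(cop - com[foot], F)
            d[i0 + 5] -= float(grf_tz)

        def add_force(col, seg, point_world, direction_world, sign=1.0):
            i0 = row_of[seg]
            C[i0:i0 + 3, col] += sign * direction_world
            C[i0 + 3:i0 + 6, col] += sign * np.cross(point_world - com[seg],
                                                     direction_world)

        # joint constraint forces/moments
        for jname, (par, ploc, child, cloc) in self.joints.items():
            jpos = p[par] + R[par] @ ploc
            for k, ax in enumerate("xyz"):
                e = np.eye(3)[k]
                col = col_of[f"{jname}_F{ax}"]
                add_force(col, child, jpos, e, +1.0)
                add_force(col, par, jpos, e, -1.0)
            if self.mode == "torque":
                basis = np.eye(3)
            elif jname in self.hinge_axis:
                axis_w = R[child] @ self.hinge_axis[jname]
                ref = np.eye(3)[0] if abs(axis_w[0]) < 0.9 else np.eye(3)[2]
                e1 = np.cross(axis_w, ref)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(axis_w, e1)
                basis = np.stack([e1, e2])
            else:
                basis = None
            if basis is not None:
                for k, e in enumerate(basis):
                    col = col_of[f"{jname}_M{k}"]
                    i0c, i0p = row_of[child], row_of[par]
                    C[i0c + 3:i0c + 6, col] += e
                    C[i0p + 3:i0p + 6, col] -= e

        # muscle columns: unit-tension path forces on owning segments
        for mi, mu in enumerate(self.muscles):
            path = self.model.attachments[mu.name]
            pts = [p[seg] + R[seg] @ np.asarray(loc) for seg, loc in path]
            owners = [seg for seg, _ in path]
            for j, (pt, owner) in enumerate(zip(pts, owners)):
                if owner not in row_of:
                    continue
                pull = np.zeros(3)
                if j + 1 < len(pts):
                    u = pts[j + 1] - pt
                    pull += u / np.linalg.norm(u)
                if j - 1 >= 0:
                    u = pts[j - 1] - pt
                    pull += u / np.linalg.norm(u)
                add_force(mi, owner, pt, pull, +1.0)

        # pelvis residual actuators
        for k, ax in enumerate("xyz"):
            i0 = row_of["pelvis"]
            C[i0 + k, col_of[f"res_F{ax}"]] = 1.0
            C[i0 + 3 + k, col_of[f"res_M{ax}"]] = 1.0
        return EquilibriumSystem(C=C, d=d, n_M=len(self.muscles),
                                 column_names=col_names, row_names=rows)

    # ------------------------------------------------------------------
    def run(self, km: kin.KinematicModel, traj: kin.JointAngleTrajectory,
            trial, frames: np.ndarray) -> dict:
        """Solve recruitment over the given marker-frame indices."""
        poses, seg_kin = self.segment_kinematics(km, traj.q, 1.0 / (traj.time[1] - traj.time[0]))
        tf = np.arange(len(trial.grf["plate2"]["force"])) / trial.force_rate
        mk_t = traj.time
        plate = trial.grf["plate2"]
        Fg = np.stack([np.interp(mk_t, tf, plate["force"][:, k]) for k in range(3)], axis=1)
        copg = np.stack([np.interp(mk_t, tf, plate["cop"][:, k]) for k in range(3)], axis=1)
        tzg = np.interp(mk_t, tf, plate["free_moment"])

        nm = len(self.muscles)
        nfr = len(frames)
        out = {
            "frames": frames,
            "time": mk_t[frames],
            "muscle_forces": np.zeros((nfr, nm)),
            "G": np.zeros(nfr),
            "residuals": np.zeros((nfr, 6)),
            "knee_force": np.zeros((nfr, 3)),
            "knee_moment": np.zeros((nfr, 3)),
            "poses": poses,
            "muscle_names": [mu.name for mu in self.muscles],
        }
        x_prev = None
        child = self.segments[2]
        for i, fr in enumerate(frames):
            sys_i = self.assemble_frame(seg_kin, Fg[fr], copg[fr], tzg[fr], fr)
            x = solve_recruitment(sys_i, self.muscles,
                                  residual_weight=self.residual_weight,
                                  residual_scale=self.model.body_weight,
                                  x0=x_prev)
            x_prev = x
            names = sys_i.column_names
            fmus = x[:nm]
            N = np.array([mu.strength for mu in self.muscles])
            v = np.array([mu.volume_factor for mu in self.muscles])
            out["muscle_forces"][i] = fmus
            out["G"][i] = float(np.sum(v * (fmus / N) ** 3))
            out["residuals"][i] = [x[names.index(f"res_F{ax}")] for ax in "xyz"] + \
                                  [x[names.index(f"res_M{ax}")] for ax in "xyz"]
            out["knee_force"][i] = [x[names.index(f"knee_F{ax}")] for ax in "xyz"]
            axis_w = seg_kin[child]["R"][fr] @ self.hinge_axis["knee"]
            ref = np.eye(3)[0] if abs(axis_w[0]) < 0.9 else np.eye(3)[2]
            e1 = np.cross(axis_w, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis_w, e1)
            out["knee_moment"][i] = (x[names.index("knee_M0")] * e1
                                     + x[names.index("knee_M1")] * e2)
        return out


def joint_reaction(solution_x: np.ndarray, system: EquilibriumSystem,
                   joint: str) -> tuple[np.ndarray, np.ndarray]:
    """Constraint force and moment (world frame, parent-on-child) at a joint."""
    names = system.column_names
    fcols = [f"{joint}_F{ax}" for ax in "xyz"]
    if fcols[0] not in names:
        raise KeyError(f"unknown joint {joint!r}")
    F = np.array([solution_x[names.index(c)] for c in fcols])
    M = np.zeros(3)
    mcols = [c for c in names if c.startswith(f"{joint}_M")]
    if mcols:
        # hinge moments enter C through their world basis vectors on the
        # child's moment rows; summing those columns reconstructs the moment
        child_moment_rows = _child_moment_rows(system, joint)
        M = sum(solution_x[names.index(c)]
                * system.C[child_moment_rows, names.index(c)] for c in mcols)
    return F, np.asarray(M, dtype=float)


def _child_moment_rows(system: EquilibriumSystem, joint: str) -> np.ndarray:
    child_of = {"hip": "thigh", "knee": "shank", "ankle": "foot"}
    prefix = child_of[joint]
    rows = [i for i, r in enumerate(system.row_names)
            if r.startswith(prefix) and "_M" in r]
    return np.array(rows)


def muscle_generalized_force(km: kin.KinematicModel, model, muscle_name: str,
                             q: np.ndarray, dof: str, eps: float = 1e-7) -> float:
    """Generalized force of unit muscle tension on a coordinate (virtual work)."""
    path = model.attachments[muscle_name]

    def points(qq):
        poses, _ = kin.forward_kinematics(km, qq)
        return [poses[seg][1][0] + poses[seg][0][0] @ np.asarray(loc)
                for seg, loc in path]

    d = kin.DOF_NAMES.index(dof)
    qp = np.array(q, dtype=float)
    qm = qp.copy()
    qp[d] += eps
    qm[d] -= eps
    P0 = points(q)
    Pp = points(qp)
    Pm = points(qm)
    # unit-tension force on each point, from the path geometry at q
    tau = 0.0
    npts = len(P0)
    for j in range(npts):
        pull = np.zeros(3)
        if j + 1 < npts:
            u = P0[j + 1] - P0[j]
            pull += u / np.linalg.norm(u)
        if j - 1 >= 0:
            u = P0[j - 1] - P0[j]
            pull += u / np.linalg.norm(u)
        dpdq = (Pp[j] - Pm[j]) / (2 * eps)
        tau += pull @ dpdq
    return float(tau)


def muscle_length_gradient(km: kin.KinematicModel, model, muscle_name: str,
                           q: np.ndarray, dof: str, eps: float = 1e-7) -> float:
    """Finite-difference tendon excursion d(path length)/d(coordinate)."""
    path = model.attachments[muscle_name]

    def length(qq):
        poses, _ = kin.forward_kinematics(km, qq)
        pts = [poses[seg][1][0] + poses[seg][0][0] @ np.asarray(loc)
               for seg, loc in path]
        return sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:]))

    d = kin.DOF_NAMES.index(dof)
    qp = np.array(q, dtype=float)
    qm = qp.copy()
    qp[d] += eps
    qm[d] -= eps
    return float((length(qp) - length(qm)) / (2 * eps))
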