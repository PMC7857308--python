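"""Knee loads in the tibial frame and medial/lateral force decomposition.

The tibial coordinate system follows the clinical convention: the
proximal-distal (PD) axis points from the talocrural joint center to the
midpoint between the medial and lateral tibia edges; the medial-lateral
(ML) axis is orthogonal to PD and points toward the lateral tibia edge for
the right knee (medial for the left, which keeps the triad right-handed);
the anterior-posterior (AP) axis is PD x ML and points anteriorly.

The total tibiofemoral contact force is the knee constraint force expressed
in this frame (compression = its PD component).  The frontal-plane
equilibrium about the tibial origin,

    MCF + LCF = TCF_compressive
    MCF * d_med - LCF * d_lat = M_adduction,

splits the compression into medial and lateral compartment forces using the
lever arms d_med/d_lat from the tibial origin to the plateau centers.
Adduction moment is signed positive when it loads the medial compartment,
for both legs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scaling import MomentArms, seedhom_moment_arms  # re-export for API convenience

__all__ = ["TibialFrame", "MomentArms", "KneeLoadTrajectory",
           "build_tibial_frame", "express_knee_loads",
           "moment_arms_from_geometry", "seedhom_moment_arms",
           "decompose_medial_lateral"]


@dataclass
class TibialFrame:
    origin: np.ndarray        # tibial reference point, shank frame (m)
    PD: np.ndarray
    ML: np.ndarray
    AP: np.ndarray
    leg: str

    def __post_init__(self):
        M = np.stack([self.PD, self.ML, self.AP])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise ValueError("tibial frame axes are not orthonormal")


def build_tibial_frame(talocrural_center, medial_edge, lateral_edge,
                       leg: str) -> TibialFrame:
    """Construct the tibial frame from three landmarks (shank-frame coords)."""
    tc = np.asarray(talocrural_center, dtype=float)
    med = np.asarray(medial_edge, dtype=float)
    lat = np.asarray(lateral_edge, dtype=float)
    origin = 0.5 * (med + lat)
    pd = origin - tc
    n = np.linalg.norm(pd)
    if n < 1e-12:
        raise ValueError("talocrural center coincides with the tibial origin")
    pd = pd / n
    target = (lat - med) if leg.upper() == "R" else (med - lat)
    ml = target - (target @ pd) * pd
    n = np.linalg.norm(ml)
    if n < 1e-12:
        raise ValueError("collinear tibial landmarks")
    ml = ml / n
    ap = np.cross(pd, ml)
    return TibialFrame(origin=origin, PD=pd, ML=ml, AP=ap, leg=leg.upper())


def express_knee_loads(force, moment, frame: TibialFrame,
                       application_point=None):
    """Project a knee reaction onto the tibial frame.

    ``force``/``moment`` are the joint constraint force and moment acting on
    the tibia, in the same (shank-frame) coordinates as the frame axes.  If
    ``application_point`` differs from the tibial origin, the moment is
    transported.  Returns a dict with compressive/AP/ML force components,
    the flexion moment (about ML) and the adduction moment (about AP,
    positive = medial loading for either leg).
    """
    F = np.asarray(force, dtype=float)
    M = np.asarray(moment, dtype=float)
    if application_point is not None:
        r = np.asarray(application_point, dtype=float) - frame.origin
        M = M + np.cross(r, F)
    sign_adduction = -1.0 if frame.leg == "R" else 1.0
    return {
        # force ON the tibia: compression acts along -PD (femur pushes down)
        "compression": -float(F @ frame.PD),
        "anterior": float(F @ frame.AP),
        "lateral": float(F @ frame.ML),
        "flexion_moment": float(M @ frame.ML),
        "adduction_moment": sign_adduction * float(M @ frame.AP),
    }


def moment_arms_from_geometry(tibial_landmarks: dict, leg: str) -> MomentArms:
    """Lever arms measured on (personalized) tibial geometry.

    ``tibial_landmarks`` must contain the talocrural center, tibia edges and
    plateau centers in the shank frame.
    """
    req = ("talocrural_center", "tibia_medial_edge", "tibia_lateral_edge",
           "medial_plateau_center", "lateral_plateau_center")
    missing = [k for k in req if k not in tibial_landmarks]
    if missing:
        raise KeyError(f"missing tibial landmarks: {missing}")
    lm = {k: np.asarray(tibial_landmarks[k], dtype=float) for k in req}
    frame = build_tibial_frame(lm["talocrural_center"], lm["tibia_medial_edge"],
                               lm["tibia_lateral_edge"], leg)
    d_med = abs(float((lm["medial_plateau_center"] - frame.origin) @ frame.ML))
    d_lat = abs(float((lm["lateral_plateau_center"] - frame.origin) @ frame.ML))
    return MomentArms(d_med=d_med, d_lat=d_lat, provenance="geometry")


def decompose_medial_lateral(f_compressive: float, m_adduction: float,
                             arms: MomentArms, clamp: bool = True):
    """Frontal-plane equilibrium split of the compressive force.

    MCF = (F * d_lat + M_add) / (d_med + d_lat); LCF = F - MCF.  With
    ``clamp``, a negative compartment force (condylar lift-off) is clamped
    to zero with the other compartment carrying the full compression, and
    the frame is flagged.  Returns (MCF, LCF, clamped_flag).
    """
    span = arms.d_med + arms.d_lat
    if span <= 0:
        raise ValueError("degenerate moment arms")
    mcf = (f_compressive * arms.d_lat + m_adduction) / span
    lcf = f_compressive - mcf
    flagged = False
    if clamp and (mcf < 0 or lcf < 0):
        flagged = True
        if mcf < 0:
            mcf, lcf = 0.0, f_compressive
        else:
            mcf, lcf = f_compressive, 0.0
    return float(mcf), float(lcf), flagged


@dataclass
class KneeLoadTrajectory:
    """Per-frame knee loads for one trial (tested leg, tibial frame)."""

    time: np.ndarray
    KFA: np.ndarray            # degrees
    KFM: np.ndarray            # N*m, external flexion moment convention
    KAM: np.ndarray            # N*m, adduction positive = medial loading
    TCF: np.ndarray            # N, compressive component
    MCF: np.ndarray
    LCF: np.ndarray
    frame: TibialFrame
    arms: MomentArms
    clamped: np.ndarray = field(default=None)
    body_weight: float = None  # N
    body_height: float = None  # m

    def normalized(self, var: str) -> np.ndarray:
        """%BW for forces, %BW*BH for moments."""
        x = getattr(self, var)
        if var in ("TCF", "MCF", "LCF"):
            return 100.0 * x / self.body_weight
        if var in ("KAM", "KFM"):
            return 100.0 * x / (self.body_weight * self.body_height)
        return x


def knee_loads_from_dynamics(dyn_out: dict, model, traj, leg: str,
                             clamp: bool = True) -> KneeLoadTrajectory:
    """Assemble the knee-load trajectory from a recruitment run.

    The knee constraint force/moment (world frame) are rotated into the
    shank frame per analyzed frame, expressed in the tibial frame and
    decomposed using the model's moment arms.
    """
    side = leg.lower()
    lm = model.tibial_landmarks[side]
    frame = build_tibial_frame(lm["talocrural_center"], lm["tibia_medial_edge"],
                               lm["tibia_lateral_edge"], leg)
    arms = model.knee_moment_arms
    R_shank = dyn_out["poses"][f"shank_{side}"][0]
    frames = dyn_out["frames"]
    n = len(frames)
    tcf = np.zeros(n)
    kam = np.zeros(n)
    kfm = np.zeros(n)
    mcf = np.zeros(n)
    lcf = np.zeros(n)
    clamped = np.zeros(n, dtype=bool)
    for i, fr in enumerate(frames):
        Rw = R_shank[fr]
        F_local = Rw.T @ dyn_out["knee_force"][i]
        M_local = Rw.T @ dyn_out["knee_moment"][i]
        loads = express_knee_loads(F_local, M_local, frame,
                                   application_point=np.zeros(3))
        tcf[i] = loads["compression"]
        kam[i] = loads["adduction_moment"]
        kfm[i] = loads["flexion_moment"]
        mcf[i], lcf[i], clamped[i] = decompose_medial_lateral(
            tcf[i], kam[i], arms, clamp=clamp)
    import gaitload.kinematics as kin
    kfa = np.rad2deg(traj.q[frames, kin.DOF_NAMES.index(f"knee_flex_{side}")])
    return KneeLoadTrajectory(time=dyn_out["time"], KFA=kfa, KFM=kfm, KAM=kam,
                              TCF=tcf, MCF=mcf, LCF=lcf, frame=frame, arms=arms,
                              clamped=clamped, body_weight=model.body_weight,
                              body_height=model.height / 100.0)
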