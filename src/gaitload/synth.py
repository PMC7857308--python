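"""Synthetic gait laboratory: subjects, bone geometry and motion trials.

Stands in for a five-patient motion-capture + MRI data collection so the
whole pipeline is testable with known ground truth.  It emulates:

* a 32-marker bilateral lower-body protocol sampled at 120 Hz,
* force plates at 2000 Hz, with the symptomatic leg contacting plate 2,
* a standing reference trial per subject,
* seven gait conditions: normal shod walking, lateral wedge insoles at 0, 5
  and 10 degrees, toe-in, toe-out and wide-stance walking,
* per-subject bone geometry produced by a *recorded* deformation of the
  template (per-bone anisotropic scaling plus a smooth Gaussian bump field,
  expressed in a rigidly displaced scan frame), standing in for MRI
  segmentation.

Joint-angle ground truth follows parametric gait-cycle curves; markers are
the forward kinematics of those poses plus cluster-level soft-tissue
artifact and white noise.  The vertical ground reaction is a double-hump
curve scaled to body weight; the insole conditions tilt the frontal-plane
ground reaction medially and shift the center of pressure laterally in
proportion to the wedge angle; toe-in/toe-out rotate foot progression via
hip axial rotation; wide stance abducts the limb to a larger step width.
Prescribed kinematics and the parametric ground reactions are not forced to
be dynamically consistent; the recruitment stage absorbs the mismatch with
penalized pelvis residual actuators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinematics as kin
from .template import (ANKLE_HEIGHT, REF_HEIGHT, REF_LENGTHS, REF_MASS,
                       CLUSTER_MARKERS, BoneGeometry, TemplateModel)

GRAVITY = 9.81

# demographics of the five-patient cohort the synthetic study emulates
# (mass kg, height cm, tested leg)
COHORT_DEMOGRAPHICS = (
    {"id": "P1", "mass": 74.0, "height": 156.0, "tested_leg": "R"},
    {"id": "P2", "mass": 112.0, "height": 184.0, "tested_leg": "L"},
    {"id": "P3", "mass": 90.0, "height": 163.0, "tested_leg": "R"},
    {"id": "P4", "mass": 89.0, "height": 165.5, "tested_leg": "R"},
    {"id": "P5", "mass": 71.2, "height": 167.5, "tested_leg": "L"},
)


@dataclass
class SubjectSpec:
    id: str
    mass: float                 # kg
    height: float               # cm
    tested_leg: str             # "L" | "R"
    true_segment_lengths: dict  # m
    tibial_plateau_width: float # m
    fat_fraction: float
    rng_seed: int

    def __post_init__(self):
        if self.mass <= 0 or self.height <= 0:
            raise ValueError("mass and height must be positive")
        if self.tested_leg not in ("L", "R"):
            raise ValueError("tested_leg must be 'L' or 'R'")
        if any(v <= 0 for v in self.true_segment_lengths.values()):
            raise ValueError("segment lengths must be positive")
        if not 0 <= self.fat_fraction < 1:
            raise ValueError("fat fraction must be in [0, 1)")

    @property
    def bmi(self) -> float:
        return self.mass / (self.height / 100.0) ** 2

    @property
    def body_weight(self) -> float:
        return self.mass * GRAVITY


@dataclass
class GaitCondition:
    name: str
    wedge_angle: float = 0.0              # degrees
    foot_progression_offset: float = 0.0  # degrees, negative = toe-in
    step_width_offset: float = 0.0        # m

    def __post_init__(self):
        if self.name.startswith("insole") or self.name == "shod":
            if self.foot_progression_offset or self.step_width_offset:
                raise ValueError("insole/shod conditions modify only the wedge")
        else:
            if self.wedge_angle != 0:
                raise ValueError("gait-modification conditions have no wedge")
        if self.wedge_angle < 0:
            raise ValueError("wedge angle must be >= 0")


def default_conditions(toe_offset_deg: float = 10.0,
                       width_offset_m: float = 0.03) -> dict:
    """The seven study conditions with configurable modification magnitudes."""
    return {
        "shod": GaitCondition("shod"),
        "insole_0": GaitCondition("insole_0", wedge_angle=0.0),
        "insole_5": GaitCondition("insole_5", wedge_angle=5.0),
        "insole_10": GaitCondition("insole_10", wedge_angle=10.0),
        "toe_in": GaitCondition("toe_in", foot_progression_offset=-toe_offset_deg),
        "toe_out": GaitCondition("toe_out", foot_progression_offset=toe_offset_deg),
        "wide": GaitCondition("wide", step_width_offset=width_offset_m),
    }


@dataclass
class MarkerNoise:
    white_std: float = 0.001      # m
    sta_amplitude: float = 0.003  # m, cluster-level soft-tissue artifact

    @classmethod
    def none(cls):
        return cls(0.0, 0.0)


@dataclass
class TrialDataset:
    markers: dict                  # name -> (N, 3) m, lab frame
    marker_rate: float             # Hz
    grf: dict                      # plate -> {"force","cop": (Nf,3), "free_moment": (Nf,)}
    force_rate: float              # Hz
    condition: GaitCondition
    events: dict = field(default_factory=dict)      # "heel_strike"/"toe_off" s
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.markers.values())))

    @property
    def duration(self) -> float:
        return self.n_frames / self.marker_rate


# ---------------------------------------------------------------------------
# bone deformation ground truth

@dataclass
class BoneDeformation:
    """Recorded template-to-subject map: y = S x + bump(x), then a rigid
    displacement into the scan frame.

    The bump field is a sum of smooth Gaussian bumps minus its own best-fit
    affine component over the bone surface, with the fit constrained so the
    corrected field vanishes *exactly* at the two joint anchor points.  The
    affine removal makes the non-affine variability orthogonal to what the
    affine registration stage captures (so the decomposition of the
    deformation into rigid x affine x residual is well defined), and the
    anchor constraint makes joint-to-joint distances scale exactly with S.
    """

    scale: np.ndarray            # (3,) diagonal
    bump_centers: np.ndarray     # (k, 3)
    bump_amps: np.ndarray        # (k, 3) m
    bump_sigma: float            # m
    anchors: np.ndarray          # (2, 3) template points where bump = 0
    affine_correction: np.ndarray   # (4, 3): rows [B; c], bump -= x@B + c
    anchor_correction: np.ndarray   # (2, 3): Gaussian-at-anchor coefficients
    scan_R: np.ndarray           # (3, 3)
    scan_t: np.ndarray           # (3,)

    def _raw_bump(self, pts):
        d2 = ((pts[:, None, :] - self.bump_centers[None]) ** 2).sum(-1)
        w = np.exp(-d2 / (2 * self.bump_sigma ** 2))
        return w @ self.bump_amps

    def bump(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        b = (self._raw_bump(pts) - pts @ self.affine_correction[:3]
             - self.affine_correction[3])
        d2a = ((pts[:, None, :] - self.anchors[None]) ** 2).sum(-1)
        return b - np.exp(-d2a / (2 * self.bump_sigma ** 2)) @ self.anchor_correction

    def true_map(self, pts):
        """Deformation in the template segment frame (scan pose removed)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts * self.scale + self.bump(pts)

    def scan_map(self, pts):
        return self.true_map(pts) @ self.scan_R.T + self.scan_t

    @staticmethod
    def fit_corrections(raw_bump, surface_pts, anchors, sigma):
        """Affine removal + anchor zeroing of a raw bump field.

        First the unconstrained best-fit affine of the field over the bone
        surface is found (so the residual deformation carries no net affine
        component for the registration stage to absorb); then two Gaussian
        bumps centered at the joint anchors are solved to make the corrected
        field vanish there exactly.
        """
        X = np.hstack([surface_pts, np.ones((len(surface_pts), 1))])
        Y = raw_bump(surface_pts)
        d2s = ((surface_pts[:, None, :] - anchors[None]) ** 2).sum(-1)
        Gs = np.exp(-d2s / (2 * sigma ** 2))
        Xa = np.hstack([anchors, np.ones((2, 1))])
        Ya = raw_bump(anchors)
        d2 = ((anchors[:, None, :] - anchors[None]) ** 2).sum(-1)
        G = np.exp(-d2 / (2 * sigma ** 2))
        corr = np.zeros((4, 3))
        anchor_corr = np.zeros((2, 3))
        # alternate the two projections until the corrected field both has no
        # net affine component over the surface and vanishes at the anchors
        for _ in range(8):
            corr_new, *_ = np.linalg.lstsq(X, Y - Gs @ anchor_corr, rcond=None)
            anchor_corr_new = np.linalg.solve(
                G, Ya - anchors @ corr_new[:3] - corr_new[3])
            if (np.abs(corr_new - corr).max() < 1e-15
                    and np.abs(anchor_corr_new - anchor_corr).max() < 1e-15):
                corr, anchor_corr = corr_new, anchor_corr_new
                break
            corr, anchor_corr = corr_new, anchor_corr_new
        return corr, anchor_corr


class TrueSubjectModel:
    """The generating skeleton: template geometry scaled per segment type."""

    def __init__(self, template: TemplateModel, lengths: dict):
        self.segment_lengths = dict(lengths)
        self._scales = {k: lengths[k] / REF_LENGTHS[k] for k in REF_LENGTHS}
        self.marker_locals = {}
        for seg, mk in template.marker_protocol.items():
            s = self._scales["pelvis_width" if seg == "pelvis" else seg.split("_")[0]]
            self.marker_locals[seg] = {m: np.asarray(p) * s for m, p in mk.items()}
        self._template = template

    def joint_origin(self, segment: str) -> np.ndarray:
        side = segment[-1]
        sgn = -1.0 if side == "r" else 1.0
        L = self.segment_lengths
        if segment.startswith("thigh"):
            return np.array([0.0, sgn * L["pelvis_width"] / 2, 0.0])
        if segment.startswith("shank"):
            return np.array([0.0, 0.0, -L["thigh"]])
        if segment.startswith("foot"):
            return np.array([0.0, 0.0, -L["shank"]])
        raise KeyError(segment)


@dataclass
class SyntheticSubject:
    spec: SubjectSpec
    bones: dict                  # segment -> target BoneGeometry (scan frame)
    deformations: dict           # segment -> BoneDeformation (recorded truth)
    true_model: TrueSubjectModel
    template: TemplateModel


_BONE_ANCHORS = {
    "pelvis": ("r_hip_center", "l_hip_center"),
    "thigh": ("hip_center", "knee_center"),
    "shank": (None, "talocrural_center"),    # None -> frame origin
    "foot": ("heel", "toe"),
}


def _make_deformation(bone: BoneGeometry, seg: str, scale: np.ndarray,
                      rng: np.random.Generator, bump_amp: float,
                      bump_sigma: float, identity: bool) -> BoneDeformation:
    a_name, b_name = _BONE_ANCHORS[seg.split("_")[0] if seg != "pelvis" else "pelvis"]
    a = np.zeros(3) if a_name is None else np.asarray(bone.landmarks[a_name], dtype=float)
    b = np.asarray(bone.landmarks[b_name], dtype=float)
    lo = bone.mesh.vertices.min(0)
    hi = bone.mesh.vertices.max(0)
    k = 3
    centers = rng.uniform(lo, hi, size=(k, 3))
    amps = rng.normal(0.0, bump_amp, size=(k, 3))
    if seg.startswith("foot"):
        # foot shape variability is affine-only, matching the foot's
        # landmark-based affine morph protocol
        amps = np.zeros_like(amps)
    if identity:
        amps = np.zeros_like(amps)
        angle, axis_v, t = 0.0, np.array([0.0, 0.0, 1.0]), np.zeros(3)
    else:
        angle = rng.uniform(-0.12, 0.12)           # ~±7 deg scan misalignment
        axis_v = rng.normal(size=3)
        axis_v /= np.linalg.norm(axis_v)
        t = rng.uniform(-0.02, 0.02, size=3)
    K = np.array([[0, -axis_v[2], axis_v[1]], [axis_v[2], 0, -axis_v[0]],
                  [-axis_v[1], axis_v[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    anchors = np.stack([a, b])

    def raw(pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d2 = ((pts[:, None, :] - centers[None]) ** 2).sum(-1)
        return np.exp(-d2 / (2 * bump_sigma ** 2)) @ amps

    corr, anchor_corr = BoneDeformation.fit_corrections(
        raw, bone.mesh.vertices, anchors, bump_sigma)
    return BoneDeformation(scale=np.asarray(scale, dtype=float),
                           bump_centers=centers, bump_amps=amps,
                           bump_sigma=bump_sigma, anchors=anchors,
                           affine_correction=corr, anchor_correction=anchor_corr,
                           scan_R=R, scan_t=t)


def generate_subject(seed: int, demographics: dict | None = None,
                     template: TemplateModel | None = None,
                     identity_deformation: bool = False,
                     bump_amplitude: float = 0.0025,
                     bump_sigma: float = 0.09,
                     length_jitter: float = 0.02) -> SyntheticSubject:
    """Create a subject with recorded bone deformations and a true skeleton.

    ``demographics`` may provide id/mass/height/tested_leg; anything absent
    is drawn from physiological ranges.  With ``identity_deformation`` the
    bone targets equal the template (unit scales, no bump, no scan offset).
    """
    rng = np.random.default_rng(seed)
    demo = dict(demographics or {})
    mass = float(demo.get("mass", rng.uniform(60, 100)))
    height = float(demo.get("height", rng.uniform(155, 185)))
    leg = demo.get("tested_leg", "R")
    if mass <= 0 or height <= 0:
        raise ValueError("non-physiological demographics: mass and height must be > 0")
    template = template or TemplateModel()

    if identity_deformation:
        sz = {k: 1.0 for k in REF_LENGTHS}
        s_width = 1.0
    else:
        h_ratio = height / REF_HEIGHT
        sz = {k: h_ratio * (1 + rng.normal(0, length_jitter)) for k in REF_LENGTHS}
        s_width = float(np.sqrt((mass / REF_MASS) / h_ratio))
        s_width = float(np.clip(s_width, 0.8, 1.35))

    scale_of = {
        "pelvis": np.array([s_width, sz["pelvis_width"], s_width]),
        "thigh": np.array([s_width, s_width, sz["thigh"]]),
        "shank": np.array([s_width, s_width, sz["shank"]]),
        "foot": np.array([sz["foot"], s_width, s_width]),
    }

    deformations, bones = {}, {}
    for seg, bone in template.bones.items():
        base = "pelvis" if seg == "pelvis" else seg.split("_")[0]
        d = _make_deformation(bone, seg, scale_of[base], rng, bump_amplitude,
                              bump_sigma, identity_deformation)
        deformations[seg] = d
        mesh = bone.mesh.copy()
        mesh.vertices = d.scan_map(mesh.vertices)
        landmarks = {n: d.scan_map(p)[0] for n, p in bone.landmarks.items()}
        attach = {}
        for mu in template.muscles:
            for i, (owner, p) in enumerate(mu.path):
                if owner == seg:
                    attach[f"{mu.name}/{i}"] = d.scan_map(p)[0]
        bones[seg] = BoneGeometry(name=seg, mesh=mesh, landmarks=landmarks,
                                  attachment_sites=attach,
                                  regions={k: v.copy() for k, v in bone.regions.items()},
                                  watertight=False)

    # true lengths from deformed joint-to-joint distances (bump vanishes at
    # the joint anchors, so these equal the scaled template lengths exactly)
    pel = deformations["pelvis"]
    fem = deformations["thigh_r"]
    tib = deformations["shank_r"]
    ft = deformations["foot_r"]
    pl = template.bones["pelvis"].landmarks
    fl = template.bones["thigh_r"].landmarks
    tl = template.bones["shank_r"].landmarks
    fo = template.bones["foot_r"].landmarks
    lengths = {
        "pelvis_width": float(np.linalg.norm(
            pel.true_map(pl["r_hip_center"]) - pel.true_map(pl["l_hip_center"]))),
        "thigh": float(np.linalg.norm(
            fem.true_map(fl["hip_center"]) - fem.true_map(fl["knee_center"]))),
        "shank": float(np.linalg.norm(tib.true_map(tl["talocrural_center"])
                                      - tib.true_map([0, 0, 0]))),
        "foot": float(np.linalg.norm(ft.true_map(fo["toe"]) - ft.true_map(fo["heel"]))),
    }
    plateau = float(np.linalg.norm(
        tib.true_map(tl["tibia_medial_edge"]) - tib.true_map(tl["tibia_lateral_edge"])))

    bmi = mass / (height / 100.0) ** 2
    from .scaling import fat_fraction_from_bmi
    spec = SubjectSpec(id=str(demo.get("id", f"S{seed}")), mass=mass, height=height,
                       tested_leg=leg, true_segment_lengths=lengths,
                       tibial_plateau_width=plateau,
                       fat_fraction=fat_fraction_from_bmi(bmi), rng_seed=int(seed))
    true_model = TrueSubjectModel(template, lengths)
    return SyntheticSubject(spec=spec, bones=bones, deformations=deformations,
                            true_model=true_model, template=template)


# ---------------------------------------------------------------------------
# gait curves

STANCE_FRACTION = 0.62


def _pgauss(phase, mu, sigma):
    d = (phase - mu + 0.5) % 1.0 - 0.5
    return np.exp(-d ** 2 / (2 * sigma ** 2))


def gait_angles_deg(phase, side_sign: float = 1.0):
    """Parametric joint-angle templates over the gait cycle (degrees).

    ``phase`` 0 at heel strike.  Values are for one leg; pelvis terms carry
    ``side_sign`` (+1 right stance leg, -1 left) for lateral sway symmetry.
    """
    p = np.asarray(phase)
    return {
        "hip_flex": 8.0 + 20.0 * np.cos(2 * np.pi * p),
        "hip_add": 3.0 * np.cos(2 * np.pi * (p - 0.2)),
        "hip_rot": 2.0 * np.sin(2 * np.pi * p),
        "knee_flex": 6.0 + 16.0 * _pgauss(p, 0.15, 0.08) + 55.0 * _pgauss(p, 0.75, 0.09),
        "ankle_dorsi": (-4.0 + 8.0 * _pgauss(p, 0.40, 0.12)
                        - 18.0 * _pgauss(p, 0.65, 0.05)),
    }


def _ground_truth_q(subject: SyntheticSubject, condition: GaitCondition,
                    time, stride_time, t_hs, speed, amp_scale, rng):
    """Generalized-coordinate trajectories for the whole trial."""
    n = len(time)
    q = np.zeros((n, kin.NDOF))
    leg = subject.spec.tested_leg.lower()
    other = "l" if leg == "r" else "r"
    L = subject.true_model.segment_lengths
    pelvis_h = (L["thigh"] + L["shank"] + ANKLE_HEIGHT) * 0.985

    phase = ((time - t_hs) / stride_time) % 1.0
    phase_other = (phase + 0.5) % 1.0

    d2r = np.pi / 180.0
    for side, ph in ((leg, phase), (other, phase_other)):
        ang = gait_angles_deg(ph)
        q[:, kin.DOF_NAMES.index(f"hip_flex_{side}")] = ang["hip_flex"] * amp_scale * d2r
        q[:, kin.DOF_NAMES.index(f"hip_add_{side}")] = ang["hip_add"] * d2r
        q[:, kin.DOF_NAMES.index(f"hip_rot_{side}")] = ang["hip_rot"] * d2r
        q[:, kin.DOF_NAMES.index(f"knee_flex_{side}")] = ang["knee_flex"] * amp_scale * d2r
        q[:, kin.DOF_NAMES.index(f"ankle_dorsi_{side}")] = ang["ankle_dorsi"] * d2r

    # condition-specific modifications of the tested leg
    if condition.foot_progression_offset:
        # negative offset = toe-in = internal hip rotation (positive internal)
        q[:, kin.DOF_NAMES.index(f"hip_rot_{leg}")] += \
            -condition.foot_progression_offset * d2r
    if condition.step_width_offset:
        leg_len = L["thigh"] + L["shank"]
        q[:, kin.DOF_NAMES.index(f"hip_add_{leg}")] += \
            -np.arcsin(condition.step_width_offset / leg_len)

    q[:, 0] = speed * time
    # lateral sway moves the pelvis over the stance-side foot
    lat_sign = -1.0 if leg == "r" else 1.0
    q[:, 1] = lat_sign * 0.025 * np.sin(2 * np.pi * phase)
    q[:, 2] = pelvis_h + 0.012 * np.cos(4 * np.pi * phase)
    q[:, 3] = 2.0 * d2r * np.sin(2 * np.pi * phase)
    q[:, 4] = 1.0 * d2r * (1 + np.sin(2 * np.pi * phase))
    q[:, 5] = 2.0 * d2r * np.sin(2 * np.pi * phase + np.pi / 2)
    return q


# condition effect coefficients (documented in the methods note)
WEDGE_COP_SHIFT = 0.002      # m of lateral CoP shift per wedge degree
WEDGE_GRF_TILT = 0.004       # fraction of Fz redirected medially per wedge degree


def _grf_profiles(u, bw):
    """Stance-normalized ground reaction profiles (lab frame, right leg)."""
    fz = 1.18 * bw * np.clip(np.sin(np.pi * u) + 0.3 * np.sin(3 * np.pi * u), 0, None)
    fx = -0.18 * bw * np.sin(2 * np.pi * u)
    fy = 0.04 * bw * np.sin(np.pi * u)      # small medially-directed component
    return fx, fy, fz


def generate_trial(subject: SyntheticSubject, condition: GaitCondition,
                   duration: float = 1.6, noise: MarkerNoise | None = None,
                   seed: int = 0, marker_rate: float = 120.0,
                   force_rate: float = 2000.0, stride_time: float = 1.1,
                   speed: float = 1.2,
                   wedge_cop_shift: float = WEDGE_COP_SHIFT,
                   wedge_grf_tilt: float = WEDGE_GRF_TILT,
                   trial_variability: float = 0.03) -> TrialDataset:
    """One gait trial: markers + force plates + recorded ground truth."""
    noise = MarkerNoise() if noise is None else noise
    rng = np.random.default_rng(seed)
    amp_scale = 1.0 + trial_variability * rng.standard_normal()
    stride = stride_time * (1.0 + trial_variability * rng.standard_normal() / 2)
    spd = speed * (1.0 + trial_variability * rng.standard_normal())
    t_hs = 0.35
    t_to = t_hs + STANCE_FRACTION * stride
    if duration < t_to + 0.1:
        raise ValueError(
            f"duration {duration} s too short for a full stance phase "
            f"(toe-off at {t_to:.2f} s)")

    time = np.arange(int(round(duration * marker_rate))) / marker_rate
    q = _ground_truth_q(subject, condition, time, stride, t_hs, spd, amp_scale, rng)
    km = kin.KinematicModel.from_model(subject.true_model)
    poses, markers_clean = kin.forward_kinematics(km, q)

    markers = {m: v.copy() for m, v in markers_clean.items()}
    leg = subject.spec.tested_leg.lower()
    phase = ((time - t_hs) / stride) % 1.0
    if noise.sta_amplitude > 0:
        for seg, cluster in CLUSTER_MARKERS.items():
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            ph0 = rng.uniform(0, 2 * np.pi)
            R, _ = poses[seg]
            disp = (noise.sta_amplitude * np.sin(2 * np.pi * phase + ph0)[:, None]
                    * np.einsum("nij,j->ni", R, direction))
            for m in cluster:
                markers[m] = markers[m] + disp
    if noise.white_std > 0:
        for m in markers:
            markers[m] = markers[m] + rng.normal(0, noise.white_std,
                                                 size=markers[m].shape)

    # force plates
    tf = np.arange(int(round(duration * force_rate))) / force_rate
    bw = subject.spec.body_weight
    lat_sign = -1.0 if leg == "r" else 1.0      # lab +y is left; lateral for right leg is -y
    grf = {}
    def plate_record(t_hs_i, side):
        heel_l = subject.true_model.marker_locals[f"foot_{side}"][
            "RHEE" if side == "r" else "LHEE"]
        toe_l = subject.true_model.marker_locals[f"foot_{side}"][
            "RTOE" if side == "r" else "LTOE"]
        u = (tf - t_hs_i) / (STANCE_FRACTION * stride)
        in_stance = (u >= 0) & (u <= 1)
        uu = np.clip(u, 0, 1)
        fx, fy, fz = _grf_profiles(uu, bw)
        sgn = -1.0 if side == "r" else 1.0      # lateral sign for this side
        fy = -sgn * fy                           # medially directed
        wedge = condition.wedge_angle if side == leg else 0.0
        fy = fy + (-sgn) * wedge_grf_tilt * wedge * fz
        prog = np.deg2rad(condition.foot_progression_offset) if side == leg else 0.0
        fx_r = fx * np.cos(prog) - fy * np.sin(prog)
        fy_r = fx * np.sin(prog) + fy * np.cos(prog)
        force = np.stack([fx_r, fy_r, fz], axis=1)
        force[~in_stance] = 0.0
        # CoP: heel-to-toe progression along the foot, projected to the floor
        idx = np.clip((((tf - 0) * marker_rate)).astype(int), 0, len(time) - 1)
        seg = f"foot_{side}"
        Rs, ps = poses[seg]
        local = (heel_l[None] * (1 - uu[:, None]) + toe_l[None] * uu[:, None])
        if side == leg:
            local = local + np.array([0.0, 1.0, 0.0]) * (sgn * wedge_cop_shift * wedge)
        cop = (ps[idx] + np.einsum("nij,nj->ni", Rs[idx], local))
        cop[:, 2] = 0.0
        cop[~in_stance] = 0.0
        tz = np.where(in_stance, 0.5 * np.sin(np.pi * uu), 0.0)
        return {"force": force, "cop": cop, "free_moment": tz}

    grf["plate2"] = plate_record(t_hs, leg)
    other = "l" if leg == "r" else "r"
    grf["plate1"] = plate_record(t_hs + stride / 2, other)

    events = {"heel_strike": float(t_hs), "toe_off": float(t_to)}
    gt = {"q": q, "time": time, "events": events, "stride_time": float(stride),
          "speed": float(spd), "amp_scale": float(amp_scale),
          "condition": condition.name}
    return TrialDataset(markers=markers, marker_rate=marker_rate, grf=grf,
                        force_rate=force_rate, condition=condition,
                        events=events, ground_truth=gt)


def generate_standing_trial(subject: SyntheticSubject, seed: int = 0,
                            duration: float = 1.2,
                            noise: MarkerNoise | None = None,
                            marker_rate: float = 120.0,
                            force_rate: float = 2000.0) -> TrialDataset:
    """Static standing reference trial in the neutral pose."""
    noise = MarkerNoise(white_std=0.001, sta_amplitude=0.0) if noise is None else noise
    rng = np.random.default_rng(seed)
    L = subject.true_model.segment_lengths
    pelvis_h = L["thigh"] + L["shank"] + ANKLE_HEIGHT
    q = np.zeros(kin.NDOF)
    q[2] = pelvis_h
    km = kin.KinematicModel.from_model(subject.true_model)
    _, mk = kin.forward_kinematics(km, q)
    n = int(round(duration * marker_rate))
    markers = {}
    for m, v in mk.items():
        traj = np.tile(v[0], (n, 1))
        if noise.white_std > 0:
            traj = traj + rng.normal(0, noise.white_std, size=traj.shape)
        markers[m] = traj
    nf = int(round(duration * force_rate))
    bw = subject.spec.body_weight
    half = np.zeros((nf, 3))
    half[:, 2] = bw / 2
    grf = {p: {"force": half.copy(),
               "cop": np.zeros((nf, 3)), "free_moment": np.zeros(nf)}
           for p in ("plate1", "plate2")}
    gt = {"q": np.tile(q, (n, 1)), "pose": q}
    return TrialDataset(markers=markers, marker_rate=marker_rate, grf=grf,
                        force_rate=force_rate,
                        condition=GaitCondition("shod"),
                        ground_truth=gt)
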