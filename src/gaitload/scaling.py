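"""Model personalization: marker-based linear scaling and geometric morphing.

Two routes produce a :class:`PersonalizedModel` from the template:

* **Linear scaling** — a nonlinear least-squares fit of four segment scale
  factors (pelvis width, thigh, shank, foot), the standing pose, and the
  local positions of selected (cluster) markers to a standing reference
  trial.  Markers on bony landmarks stay fixed in their template-relative
  positions; cluster markers are free, so the scale information comes from
  the bony-landmark set.

* **Geometric morphing** — per-bone composite transform (least-squares
  affine, exact tri-harmonic RBF landmark interpolation, reverse rigid
  re-alignment into the template segment frame) applied to template meshes,
  landmarks and muscle attachment sites; segment lengths are recomputed from
  morphed joint-to-joint distances, and joint axes/centers are refit to the
  morphed geometry with analytical cylinder/sphere fits.

Both routes feed a length-mass-fat law that scales each muscle's template
isometric strength by its segment's mass ratio, inverse length ratio and
lean-mass ratio, with the fat fraction mapped linearly from BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.linalg import polar

from . import kinematics as kin
from .jointfit import fit_cylinder, fit_sphere
from .template import (BoneGeometry, REF_MASS, REF_PLATEAU_WIDTH,
                       CLUSTER_MARKERS, SIDES, TemplateModel)
from .transforms import (CompositeTransform, RigidTransform, fit_affine, fit_rbf)

# default fat-fraction map: F = FAT_INTERCEPT + FAT_SLOPE * BMI, clipped.
# Chosen so the template cadaver (BMI 24.2) sits at F = 0.25.
FAT_SLOPE = 0.01
FAT_INTERCEPT = 0.25 - FAT_SLOPE * (REF_MASS / (1.76 ** 2))
FAT_BOUNDS = (0.05, 0.60)


def fat_fraction_from_bmi(bmi: float, slope: float = FAT_SLOPE,
                          intercept: float = FAT_INTERCEPT) -> float:
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    f = intercept + slope * bmi
    f = float(np.clip(f, *FAT_BOUNDS))
    if f >= 1:
        raise ValueError("fat fraction >= 1 is non-physical")
    return f


@dataclass
class MomentArms:
    """Frontal-plane lever arms from the tibial origin to the plateau centers."""

    d_med: float
    d_lat: float
    provenance: str = "geometry"     # "geometry" | "seedhom"

    def __post_init__(self):
        if self.d_med <= 0 or self.d_lat <= 0:
            raise ValueError("moment arms must be positive")


@dataclass
class PersonalizedModel:
    """A subject-specific model: scaled lengths, strengths and geometry.

    ``scale_factors`` are the per-segment-type isotropic factors applied to
    local geometry (markers, attachments, landmarks).  For the morphing
    route, attachments and tibial landmarks are replaced by their morphed
    positions, and only the marker locals use the length-ratio scaling (the
    stand-in for MRI-digitized skin-marker positions).
    """

    provenance: str                       # "linear" | "mri_morph"
    segment_lengths: dict                 # m
    scale_factors: dict
    mass: float
    height: float                         # cm
    bmi: float
    tested_leg: str
    muscles: list
    marker_locals: dict
    attachments: dict                     # muscle name -> list[(segment, point)]
    tibial_landmarks: dict                # per side: {name -> point, shank frame}
    knee_moment_arms: MomentArms
    plateau_width: float
    joint_fits: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v <= 0 for v in self.segment_lengths.values()):
            raise ValueError("segment lengths must be positive")

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

    @property
    def body_weight(self) -> float:
        return self.mass * 9.81


def _segment_type(segment: str) -> str:
    return "pelvis_width" if segment == "pelvis" else segment.split("_")[0]


def scale_strength(template: TemplateModel, segment_lengths: dict,
                   segment_masses: dict | None, bmi: float,
                   fat_slope: float = FAT_SLOPE,
                   fat_intercept: float = FAT_INTERCEPT) -> dict:
    """Length-mass-fat muscle strength scaling.

    N_i = N0_i * (m_seg/m_ref) / (l_seg/l_ref) * (1-F)/(1-F_ref), where each
    muscle uses the segment of its insertion (distal-most path point), F is
    the subject fat fraction mapped from BMI and F_ref the template's.
    """
    if bmi <= 0 or any(v <= 0 for v in segment_lengths.values()):
        raise ValueError("lengths and BMI must be positive")
    F = fat_fraction_from_bmi(bmi, fat_slope, fat_intercept)
    F_ref = fat_fraction_from_bmi(template.bmi, fat_slope, fat_intercept)
    strengths = {}
    for mu in template.muscles:
        seg = mu.path[-1][0]
        seg_type = _segment_type(seg)
        l_ratio = segment_lengths[seg_type] / template.segment_lengths[seg_type]
        if segment_masses is None:
            m_ratio = 1.0
        else:
            ref_mass = (template.segment_mass(seg) if seg != "pelvis"
                        else template.segment_mass("pelvis"))
            m_ratio = segment_masses[seg] / ref_mass
        strengths[mu.name] = mu.template_strength * m_ratio / l_ratio * (1 - F) / (1 - F_ref)
    return strengths


def _default_segment_masses(template: TemplateModel, mass: float) -> dict:
    return {seg: template.segment_mass(seg, mass) for seg in template.segment_names()}


def _scaled_locals(template: TemplateModel, scales: dict) -> dict:
    out = {}
    for seg, mk in template.marker_protocol.items():
        s = scales[_segment_type(seg)]
        out[seg] = {m: np.asarray(p) * s for m, p in mk.items()}
    return out


def _scaled_attachments(template: TemplateModel, scales: dict) -> dict:
    return {mu.name: [(seg, np.asarray(p) * scales[_segment_type(seg)])
                      for seg, p in mu.path]
            for mu in template.muscles}


def _tibial_landmark_names():
    return ("talocrural_center", "tibia_medial_edge", "tibia_lateral_edge",
            "medial_plateau_center", "lateral_plateau_center")


def _scaled_tibial_landmarks(template: TemplateModel, scales: dict) -> dict:
    out = {}
    for side in SIDES:
        bone = template.bones[f"shank_{side}"]
        out[side] = {n: np.asarray(bone.landmarks[n]) * scales["shank"]
                     for n in _tibial_landmark_names()}
    return out


def seedhom_moment_arms(plateau_width: float, c_med: float = 0.24,
                        c_lat: float = 0.24) -> MomentArms:
    """Regression-style lever arms proportional to tibial plateau width."""
    if plateau_width <= 0:
        raise ValueError("plateau width must be positive")
    return MomentArms(d_med=c_med * plateau_width, d_lat=c_lat * plateau_width,
                      provenance="seedhom")


def _finalize(template, provenance, scales, lengths, subject, marker_locals,
              attachments, tib_lms, arms, plateau_width, joint_fits=None):
    masses = _default_segment_masses(template, subject.mass)
    strengths = scale_strength(template, lengths, masses, subject.bmi)
    muscles = [mu.scaled(strengths[mu.name]) for mu in template.muscles]
    return PersonalizedModel(
        provenance=provenance, segment_lengths=lengths, scale_factors=scales,
        mass=subject.mass, height=subject.height, bmi=subject.bmi,
        tested_leg=subject.tested_leg, muscles=muscles,
        marker_locals=marker_locals, attachments=attachments,
        tibial_landmarks=tib_lms, knee_moment_arms=arms,
        plateau_width=plateau_width, joint_fits=joint_fits or {})


# ---------------------------------------------------------------------------
# linear scaling

@dataclass
class ScalingReport:
    scale_factors: dict
    rms_residual: float               # m, over fixed markers
    per_marker_rms: dict
    optimized_marker_locals: dict
    condition_number: float
    rank_deficient: bool


def default_marker_partition(template: TemplateModel):
    """Bony-landmark markers stay fixed; thigh/shank cluster markers are free."""
    optimized = {m for cluster in CLUSTER_MARKERS.values() for m in cluster}
    fixed = {m for seg in template.marker_protocol.values() for m in seg} - optimized
    return fixed, optimized


def optimize_linear_scaling(standing, template: TemplateModel, subject,
                            fixed_markers=None, optimized_markers=None):
    """Fit segment scale factors + standing pose to a standing reference trial.

    Returns (PersonalizedModel, ScalingReport).  Deterministic: the solver
    starts from unit scales and a neutral pose located under the pelvis
    markers, and the trial's frames are averaged (static trial) before the
    fit.
    """
    if fixed_markers is None or optimized_markers is None:
        fixed_markers, optimized_markers = default_marker_partition(template)
    overlap = set(fixed_markers) & set(optimized_markers)
    if overlap:
        raise ValueError(f"markers in both partitions: {sorted(overlap)}")
    n_frames = len(next(iter(standing.markers.values())))
    if n_frames < standing.marker_rate:       # >= 1 s of frames
        raise ValueError("standing trial must cover at least one second")
    meas = {m: np.asarray(tr, dtype=float).mean(axis=0)
            for m, tr in standing.markers.items()}

    fixed = sorted(m for m in fixed_markers if m in meas)
    seg_of = {m: seg for seg, mk in template.marker_protocol.items() for m in mk}
    per_seg_fixed = {}
    for m in fixed:
        per_seg_fixed.setdefault(seg_of[m], []).append(m)
    rank_deficient = any(len(v) * 3 < 3 for v in per_seg_fixed.values())

    scale_keys = ("pelvis_width", "thigh", "shank", "foot")

    def build(scales_vec, q):
        scales = dict(zip(scale_keys, scales_vec))
        lengths = {k: template.segment_lengths[k] * scales[k] for k in scale_keys}
        locals_ = _scaled_locals(template, scales)

        class _Geom:
            marker_locals = locals_

            @staticmethod
            def joint_origin(segment):
                side = segment[-1]
                sgn = -1.0 if side == "r" else 1.0
                if segment.startswith("thigh"):
                    return np.array([0.0, sgn * lengths["pelvis_width"] / 2, 0.0])
                if segment.startswith("shank"):
                    return np.array([0.0, 0.0, -lengths["thigh"]])
                return np.array([0.0, 0.0, -lengths["shank"]])

        km = kin.KinematicModel.from_model(_Geom)
        _, mk = kin.forward_kinematics(km, q)
        return lengths, locals_, {m: v[0] for m, v in mk.items()}

    meas_fixed = np.array([meas[m] for m in fixed])

    def resid(x):
        _, _, mk = build(x[:4], x[4:])
        return (np.array([mk[m] for m in fixed]) - meas_fixed).ravel()

    x0 = np.zeros(4 + kin.NDOF)
    x0[:4] = 1.0
    pel_markers = [m for m in fixed if seg_of[m] == "pelvis"]
    if pel_markers:
        locs = np.array([template.marker_protocol["pelvis"][m] for m in pel_markers])
        x0[4:7] = np.array([meas[m] for m in pel_markers]).mean(0) - locs.mean(0)
    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-12,
                        max_nfev=5000)
    scales = dict(zip(scale_keys, sol.x[:4]))
    q_stand = sol.x[4:]
    lengths, locals_, mk = build(sol.x[:4], q_stand)

    J = sol.jac
    sv = np.linalg.svd(J, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    rank_deficient = rank_deficient or cond > 1e8

    res = np.array([mk[m] for m in fixed]) - meas_fixed
    per_marker = {m: float(np.linalg.norm(res[i])) for i, m in enumerate(fixed)}
    rms = float(np.sqrt(np.mean(res ** 2) * 3))

    # re-estimate the optimized (cluster) markers' local positions in the
    # fitted pose, as the optimizer's joint marker-position estimate
    km = kin.KinematicModel.from_model(
        type("G", (), {"marker_locals": locals_,
                       "joint_origin": staticmethod(
                           lambda seg, L=lengths: PersonalizedModel.joint_origin(
                               type("P", (), {"segment_lengths": L})(), seg))})())
    poses, _ = kin.forward_kinematics(km, q_stand)
    opt_locals = {}
    for m in sorted(optimized_markers):
        if m not in meas:
            continue
        seg = seg_of[m]
        R, p = poses[seg]
        opt_locals[m] = R[0].T @ (meas[m] - p[0])
        locals_[seg][m] = opt_locals[m]

    plateau = REF_PLATEAU_WIDTH * scales["shank"]
    arms = seedhom_moment_arms(plateau)
    model = _finalize(template, "linear", scales, lengths, subject, locals_,
                      _scaled_attachments(template, scales),
                      _scaled_tibial_landmarks(template, {**scales}),
                      arms, plateau)
    report = ScalingReport(scale_factors=scales, rms_residual=rms,
                           per_marker_rms=per_marker,
                           optimized_marker_locals=opt_locals,
                           condition_number=cond, rank_deficient=rank_deficient)
    return model, report


# ---------------------------------------------------------------------------
# geometric morphing

def _vertex_correspondences(template_bone: BoneGeometry,
                            target_bone: BoneGeometry, n: int = 70):
    """Subsampled matched mesh vertices (morphed surfaces share point
    numbering, so vertex index i corresponds across template and target)."""
    vs = template_bone.mesh.vertices
    vt = target_bone.mesh.vertices
    if len(vs) != len(vt):
        return None
    idx = np.unique(np.linspace(0, len(vs) - 1, n).astype(int))
    return vs[idx], vt[idx]


def morph_bone(template_bone: BoneGeometry, target_bone: BoneGeometry,
               use_vertex_correspondence: bool = True):
    """Composite affine -> RBF -> reverse-rigid morph of one bone.

    The affine stage captures target pose and size; the RBF stage matches
    the paired landmarks (plus, when the surfaces share point numbering, a
    subsampled set of matched mesh vertices) exactly; the reverse rigid
    stage — the inverse of the rigid polar factor of the affine — re-expresses
    the morphed geometry in the template segment frame, leaving the pure
    deformation.
    """
    names = [n for n in template_bone.landmarks if n in target_bone.landmarks]
    missing = set(template_bone.landmarks) - set(names)
    if len(names) < 4:
        raise ValueError(
            f"bone {template_bone.name}: insufficient paired landmarks "
            f"(missing {sorted(missing)})")
    src = np.array([template_bone.landmarks[n] for n in names])
    tgt = np.array([target_bone.landmarks[n] for n in names])
    aff_src, aff_tgt = src, tgt
    if use_vertex_correspondence:
        extra = _vertex_correspondences(template_bone, target_bone)
        if extra is not None:
            vs, vt = extra
            # drop vertices that duplicate a named landmark location
            keep = np.min(np.linalg.norm(vs[:, None, :] - src[None], axis=2),
                          axis=1) > 1e-9
            src = np.vstack([src, vs[keep]])
            tgt = np.vstack([tgt, vt[keep]])
            # the affine (pose+size) stage registers the full matched surface
            aff_src = np.vstack([aff_src, template_bone.mesh.vertices])
            aff_tgt = np.vstack([aff_tgt, target_bone.mesh.vertices])
    aff = fit_affine(aff_src, aff_tgt)
    rbf = fit_rbf(aff.apply(src), tgt)
    Rp, _ = polar(aff.A)
    reverse = RigidTransform(R=Rp.T, t=-Rp.T @ aff.t)
    return CompositeTransform([aff, rbf, reverse])


def morph_model(template: TemplateModel, target_bones: dict, subject,
                foot_affine_only: bool = True):
    """Personalize by morphing template bones onto subject bone geometry.

    ``target_bones`` maps segment name -> BoneGeometry in the (synthetic)
    scan frame.  Feet use a landmark-based affine only, matching the common
    practice of treating the foot as a rigidly scalable segment.  Segment
    lengths come from morphed joint-to-joint distances; the knee and ankle
    axes and hip center are refit to morphed mesh regions; medial/lateral
    knee lever arms are measured on the morphed tibial geometry.
    """
    transforms = {}
    for seg, tmpl_bone in template.bones.items():
        if seg not in target_bones:
            raise ValueError(f"missing target geometry for {seg}")
        if foot_affine_only and seg.startswith("foot"):
            names = [n for n in tmpl_bone.landmarks if n in target_bones[seg].landmarks]
            src = np.array([tmpl_bone.landmarks[n] for n in names])
            tgt = np.array([target_bones[seg].landmarks[n] for n in names])
            aff = fit_affine(src, tgt)
            Rp, _ = polar(aff.A)
            reverse = RigidTransform(R=Rp.T, t=-Rp.T @ aff.t)
            transforms[seg] = CompositeTransform([aff, reverse])
        else:
            transforms[seg] = morph_bone(tmpl_bone, target_bones[seg])

    def t(seg, pts):
        return transforms[seg].apply(np.atleast_2d(pts))

    pel = template.bones["pelvis"].landmarks
    fem_r = template.bones["thigh_r"].landmarks
    tib_r = template.bones["shank_r"].landmarks
    foot_r = template.bones["foot_r"].landmarks
    lengths = {
        "pelvis_width": float(np.linalg.norm(
            t("pelvis", pel["r_hip_center"]) - t("pelvis", pel["l_hip_center"]))),
        "thigh": float(np.linalg.norm(
            t("thigh_r", fem_r["hip_center"]) - t("thigh_r", fem_r["knee_center"]))),
        "shank": float(np.linalg.norm(
            t("shank_r", tib_r["talocrural_center"])
            - t("shank_r", [0.0, 0.0, 0.0]))),
        "foot": float(np.linalg.norm(
            t("foot_r", foot_r["toe"]) - t("foot_r", foot_r["heel"]))),
    }
    scales = {k: lengths[k] / template.segment_lengths[k] for k in lengths}

    attachments = {mu.name: [(seg, t(seg, p)[0]) for seg, p in mu.path]
                   for mu in template.muscles}

    tib_lms = {}
    for side in SIDES:
        bone = template.bones[f"shank_{side}"]
        tib_lms[side] = {n: t(f"shank_{side}", bone.landmarks[n])[0]
                         for n in _tibial_landmark_names()}

    # analytical joint fits on morphed mesh regions
    joint_fits = {}
    for side in SIDES:
        fem = template.bones[f"thigh_{side}"]
        verts = fem.mesh.vertices
        joint_fits[f"hip_{side}"] = fit_sphere(
            t(f"thigh_{side}", verts[fem.regions["head"]]))
        joint_fits[f"knee_{side}"] = fit_cylinder(
            t(f"thigh_{side}", verts[fem.regions["condyles"]]))
        tib = template.bones[f"shank_{side}"]
        joint_fits[f"ankle_{side}"] = fit_cylinder(
            t(f"shank_{side}", tib.mesh.vertices[tib.regions["distal"]]))

    side = subject.tested_leg.lower()
    lm = tib_lms[side]
    origin = 0.5 * (lm["tibia_medial_edge"] + lm["tibia_lateral_edge"])
    plateau_width = float(np.linalg.norm(
        lm["tibia_medial_edge"] - lm["tibia_lateral_edge"]))
    ml = lm["tibia_medial_edge"] - lm["tibia_lateral_edge"]
    ml /= np.linalg.norm(ml)
    d_med = float(abs((lm["medial_plateau_center"] - origin) @ ml))
    d_lat = float(abs((lm["lateral_plateau_center"] - origin) @ ml))
    arms = MomentArms(d_med=d_med, d_lat=d_lat, provenance="geometry")

    marker_locals = _scaled_locals(template, scales)
    model = _finalize(template, "mri_morph", scales, lengths, subject,
                      marker_locals, attachments, tib_lms, arms,
                      plateau_width, joint_fits)
    return model, transforms
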