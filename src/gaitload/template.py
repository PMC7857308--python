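"""Generic lower-limb template model.

A reduced cadaver-style template: pelvis (with lumped head-arms-trunk mass),
bilateral thigh/shank/foot segments, spherical hips, hinge knees and ankles,
and 14 muscle-tendon units per leg (including a three-way vasti split that
exercises volume-normalization weighting).  Muscle paths are straight lines
through via points.  Template bone surfaces are simple parametric meshes with
named landmark sets and labelled vertex regions (femoral head, condyles,
distal tibia) used by the analytical joint-fitting step.

Conventions: lab and neutral segment frames are right-handed with x anterior,
y pointing left, z up; the right leg lies at y < 0.  All internal units are
SI (m, kg, N); STL/TRC files use mm at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

# ---------------------------------------------------------------------------
# reference anthropometry (template cadaver)

REF_MASS = 75.0          # kg
REF_HEIGHT = 176.0       # cm
REF_LENGTHS = {          # m
    "pelvis_width": 0.18,    # inter-hip-center distance
    "thigh": 0.42,           # hip center to knee center
    "shank": 0.43,           # knee center to talocrural center
    "foot": 0.23,            # heel to toe marker distance
}
REF_PLATEAU_WIDTH = 0.076    # m, medial-to-lateral tibia edge distance

# segment mass fractions of whole-body mass (Dempster/de Leva style);
# head-arms-trunk and pelvis are lumped into the root segment
MASS_FRACTIONS = {"thigh": 0.1416, "shank": 0.0433, "foot": 0.0137}
PELVIS_HAT_FRACTION = 1.0 - 2 * sum(MASS_FRACTIONS.values())

ANKLE_HEIGHT = 0.08      # m, talocrural center above the sole
SIDES = ("r", "l")
CONDITION_ORDER = ("shod", "insole_0", "insole_5", "insole_10",
                   "toe_in", "toe_out", "wide")


def mirror_y(p) -> np.ndarray:
    p = np.atleast_2d(np.asarray(p, dtype=float)).copy()
    p[:, 1] *= -1.0
    return p if p.shape[0] > 1 else p[0]


@dataclass
class MuscleUnit:
    """One muscle-tendon unit: a straight-line path through via points.

    ``path`` is an ordered list of (segment_name, local_point) pairs from
    origin to insertion.  ``template_strength`` is the isometric strength of
    the template cadaver; ``strength`` is filled in by personalization.
    ``volume_factor`` is the recruitment volume-normalization weight; split
    parts of one anatomical muscle carry factors that sum to 1.
    """

    name: str
    path: list
    template_strength: float
    volume_factor: float = 1.0
    strength: float | None = None

    def __post_init__(self):
        if self.template_strength <= 0 or self.volume_factor <= 0:
            raise ValueError("muscle strength and volume factor must be positive")

    def scaled(self, strength: float) -> "MuscleUnit":
        return replace(self, strength=float(strength))


@dataclass
class BoneGeometry:
    """A bone surface with named landmarks, attachment sites and vertex regions."""

    name: str
    mesh: trimesh.Trimesh
    landmarks: dict          # name -> (3,) array, bone frame, m
    attachment_sites: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)   # name -> vertex index array
    watertight: bool = False

    def landmark_array(self, names=None):
        names = list(self.landmarks) if names is None else list(names)
        return names, np.array([self.landmarks[n] for n in names])

    def max_landmark_surface_distance(self) -> float:
        """Greatest distance from any landmark to the nearest mesh vertex
        (vertex spacing is fine enough that this bounds surface distance)."""
        pts = np.array(list(self.landmarks.values()))
        v = self.mesh.vertices
        d = np.linalg.norm(pts[:, None, :] - v[None, :, :], axis=2).min(axis=1)
        return float(d.max())


# ---------------------------------------------------------------------------
# muscle path table (right leg, segment-local coordinates in meters)

_MUSCLES_R = [
    # name, [(segment, point), ...], N0, v
    ("iliopsoas",   [("pelvis", (0.05, -0.07, 0.02)),
                     ("thigh_r", (0.035, -0.02, -0.02)),
                     ("thigh_r", (0.010, 0.005, -0.06))], 3750.0, 1.0),
    ("glut_max",    [("pelvis", (-0.08, -0.06, 0.03)),
                     ("thigh_r", (-0.025, -0.02, -0.08))], 4500.0, 1.0),
    ("glut_med",    [("pelvis", (-0.02, -0.115, 0.05)),
                     ("thigh_r", (0.005, -0.068, -0.018))], 5000.0, 1.0),
    ("adductors",   [("pelvis", (0.02, -0.02, -0.04)),
                     ("thigh_r", (0.005, 0.01, -0.22))], 3000.0, 1.0),
    ("hip_int_rot", [("pelvis", (0.06, -0.11, 0.05)),
                     ("thigh_r", (0.02, -0.05, -0.06))], 2250.0, 1.0),
    ("hip_ext_rot", [("pelvis", (-0.08, -0.02, 0.04)),
                     ("thigh_r", (-0.01, -0.05, -0.02))], 2250.0, 1.0),
    ("hamstrings",  [("pelvis", (-0.06, -0.05, -0.04)),
                     ("shank_r", (-0.025, -0.015, -0.06))], 5000.0, 1.0),
    ("rectus_fem",  [("pelvis", (0.05, -0.09, -0.01)),
                     ("thigh_r", (0.055, 0.0, -0.38)),
                     ("shank_r", (0.035, 0.0, -0.07))], 3000.0, 1.0),
    ("vas_med",     [("thigh_r", (0.02, 0.02, -0.18)),
                     ("thigh_r", (0.05, 0.01, -0.38)),
                     ("shank_r", (0.035, 0.0, -0.07))], 3500.0, 1.0 / 3),
    ("vas_int",     [("thigh_r", (0.025, 0.0, -0.15)),
                     ("thigh_r", (0.055, 0.0, -0.38)),
                     ("shank_r", (0.035, 0.0, -0.07))], 3500.0, 1.0 / 3),
    ("vas_lat",     [("thigh_r", (0.02, -0.03, -0.17)),
                     ("thigh_r", (0.05, -0.01, -0.38)),
                     ("shank_r", (0.035, 0.0, -0.07))], 4500.0, 1.0 / 3),
    ("gastroc",     [("thigh_r", (-0.03, 0.0, -0.39)),
                     ("foot_r", (-0.055, 0.0, -0.05))], 4000.0, 1.0),
    ("soleus",      [("shank_r", (-0.025, 0.0, -0.12)),
                     ("foot_r", (-0.055, 0.0, -0.05))], 7500.0, 1.0),
    ("tib_ant",     [("shank_r", (0.03, -0.01, -0.13)),
                     ("foot_r", (0.09, 0.01, -0.045))], 2250.0, 1.0),
]

# marker protocol: 32 markers, bilateral conventional lower-body set
# (ASIS/PSIS, femoral epicondyles, malleoli, heel, toe, 4-marker thigh and
# shank clusters).  Local coordinates for the right side; left is mirrored.
_MARKERS_R = {
    "pelvis": {
        "RASI": (0.09, -0.12, 0.08),
        "RPSI": (-0.12, -0.05, 0.10),
    },
    "thigh_r": {
        "RTH1": (0.02, -0.06, -0.15),
        "RTH2": (-0.02, -0.065, -0.20),
        "RTH3": (0.03, -0.06, -0.25),
        "RTH4": (-0.01, -0.07, -0.30),
        "RLEP": (0.0, -0.055, -0.42),
        "RMEP": (0.0, 0.05, -0.42),
    },
    "shank_r": {
        "RSK1": (0.015, -0.05, -0.12),
        "RSK2": (-0.015, -0.055, -0.18),
        "RSK3": (0.02, -0.05, -0.25),
        "RSK4": (-0.01, -0.06, -0.31),
        "RLML": (0.0, -0.045, -0.43),
        "RMML": (0.0, 0.04, -0.42),
    },
    "foot_r": {
        "RHEE": (-0.06, 0.0, -0.06),
        "RTOE": (0.17, -0.01, -0.06),
    },
}

CLUSTER_MARKERS = {
    "thigh_r": ("RTH1", "RTH2", "RTH3", "RTH4"),
    "shank_r": ("RSK1", "RSK2", "RSK3", "RSK4"),
    "thigh_l": ("LTH1", "LTH2", "LTH3", "LTH4"),
    "shank_l": ("LSK1", "LSK2", "LSK3", "LSK4"),
}


def _mirror_name(name: str) -> str:
    if name.startswith("R"):
        return "L" + name[1:]
    return name


def default_marker_protocol() -> dict:
    """segment -> {marker name -> local position}, both sides (32 markers)."""
    protocol = {"pelvis": {}}
    for name, p in _MARKERS_R["pelvis"].items():
        protocol["pelvis"][name] = np.array(p)
        protocol["pelvis"][_mirror_name(name)] = mirror_y(p)
    for seg in ("thigh_r", "shank_r", "foot_r"):
        left = seg[:-2] + "_l"
        protocol[seg] = {n: np.array(p) for n, p in _MARKERS_R[seg].items()}
        protocol[left] = {_mirror_name(n): mirror_y(p) for n, p in _MARKERS_R[seg].items()}
    return protocol


def default_muscles() -> list:
    """All 28 muscle units (14 per leg); left paths mirror the right."""
    units = []
    for name, path, n0, v in _MUSCLES_R:
        units.append(MuscleUnit(name=f"{name}_r", path=[(s, np.array(p)) for s, p in path],
                                template_strength=n0, volume_factor=v))
        lpath = [(s.replace("_r", "_l") if s != "pelvis" else s, mirror_y(p)) for s, p in path]
        units.append(MuscleUnit(name=f"{name}_l", path=lpath,
                                template_strength=n0, volume_factor=v))
    return units


# ---------------------------------------------------------------------------
# template bone meshes

def _tube(radius, z_top, z_bot, sections=24, stacks=10, radius_bot=None):
    """Open (possibly tapered) cylinder along z between z_top and z_bot."""
    zs = np.linspace(z_top, z_bot, stacks)
    radii = np.linspace(radius, radius_bot if radius_bot is not None else radius,
                        stacks)
    th = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    verts = []
    for z, r in zip(zs, radii):
        for t in th:
            verts.append([r * np.cos(t), r * np.sin(t), z])
    verts = np.array(verts)
    faces = []
    for i in range(stacks - 1):
        for j in range(sections):
            a = i * sections + j
            b = i * sections + (j + 1) % sections
            c = (i + 1) * sections + j
            d = (i + 1) * sections + (j + 1) % sections
            faces.append([a, b, c])
            faces.append([b, d, c])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def _translate(mesh, offset):
    m = mesh.copy()
    m.apply_translation(offset)
    return m


def _concat_with_regions(parts):
    """Concatenate (name, mesh) parts, returning mesh + per-part vertex regions."""
    meshes, regions, offset = [], {}, 0
    for name, m in parts:
        meshes.append(m)
        regions[name] = np.arange(offset, offset + len(m.vertices))
        offset += len(m.vertices)
    return trimesh.util.concatenate(meshes), regions


def _femur_mesh():
    head = _translate(trimesh.creation.icosphere(subdivisions=2, radius=0.024), (0, 0, 0))
    trochanter = _tube(0.055, -0.01, -0.10, sections=24, stacks=6, radius_bot=0.016)
    shaft = _tube(0.016, -0.10, -0.38, radius_bot=0.030)
    condyles = _tube(0.022, 0, 0.08, sections=28, stacks=8)
    # condylar cylinder: axis along y through the knee center
    condyles.apply_transform(trimesh.transformations.rotation_matrix(np.pi / 2, (1, 0, 0)))
    condyles.apply_translation((0, 0.04, -0.42))
    mesh, regions = _concat_with_regions(
        [("head", head), ("trochanter", trochanter), ("shaft", shaft),
         ("condyles", condyles)])
    landmarks = {
        "hip_center": np.array([0.0, 0.0, 0.0]),
        "greater_trochanter": np.array([0.0, -0.05, -0.02]),
        "lesser_trochanter": np.array([0.01, 0.005, -0.06]),
        "shaft_ant_prox": np.array([0.016, 0.0, -0.10]),
        "shaft_lat_mid": np.array([0.0, -0.016, -0.20]),
        "shaft_ant_mid": np.array([0.016, 0.0, -0.25]),
        "shaft_med_dist": np.array([0.0, 0.016, -0.33]),
        "lat_epicondyle": np.array([0.0, -0.04, -0.42]),
        "med_epicondyle": np.array([0.0, 0.04, -0.42]),
        "knee_center": np.array([0.0, 0.0, -0.42]),
        "condyle_ant": np.array([0.022, 0.0, -0.42]),
        "condyle_post": np.array([-0.022, 0.0, -0.42]),
        "patellar_surface": np.array([0.03, 0.0, -0.40]),
    }
    # digitized shaft correspondence rings (dense-registration stand-in)
    r = 0.016
    for zi, z in enumerate((-0.08, -0.15, -0.22, -0.29, -0.36)):
        for ai, (x, y) in enumerate(((r, 0), (-r, 0), (0, r), (0, -r))):
            landmarks[f"shaft_ring{zi}_{ai}"] = np.array([x, y, z])
    return mesh, landmarks, regions


def _tibia_mesh():
    plateau = _tube(0.036, 0.0, -0.03, sections=28, stacks=5)
    metaphysis = _tube(0.036, -0.03, -0.15, sections=24, stacks=8, radius_bot=0.014)
    shaft = _tube(0.014, -0.15, -0.41)
    distal = _tube(0.018, 0, 0.05, sections=24, stacks=6)
    distal.apply_transform(trimesh.transformations.rotation_matrix(np.pi / 2, (1, 0, 0)))
    distal.apply_translation((0, 0.025, -0.43))
    mesh, regions = _concat_with_regions(
        [("plateau", plateau), ("metaphysis", metaphysis), ("shaft", shaft),
         ("distal", distal)])
    w = REF_PLATEAU_WIDTH
    landmarks = {
        "tibia_medial_edge": np.array([0.0, w / 2, -0.005]),
        "tibia_lateral_edge": np.array([0.0, -w / 2, -0.005]),
        "medial_plateau_center": np.array([0.0, 0.019, -0.002]),
        "lateral_plateau_center": np.array([0.0, -0.019, -0.002]),
        "tibial_tuberosity": np.array([0.035, 0.0, -0.07]),
        "shaft_ant_prox": np.array([0.014, 0.0, -0.12]),
        "shaft_lat_mid": np.array([0.0, -0.014, -0.22]),
        "shaft_ant_dist": np.array([0.014, 0.0, -0.33]),
        "med_malleolus": np.array([0.0, 0.04, -0.42]),
        "lat_malleolus": np.array([0.0, -0.045, -0.43]),
        "talocrural_center": np.array([0.0, 0.0, -0.43]),
    }
    r = 0.014
    for zi, z in enumerate((-0.08, -0.16, -0.24, -0.32, -0.39)):
        for ai, (x, y) in enumerate(((r, 0), (-r, 0), (0, r), (0, -r))):
            landmarks[f"shaft_ring{zi}_{ai}"] = np.array([x, y, z])
    return mesh, landmarks, regions


def _pelvis_mesh():
    box = trimesh.creation.box(extents=(0.18, 0.26, 0.20)).subdivide().subdivide()
    box = _translate(box, (-0.02, 0, 0.02))
    sock_r = _translate(trimesh.creation.icosphere(subdivisions=2, radius=0.027),
                        (0, -0.09, 0))
    sock_l = _translate(trimesh.creation.icosphere(subdivisions=2, radius=0.027),
                        (0, 0.09, 0))
    mesh, regions = _concat_with_regions(
        [("iliac", box), ("acetabulum_r", sock_r), ("acetabulum_l", sock_l)])
    landmarks = {
        "r_asis": np.array([0.06, -0.12, 0.08]),
        "l_asis": np.array([0.06, 0.12, 0.08]),
        "r_psis": np.array([-0.10, -0.05, 0.10]),
        "l_psis": np.array([-0.10, 0.05, 0.10]),
        "pubic_symphysis": np.array([0.05, 0.0, -0.02]),
        "sacrum": np.array([-0.10, 0.0, 0.05]),
        "r_hip_center": np.array([0.0, -0.09, 0.0]),
        "l_hip_center": np.array([0.0, 0.09, 0.0]),
        "r_ischial": np.array([-0.06, -0.05, -0.02]),
        "l_ischial": np.array([-0.06, 0.05, -0.02]),
    }
    for i, (x, y, z) in enumerate([
            (0.06, 0.06, 0.10), (0.06, -0.06, 0.10), (-0.10, 0.09, 0.08),
            (-0.10, -0.09, 0.08), (0.02, 0.12, 0.0), (0.02, -0.12, 0.0),
            (0.06, 0.0, 0.05), (-0.10, 0.0, -0.01), (0.0, 0.10, -0.02),
            (0.0, -0.10, -0.02), (0.03, 0.06, -0.02), (0.03, -0.06, -0.02)]):
        landmarks[f"surface_pt{i}"] = np.array([x, y, z])
    return mesh, landmarks, regions


def _foot_mesh():
    box = trimesh.creation.box(extents=(0.25, 0.09, 0.06)).subdivide().subdivide()
    box = _translate(box, (0.055, 0, -0.05))
    mesh, regions = _concat_with_regions([("body", box)])
    landmarks = {
        "heel": np.array([-0.06, 0.0, -0.06]),
        "toe": np.array([0.17, 0.0, -0.06]),
        "met1": np.array([0.12, 0.035, -0.07]),
        "met5": np.array([0.10, -0.04, -0.07]),
        "navicular": np.array([0.03, 0.03, -0.04]),
        "cuboid": np.array([0.03, -0.03, -0.05]),
        "ankle_center": np.array([0.0, 0.0, 0.0]),
        "calcaneus_post": np.array([-0.065, 0.0, -0.04]),
        "dorsal_mid": np.array([0.06, 0.0, -0.02]),
    }
    # extra correspondence points so the foot reaches the 36-landmark affine
    # protocol when both sides' sets are pooled with digitized extras
    for i, (x, y) in enumerate([(0.0, 0.04), (0.0, -0.04), (0.06, 0.04),
                                (0.06, -0.045), (0.14, 0.02), (0.14, -0.03),
                                (0.17, 0.02), (-0.05, 0.03), (-0.05, -0.03)]):
        landmarks[f"foot_pt{i}"] = np.array([x, y, -0.075])
    return mesh, landmarks, regions


def _mirror_bone(bone: BoneGeometry, name: str) -> BoneGeometry:
    mesh = bone.mesh.copy()
    mesh.apply_transform(np.diag([1.0, -1.0, 1.0, 1.0]))
    mesh.invert()
    landmarks = {k: mirror_y(v) for k, v in bone.landmarks.items()}
    return BoneGeometry(name=name, mesh=mesh, landmarks=landmarks,
                        regions={k: v.copy() for k, v in bone.regions.items()},
                        watertight=False)


def template_bones() -> dict:
    """Template BoneGeometry per segment (pelvis, femur/tibia/foot both sides)."""
    bones = {}
    for seg, builder in (("pelvis", _pelvis_mesh), ("thigh_r", _femur_mesh),
                         ("shank_r", _tibia_mesh), ("foot_r", _foot_mesh)):
        mesh, lms, regions = builder()
        bones[seg] = BoneGeometry(name=seg, mesh=mesh, landmarks=lms,
                                  regions=regions, watertight=False)
    for seg in ("thigh_r", "shank_r", "foot_r"):
        bones[seg.replace("_r", "_l")] = _mirror_bone(bones[seg], seg.replace("_r", "_l"))
    return bones


@dataclass
class TemplateModel:
    """The generic body model personalization starts from."""

    segment_lengths: dict = field(default_factory=lambda: dict(REF_LENGTHS))
    mass: float = REF_MASS
    height: float = REF_HEIGHT
    plateau_width: float = REF_PLATEAU_WIDTH
    muscles: list = field(default_factory=default_muscles)
    marker_protocol: dict = field(default_factory=default_marker_protocol)
    bones: dict = field(default_factory=template_bones)

    @property
    def bmi(self) -> float:
        return self.mass / (self.height / 100.0) ** 2

    def segment_names(self):
        return ["pelvis"] + [f"{s}_{side}" for side in SIDES
                             for s in ("thigh", "shank", "foot")]

    def joint_origin(self, segment: str, lengths: dict | None = None) -> np.ndarray:
        """Location of a segment's proximal joint in its parent's local frame."""
        L = lengths or self.segment_lengths
        side = segment[-1]
        sgn = -1.0 if side == "r" else 1.0
        if segment.startswith("thigh"):
            return np.array([0.0, sgn * L["pelvis_width"] / 2, 0.0])
        if segment.startswith("shank"):
            return np.array([0.0, 0.0, -L["thigh"]])
        if segment.startswith("foot"):
            return np.array([0.0, 0.0, -L["shank"]])
        raise KeyError(segment)

    def segment_mass(self, segment: str, body_mass: float | None = None) -> float:
        m = self.mass if body_mass is None else body_mass
        if segment == "pelvis":
            return PELVIS_HAT_FRACTION * m
        return MASS_FRACTIONS[segment.split("_")[0]] * m

    def parent(self, segment: str) -> str | None:
        if segment == "pelvis":
            return None
        if segment.startswith("thigh"):
            return "pelvis"
        return ("thigh_" if segment.startswith("shank") else "shank_") + segment[-1]
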