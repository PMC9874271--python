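"""Synthetic model generator: a desk-scale bipedal-candidate
archosauriform hindlimb model and every other input the pipeline needs.

The generator emulates the structural layout of a small-bodied,
long-tailed early archosauriform: a pelvis root with six free d.f.
against the ground, three rotational hip d.f., one flexion/extension
d.f. each at the knee, ankle and metatarsophalangeal (MTP) joints, and
pitch + yaw at a proximal and a mid-tail joint (16 active d.f.), with
locked pitch d.f. at the trunk, neck and head joints (3 locked).  The
full muscle set has 36 named hindlimb muscles partitioned into ten
functional groups; a reduced set keeps one representative per group
(carrying its group's summed mass) for fast tests.

Segment shapes are capsules (closed, watertight, exactly integrable)
with a lung cavity inside the trunk; the mass-property mathematics is
identical to arbitrary hulls.  All stochastic elements (architecture
jitter, attachment patches, trees, characters) are pure functions of the
config seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import trimesh
from dendropy.simulate import treesim

from .asr import CharacterData, DatedTree, MkModelSpec, transition_matrices
from .mesh import MeshBody
from .model import (DoF, JointSpec, Pose, SegmentSpec, SkeletonModel,
                    forward_kinematics, transform_point)
from .muscles import (ArchitectureRow, MuscleParameters, MusclePath,
                      MUSCLE_DENSITY, attachment_centroid, fmax_from_mass,
                      parameters_from_architecture, scale_architecture)
from .statics import ReserveActuator

X, Y, Z = np.eye(3)

# -- the 36 hindlimb muscles and their functional groups -------------------

MUSCLE_GROUP_MAP: dict[str, str] = {
    "IF": "hip abd.",
    "ADD1": "hip add.", "ADD2": "hip add.", "PIFE1": "hip add.",
    "PIFE2": "hip add.", "PIFE3": "hip add.", "PIT": "hip add.",
    "PIFI1": "hip flex.", "PIFI2": "hip flex.", "AMB": "hip flex.",
    "CFB": "hip ext.", "CFL": "hip ext.", "ISTR": "hip ext.",
    "FTE": "hip ext.", "FTI1": "hip ext.", "FTI2": "hip ext.",
    "FTI3": "hip ext.", "ILFB": "hip ext.",
    "IT1": "knee ext.", "IT2": "knee ext.", "FMTE": "knee ext.",
    "FMTI": "knee ext.",
    # IT3 acts as knee abductor/flexor rather than extensor and is kept
    # out of the knee-extensor group
    "IT3": "knee flex.",
    "GL": "ankle plan.", "GM": "ankle plan.", "FDL": "ankle plan.",
    "FHL": "ankle plan.", "PL": "ankle plan.", "PP": "ankle plan.",
    "TC": "ankle dorsi.", "EDL": "ankle dorsi.", "PB": "ankle dorsi.",
    "FDBP": "dig. plan.", "FDBS": "dig. plan.", "AHD": "dig. plan.",
    "EDB": "dig. dorsi.",
}

MUSCLE_NAMES = tuple(MUSCLE_GROUP_MAP)

REDUCED_SET = ("IF", "ADD1", "PIFI2", "ISTR", "IT1", "IT3", "GL", "TC",
               "FDBP", "EDB")

CONSTRAINED_DOFS = ("hip_flexion", "hip_abduction", "hip_rotation",
                    "knee_flexion", "ankle_flexion", "mtp_flexion",
                    "tail_prox_pitch", "tail_prox_yaw",
                    "tail_mid_pitch", "tail_mid_yaw")

RESERVE_DOFS = ("mtp_flexion", "tail_prox_pitch", "tail_prox_yaw",
                "tail_mid_pitch", "tail_mid_yaw")

DEFAULT_MASS_FRACTIONS = {
    "pelvis": 0.09, "trunk": 0.53, "neck": 0.05, "head": 0.07,
    "tail1": 0.08, "tail2": 0.06, "thigh": 0.06, "shank": 0.035,
    "pes": 0.015, "toes": 0.01,
}

# segment capsule layout: (parent joint, parent segment, joint location in
# parent frame, distal end in own frame, radius)
_SEGMENT_GEOMETRY = {
    "pelvis": (None, None, (0.0, 0.22, 0.0), (0.05, 0.0, 0.0), 0.030),
    "trunk": ("trunk_joint", "pelvis", (0.05, 0.01, 0.0), (0.40, 0.0, 0.0), 0.055),
    "neck": ("neck_joint", "trunk", (0.40, 0.01, 0.0), (0.10, 0.02, 0.0), 0.022),
    "head": ("head_joint", "neck", (0.10, 0.02, 0.0), (0.11, 0.0, 0.0), 0.028),
    "tail1": ("tail_prox", "pelvis", (-0.05, 0.005, 0.0), (-0.28, -0.01, 0.0), 0.028),
    "tail2": ("tail_mid", "tail1", (-0.28, -0.01, 0.0), (-0.30, -0.02, 0.0), 0.016),
    "thigh": ("hip", "pelvis", (0.0, -0.02, 0.04), (0.125, -0.085, 0.015), 0.020),
    "shank": ("knee", "thigh", (0.125, -0.085, 0.015), (-0.068, -0.088, 0.005), 0.014),
    "pes": ("ankle", "shank", (-0.068, -0.088, 0.005), (0.05, -0.024, 0.0), 0.010),
    "toes": ("mtp", "pes", (0.05, -0.024, 0.0), (0.04, -0.003, 0.0), 0.007),
}

_JOINT_DOFS = {
    None: [("pelvis_tx", X, "translation", False), ("pelvis_ty", Y, "translation", False),
           ("pelvis_tz", Z, "translation", False), ("pelvis_pitch", Z, "rotation", False),
           ("pelvis_yaw", Y, "rotation", False), ("pelvis_roll", X, "rotation", False)],
    "trunk_joint": [("trunk_pitch", Z, "rotation", True)],
    "neck_joint": [("neck_pitch", Z, "rotation", True)],
    "head_joint": [("head_pitch", Z, "rotation", True)],
    "tail_prox": [("tail_prox_pitch", Z, "rotation", False),
                  ("tail_prox_yaw", Y, "rotation", False)],
    "tail_mid": [("tail_mid_pitch", Z, "rotation", False),
                 ("tail_mid_yaw", Y, "rotation", False)],
    "hip": [("hip_flexion", Z, "rotation", False),
            ("hip_abduction", X, "rotation", False),
            ("hip_rotation", Y, "rotation", False)],
    "knee": [("knee_flexion", Z, "rotation", False)],
    "ankle": [("ankle_flexion", Z, "rotation", False)],
    "mtp": [("mtp_flexion", Z, "rotation", False)],
}

# muscle routing: origin (segment, point), optional vias, insertion
_MUSCLE_ROUTES = {
    "IF":    [("pelvis", (0.000, 0.015, 0.060)), ("thigh", (-0.006, -0.028, 0.032))],
    "ADD1":  [("pelvis", (-0.020, -0.045, 0.015)), ("thigh", (0.035, -0.055, 0.005))],
    "ADD2":  [("pelvis", (-0.030, -0.045, 0.012)), ("thigh", (0.045, -0.070, 0.003))],
    "PIFE1": [("pelvis", (0.005, -0.050, 0.010)), ("thigh", (-0.002, -0.012, 0.040))],
    "PIFE2": [("pelvis", (-0.010, -0.050, 0.008)), ("thigh", (-0.002, -0.014, 0.040))],
    "PIFE3": [("pelvis", (-0.020, -0.048, 0.010)), ("thigh", (-0.001, -0.016, 0.040))],
    "PIT":   [("pelvis", (-0.015, -0.050, 0.008)), ("thigh", (0.070, -0.085, -0.004)),
              ("shank", (0.008, -0.012, -0.004))],
    "PIFI1": [("pelvis", (0.020, -0.010, 0.020)), ("thigh", (0.020, -0.020, 0.010))],
    "PIFI2": [("pelvis", (0.045, 0.000, 0.025)), ("thigh", (0.025, -0.030, 0.018))],
    "AMB":   [("pelvis", (0.030, -0.040, 0.020)), ("thigh", (0.140, -0.063, 0.015)),
              ("shank", (0.012, -0.004, 0.008))],
    "CFB":   [("pelvis", (-0.045, -0.010, 0.015)), ("thigh", (0.030, -0.050, 0.000))],
    "CFL":   [("tail1", (-0.090, -0.020, 0.012)), ("thigh", (0.040, -0.055, -0.008))],
    "ISTR":  [("pelvis", (-0.040, -0.028, 0.006)), ("thigh", (-0.006, -0.010, 0.036))],
    "FTE":   [("pelvis", (-0.040, -0.035, 0.012)), ("thigh", (0.100, -0.100, -0.008)),
              ("shank", (-0.010, -0.015, 0.000))],
    "FTI1":  [("pelvis", (-0.030, -0.040, 0.008)), ("thigh", (0.095, -0.098, -0.010)),
              ("shank", (-0.008, -0.018, -0.005))],
    "FTI2":  [("pelvis", (-0.035, -0.042, 0.006)), ("thigh", (0.090, -0.100, -0.012)),
              ("shank", (-0.006, -0.020, -0.006))],
    "FTI3":  [("pelvis", (-0.025, -0.045, 0.010)), ("thigh", (0.098, -0.096, -0.006)),
              ("shank", (-0.010, -0.012, -0.003))],
    "ILFB":  [("pelvis", (-0.030, 0.005, 0.045)), ("thigh", (0.105, -0.095, 0.022)),
              ("shank", (-0.005, -0.020, 0.012))],
    "IT1":   [("pelvis", (0.025, 0.012, 0.048)), ("thigh", (0.140, -0.065, 0.015)),
              ("shank", (0.012, -0.005, 0.008))],
    "IT2":   [("pelvis", (0.005, 0.014, 0.050)), ("thigh", (0.140, -0.067, 0.016)),
              ("shank", (0.012, -0.004, 0.008))],
    "IT3":   [("pelvis", (-0.015, 0.012, 0.048)), ("thigh", (0.100, -0.080, 0.030)),
              ("shank", (0.002, -0.010, 0.015))],
    "FMTE":  [("thigh", (0.040, -0.045, 0.012)), ("thigh", (0.142, -0.062, 0.013)),
              ("shank", (0.011, -0.004, 0.006))],
    "FMTI":  [("thigh", (0.035, -0.050, 0.002)), ("thigh", (0.141, -0.064, 0.010)),
              ("shank", (0.011, -0.005, 0.004))],
    "GL":    [("thigh", (0.118, -0.092, 0.018)), ("shank", (-0.082, -0.080, 0.006)),
              ("pes", (-0.022, -0.008, 0.002))],
    "GM":    [("thigh", (0.112, -0.095, 0.002)), ("shank", (-0.083, -0.078, 0.000)),
              ("pes", (-0.021, -0.010, -0.002))],
    "FDL":   [("shank", (-0.015, -0.020, 0.000)), ("pes", (-0.017, -0.011, 0.000)),
              ("pes", (0.030, -0.014, 0.000)), ("toes", (0.012, -0.006, 0.000))],
    "FHL":   [("shank", (-0.012, -0.025, -0.003)), ("pes", (-0.016, -0.0115, -0.002)),
              ("pes", (0.030, -0.013, -0.002)), ("toes", (0.010, -0.0055, -0.003))],
    "PL":    [("shank", (-0.005, -0.030, 0.012)), ("shank", (-0.080, -0.082, 0.010)),
              ("pes", (-0.016, -0.010, 0.006)), ("pes", (0.020, -0.010, 0.005))],
    "PP":    [("shank", (-0.018, -0.040, -0.004)), ("pes", (-0.016, -0.010, -0.004)),
              ("pes", (0.018, -0.010, -0.004))],
    "TC":    [("shank", (0.010, -0.010, 0.004)), ("pes", (0.014, 0.004, 0.003))],
    "EDL":   [("shank", (0.008, -0.015, 0.006)), ("pes", (0.014, 0.005, 0.004)),
              ("toes", (0.008, 0.004, 0.002))],
    "PB":    [("shank", (-0.010, -0.055, 0.012)), ("pes", (0.000, 0.001, 0.008)),
              ("pes", (0.015, -0.002, 0.007))],
    "FDBP":  [("pes", (0.005, -0.011, 0.001)), ("toes", (0.010, -0.006, 0.001))],
    "FDBS":  [("pes", (0.008, -0.012, 0.002)), ("toes", (0.015, -0.0055, 0.002))],
    "AHD":   [("pes", (0.010, -0.010, -0.004)), ("toes", (0.012, -0.005, -0.004))],
    "EDB":   [("pes", (0.015, 0.002, 0.002)), ("toes", (0.012, 0.0045, 0.002))],
}


# architecture template at the source analog's body mass (kg, m)
_SOURCE_BODY_MASS = 10.0
_ARCH_TEMPLATE = {  # muscle: (muscle mass, optimal fibre length)
    "IF": (0.070, 0.035), "ADD1": (0.030, 0.045), "ADD2": (0.028, 0.045),
    "PIFE1": (0.030, 0.035), "PIFE2": (0.028, 0.035), "PIFE3": (0.026, 0.035),
    "PIT": (0.020, 0.050), "PIFI1": (0.025, 0.035), "PIFI2": (0.035, 0.040),
    "CFB": (0.040, 0.040), "CFL": (0.130, 0.065), "ISTR": (0.040, 0.025),
    "AMB": (0.022, 0.050), "IT1": (0.030, 0.055), "IT2": (0.032, 0.055),
    "IT3": (0.028, 0.055), "FMTE": (0.040, 0.045), "FMTI": (0.038, 0.045),
    "FTE": (0.045, 0.055), "FTI1": (0.030, 0.050), "FTI2": (0.025, 0.050),
    "FTI3": (0.022, 0.050), "ILFB": (0.040, 0.055), "FDL": (0.020, 0.030),
    "FHL": (0.018, 0.028), "GL": (0.040, 0.030), "GM": (0.038, 0.030),
    "PL": (0.014, 0.025), "PP": (0.012, 0.022), "EDL": (0.014, 0.030),
    "PB": (0.010, 0.020), "TC": (0.016, 0.028), "FDBP": (0.005, 0.010),
    "FDBS": (0.004, 0.010), "AHD": (0.003, 0.008), "EDB": (0.004, 0.010),
}


@dataclass
class SynthConfig:
    """Generator configuration; every stochastic choice derives from
    `seed`."""

    seed: int
    body_mass: float = 8.0  # kg
    muscle_set: str = "full"  # full (36 muscles) | reduced (10)
    mesh_sections: int = 12
    tissue_density: float = 1000.0  # kg m^-3
    mass_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MASS_FRACTIONS))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment mass fractions must sum to 1, got {total}")
        if self.muscle_set not in ("full", "reduced"):
            raise ValueError("muscle_set must be 'full' or 'reduced'")

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return MUSCLE_NAMES if self.muscle_set == "full" else REDUCED_SET


def _capsule_between(a, b, radius: float, sections: int) -> trimesh.Trimesh:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    direction = b - a
    height = float(np.linalg.norm(direction))
    mesh = trimesh.creation.capsule(height=height, radius=radius,
                                    count=[sections, sections])
    T = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], direction / height)
    T = np.asarray(T, dtype=float)
    T[:3, 3] = (a + b) / 2.0
    mesh.apply_transform(T)
    return mesh


def _segment_meshes(config: SynthConfig) -> dict[str, tuple[list, list]]:
    out = {}
    for name, (_, _, _, distal, radius) in _SEGMENT_GEOMETRY.items():
        cap = _capsule_between(np.zeros(3), distal, radius, config.mesh_sections)
        body = MeshBody(cap.vertices, cap.faces, config.tissue_density,
                        "body", f"{name}_hull")
        cavities = []
        if name == "trunk":  # lung / air-sac cavity inside the trunk hull
            lung = _capsule_between((0.18, 0.01, 0.0), (0.34, 0.01, 0.0),
                                    0.028, config.mesh_sections)
            cavities.append(MeshBody(lung.vertices, lung.faces,
                                     config.tissue_density, "cavity",
                                     "trunk_lung"))
        out[name] = ([body], cavities)
    return out


@dataclass
class HindlimbModel:
    """The generated model bundle: skeleton, per-method muscle sets and
    parameters, architecture, groups, actuator layout and the GRF COP."""

    model: SkeletonModel
    muscle_sets: dict[str, list[MusclePath]]
    parameters: dict[str, dict[str, MuscleParameters]]
    architecture: list[ArchitectureRow]
    groups: dict[str, list[str]]
    constrained_dofs: list[str]
    reserve_dofs: list[str]
    cop: np.ndarray
    stance_segment: str
    config: SynthConfig

    @property
    def n_muscles(self) -> int:
        return len(next(iter(self.muscle_sets.values())))

    @property
    def n_reserves(self) -> int:
        return len(self.reserve_dofs)

    def muscles(self, method: str = "model3_arithmetic") -> list[MusclePath]:
        return self.muscle_sets[method]

    def reserves(self, torque: float) -> list[ReserveActuator]:
        return [ReserveActuator(f"reserve_{d}", d, torque)
                for d in self.reserve_dofs]


def _attachment_patch(rng: np.random.Generator, centre: np.ndarray,
                      n: int = 12, radius: float = 0.004) -> np.ndarray:
    """A quasi-planar scatter of attachment-site vertices around a
    nominal centre (random patch plane orientation, seeded)."""
    normal = rng.normal(size=3)
    normal /= np.linalg.norm(normal)
    u = np.cross(normal, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(normal, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    r = radius * np.sqrt(rng.uniform(0.05, 1.0, n))
    th = rng.uniform(0, 2 * np.pi, n)
    bumps = rng.normal(scale=radius * 0.05, size=n)
    return (centre + r[:, None] * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)
            + bumps[:, None] * normal)


_CENTROID_METHOD = {"model1_alpha": "model1_alpha", "model2_hull": "model2_hull",
                    "model3_arithmetic": "model3_arithmetic",
                    "model4_volumetric": "model3_arithmetic"}


def generate_hindlimb_model(config: SynthConfig) -> HindlimbModel:
    """Build the full synthetic model: skeleton with 16 active + 3
    locked d.f., the muscle set routed per estimation method (attachment
    patches re-centroided per method), architecture-derived and
    volumetric muscle parameters, and the stance-foot COP."""
    meshes = _segment_meshes(config)
    segments, joints = [], []
    for name, (pjoint, pseg, location, _distal, _r) in _SEGMENT_GEOMETRY.items():
        jname = pjoint if pjoint is not None else "ground_pelvis"
        dofs = [DoF(dn, axis, kind, locked)
                for dn, axis, kind, locked in _JOINT_DOFS[pjoint]]
        joints.append(JointSpec(jname, pseg, name, np.array(location), dofs))
        body, cavities = meshes[name]
        segments.append(SegmentSpec(
            name, jname, body, cavities,
            mass_override=config.mass_fractions[name] * config.body_mass))
    model = SkeletonModel(
        segments, joints,
        body_group=("trunk", "neck", "head"), tail_group=("tail1", "tail2"),
        body_pivot_joint="trunk_joint", tail_pivot_joint="tail_prox",
        name=f"synthetic_hindlimb_seed{config.seed}")

    # stance-foot centre of pressure: centroid of the MTP-to-toe-tip
    # contact patch, projected to the ground plane
    transforms = forward_kinematics(model, model.default_pose())
    ankle_w = transform_point(transforms["pes"], np.zeros(3))
    tip_w = transform_point(transforms["toes"],
                            np.asarray(_SEGMENT_GEOMETRY["toes"][3]))
    # whole plantar surface contacts in the crouched early-stance pose
    cop = (ankle_w + tip_w) / 2.0
    cop[1] = 0.0

    architecture = generate_architecture_table(config)
    arch_by_name = {r.muscle: r for r in architecture}

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    patches: dict[tuple[str, int], np.ndarray] = {}
    names = config.muscle_names
    for mname in names:
        route = _MUSCLE_ROUTES[mname]
        for end in (0, len(route) - 1):
            patches[(mname, end)] = _attachment_patch(
                rng, np.asarray(route[end][1], dtype=float))

    muscle_sets: dict[str, list[MusclePath]] = {}
    parameters: dict[str, dict[str, MuscleParameters]] = {}
    for method in ("model1_alpha", "model2_hull", "model3_arithmetic",
                   "model4_volumetric"):
        paths = []
        for mname in names:
            route = _MUSCLE_ROUTES[mname]
            pts = [np.asarray(p, dtype=float) for _s, p in route]
            segs = [s for s, _p in route]
            pts[0] = attachment_centroid(patches[(mname, 0)],
                                         _CENTROID_METHOD[method])
            pts[-1] = attachment_centroid(patches[(mname, len(route) - 1)],
                                          _CENTROID_METHOD[method])
            paths.append(MusclePath(mname, list(zip(segs, pts)),
                                    MUSCLE_GROUP_MAP[mname]))
        muscle_sets[method] = paths
        if method != "model4_volumetric":
            parameters[method] = parameters_from_architecture(
                architecture, method, config.body_mass)

    # volumetric method: muscle masses from capsule belly meshes sized to
    # anatomical belly volumes (volumetric reconstructions recover whole
    # bellies and systematically exceed literature-scaled masses)
    vol_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    transforms0 = transforms
    params4 = {}
    for path in muscle_sets["model4_volumetric"]:
        world = [transform_point(transforms0[s], p) for s, p in path.via_points]
        chord = float(sum(np.linalg.norm(b - a)
                          for a, b in zip(world[:-1], world[1:])))
        arch = scale_architecture(arch_by_name[path.name], config.body_mass)
        target_volume = (2.0 * arch.muscle_mass / MUSCLE_DENSITY
                         * vol_rng.lognormal(0.0, 0.10))
        radius = _capsule_radius_for_volume(target_volume, chord)
        belly = _capsule_between(world[0], world[-1], radius,
                                 config.mesh_sections)
        mass = float(belly.volume) * MUSCLE_DENSITY
        l_o = max(0.35 * chord, 0.005)
        params4[path.name] = MuscleParameters(
            path.name, "model4_volumetric",
            f_max=fmax_from_mass(mass, l_o), optimal_fibre_length=l_o)
    parameters["model4_volumetric"] = params4

    groups: dict[str, list[str]] = {}
    for mname in names:
        groups.setdefault(MUSCLE_GROUP_MAP[mname], []).append(mname)

    return HindlimbModel(model, muscle_sets, parameters, architecture, groups,
                         list(CONSTRAINED_DOFS), list(RESERVE_DOFS), cop,
                         "toes", config)


def _capsule_radius_for_volume(volume: float, length: float) -> float:
    """Radius of a capsule of given cylinder length and total volume."""
    roots = np.roots([4.0 / 3.0 * np.pi, np.pi * length, 0.0, -volume])
    real = roots[np.isreal(roots)].real
    r = float(real[real > 0].min())
    return max(r, 1e-4)


def generate_architecture_table(config: SynthConfig) -> list[ArchitectureRow]:
    """Seeded architecture rows at the source analog's body mass.

    Masses are log-normal around anatomically ranked template means
    (proximal muscles heavier than distal); fibre lengths correlate with
    the template (hence with segment length).  The reduced set's single
    representative per group carries its group's summed mass so its
    torque capacity is comparable to the full set's.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    group_mass = {}
    for m, (mass, _l) in _ARCH_TEMPLATE.items():
        group_mass[MUSCLE_GROUP_MAP[m]] = group_mass.get(MUSCLE_GROUP_MAP[m], 0.0) + mass
    rows = []
    for mname in config.muscle_names:
        mass, l_o = _ARCH_TEMPLATE[mname]
        if config.muscle_set == "reduced":
            mass = group_mass[MUSCLE_GROUP_MAP[mname]]
        rows.append(ArchitectureRow(
            muscle=mname,
            muscle_mass=mass * rng.lognormal(0.0, 0.08),
            optimal_fibre_length=l_o * rng.lognormal(0.0, 0.05),
            pennation=0.0,
            source_body_mass=_SOURCE_BODY_MASS))
    return rows


# -- postures, GRF, trees --------------------------------------------------

POSTURE_KNOTS = (0.0, 25.0, 50.0, 75.0)

#: Illustrative extant-bipedal-lizard (BA, TA) posture points: low body
#: angles, moderate tail angles.  Fixture values, not literature data.
LIZARD_POSTURES = ((10.0, 25.0), (15.0, 35.0), (20.0, 20.0),
                   (25.0, 40.0), (30.0, 30.0), (35.0, 15.0))


def generate_posture_set(model: SkeletonModel | None = None,
                         knots=POSTURE_KNOTS) -> dict:
    """The 16 body x tail angle poses, the early-stance limb pose and the
    lizard-style reference points.

    The model's articulated reference pose already encodes the crouched
    early-stance limb configuration, so the limb joint coordinates are
    zero offsets from it.
    """
    limb = {d.name: 0.0 for _, d in model.active_dofs()} if model else {}
    grid = [Pose(dict(limb), body_angle=ba, tail_angle=ta)
            for ba in knots for ta in knots]
    return {"grid": grid,
            "early_stance": Pose(dict(limb), 0.0, 0.0),
            "lizard_points": list(LIZARD_POSTURES)}


def generate_grf_fixture(profile: str = "early-skewed", peak_bw: float = 2.0,
                         medial_deg: float = 14.0, cranial_deg: float = 8.0,
                         n_samples: int = 101) -> dict:
    """A GRF specification: peak magnitude (consumed by the static
    analyses) plus a stance-phase magnitude profile for documentation.

    The early-skewed profile emulates the vertical-force asymmetry of
    bipedally running lizards and birds (peak before mid-stance)."""
    if peak_bw <= 0:
        raise ValueError("peak magnitude must be positive")
    t = np.linspace(0.0, 1.0, n_samples)
    if profile == "flat":
        mag = np.full_like(t, peak_bw)
    elif profile == "early-skewed":
        tp = 0.3  # peak at 30% of stance
        with np.errstate(divide="ignore", invalid="ignore"):
            shape = (t / tp) ** 2 * np.exp(2.0 * (1.0 - t / tp))
        mag = peak_bw * np.nan_to_num(shape) * (t <= 1.0)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return {"profile": profile, "peak_bw": peak_bw, "medial_deg": medial_deg,
            "cranial_deg": cranial_deg, "stance_fraction": t,
            "magnitude_bw": mag}


def simulate_characters(tree: DatedTree, spec: MkModelSpec, rates,
                        rng: np.random.Generator,
                        root_state: int | None = None) -> dict[int, int]:
    """Simulate one discrete character down the tree under the Mk
    process; returns node index -> state."""
    Q = spec.rate_matrix(np.asarray(rates, dtype=float))
    P = transition_matrices(Q, tree.branch_lengths)
    k = spec.n_states
    states: dict[int, int] = {}
    if root_state is None:
        root_state = int(rng.integers(k))
    states[tree.root] = root_state
    for i in reversed(range(tree.n_nodes)):  # preorder
        for c in tree.children[i]:
            p = np.clip(P[c][states[i]], 0.0, None)
            states[c] = int(rng.choice(k, p=p / p.sum()))
    return states


def generate_tree_with_characters(n_tips: int, spec: MkModelSpec, rates,
                                  seed: int, birth_rate: float = 0.05,
                                  death_rate: float = 0.02,
                                  fossil_fraction: float = 0.5,
                                  ambiguous_fraction: float = 0.1,
                                  root_state: int | None = 0,
                                  ) -> tuple[DatedTree, CharacterData]:
    """A birth-death tree with fossil (shortened, non-contemporaneous)
    tips and Mk-simulated tip states; a seeded fraction of tips is
    recorded as ambiguous (flat weight vector).  Deterministic given the
    seed.  Branch lengths are Myr at the stated per-Myr rates."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, rng=random.Random(seed))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    for leaf in dtree.leaf_node_iter():
        if rng.uniform() < fossil_fraction and leaf.edge.length:
            leaf.edge.length *= float(rng.uniform(0.2, 0.9))
    tree = DatedTree(dtree)
    states = simulate_characters(tree, spec, rates, rng, root_state)
    tip_states: dict[str, int | str] = {}
    for i in tree.tip_indices:
        label = tree.labels[i]
        if rng.uniform() < ambiguous_fraction:
            tip_states[label] = "ambiguous"
        else:
            tip_states[label] = states[i]
    return tree, CharacterData.from_states(tip_states, spec.n_states)
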