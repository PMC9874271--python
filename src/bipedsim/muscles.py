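"""Muscle paths, moment arms and architectural parameter estimation.

Muscles are modelled as piecewise-straight via-point paths fixed in
segment frames.  A muscle's moment arm about a rotational degree of
freedom follows the tendon-excursion definition r = -dL/dq.  Maximal
isometric force is derived from muscle mass, optimal fibre length and a
specific tension, F_max = sigma * (m / (rho * l_o)) * cos(pennation),
ignoring force-length-velocity effects (forces are a_i * F_max,i at any
fibre length).

Four estimation methods are distinguished for how attachment sites (and,
for the volumetric method, muscle masses) are derived:
``model1_alpha`` (alpha-shape centroid of the attachment patch),
``model2_hull`` (convex-hull centroid), ``model3_arithmetic``
(arithmetic vertex mean) and ``model4_volumetric`` (masses from
volumetric muscle meshes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

from .model import Pose, SkeletonModel, forward_kinematics, transform_point

MUSCLE_DENSITY = 1060.0  # kg m^-3
SPECIFIC_TENSION = 3.0e5  # Pa
FD_STEP_RAD = 1e-4  # central-difference step for moment arms

ESTIMATION_METHODS = ("model1_alpha", "model2_hull", "model3_arithmetic",
                      "model4_volumetric")

#: The ten functional muscle groups used for reporting mean activations.
MUSCLE_GROUPS = (
    "hip abd.", "hip add.", "hip flex.", "hip ext.", "knee ext.",
    "knee flex.", "ankle plan.", "ankle dorsi.", "dig. plan.", "dig. dorsi.",
)


@dataclass
class MusclePath:
    """An actuator path: ordered via points fixed in segment frames."""

    name: str
    via_points: list[tuple[str, np.ndarray]]  # (segment, local 3-vector)
    group: str = ""

    def __post_init__(self) -> None:
        self.via_points = [(seg, np.asarray(p, dtype=float).reshape(3))
                           for seg, p in self.via_points]
        if len(self.via_points) < 2:
            raise ValueError(f"muscle {self.name!r}: needs at least two via points")
        if self.via_points[0][0] == self.via_points[-1][0]:
            raise ValueError(
                f"muscle {self.name!r}: origin and insertion must be on "
                "different segments")
        if self.group and self.group not in MUSCLE_GROUPS:
            raise ValueError(f"muscle {self.name!r}: unknown group {self.group!r}")


@dataclass
class ArchitectureRow:
    """One published-architecture table row (at the source animal's mass)."""

    muscle: str
    muscle_mass: float  # kg
    optimal_fibre_length: float  # m
    pennation: float = 0.0  # degrees
    source_body_mass: float = 1.0  # kg

    def __post_init__(self) -> None:
        if self.muscle_mass <= 0 or self.optimal_fibre_length <= 0 \
                or self.source_body_mass <= 0:
            raise ValueError(f"architecture row {self.muscle!r}: "
                             "masses and fibre length must be positive")
        if not 0.0 <= self.pennation <= 45.0:
            raise ValueError(f"architecture row {self.muscle!r}: "
                             "pennation must be within [0, 45] degrees")


@dataclass
class MuscleParameters:
    muscle: str
    method: str
    f_max: float  # N
    optimal_fibre_length: float  # m

    def __post_init__(self) -> None:
        if self.method not in ESTIMATION_METHODS:
            raise ValueError(f"unknown estimation method {self.method!r}")
        if self.f_max <= 0 or self.optimal_fibre_length <= 0:
            raise ValueError(f"parameters for {self.muscle!r} must be positive")


# -- path geometry ---------------------------------------------------------

def _posed_points(transforms: dict[str, np.ndarray],
                  muscle: MusclePath) -> np.ndarray:
    pts = []
    for seg, local in muscle.via_points:
        if seg not in transforms:
            raise KeyError(f"muscle {muscle.name!r}: unresolvable segment {seg!r}")
        pts.append(transform_point(transforms[seg], local))
    return np.array(pts)


def mtu_length(model: SkeletonModel, pose: Pose, muscle: MusclePath) -> float:
    """Muscle-tendon unit length: summed segment-to-segment distances."""
    pts = _posed_points(forward_kinematics(model, pose), muscle)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def moment_arm(model: SkeletonModel, pose: Pose, muscle: MusclePath,
               dof_name: str, step_rad: float = FD_STEP_RAD) -> float:
    """Tendon-excursion moment arm r = -dL/dq about a rotational d.f.

    Central finite difference in the joint coordinate; positive r means
    the muscle generates positive moment about the d.f. axis.
    """
    dof = model.get_dof(dof_name)
    if dof.kind != "rotation":
        raise ValueError(f"d.f. {dof_name!r} is translational: muscles have no "
                         "moment arm about pelvis translations")
    if dof.locked:
        raise ValueError(f"d.f. {dof_name!r} is locked")
    q0 = pose.values[dof_name]
    h = np.rad2deg(step_rad)
    lp = mtu_length(model, pose.with_value(dof_name, q0 + h), muscle)
    lm = mtu_length(model, pose.with_value(dof_name, q0 - h), muscle)
    return -(lp - lm) / (2.0 * step_rad)


# -- attachment centroids --------------------------------------------------

def _plane_basis(points: np.ndarray):
    """Best-fit plane (SVD): returns (origin, 2x3 in-plane basis) or None
    when the patch is rank-deficient (a point or a line)."""
    c = points.mean(axis=0)
    centred = points - c
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if len(s) < 2 or s[1] < 1e-12 * max(1.0, s[0]):
        return None
    return c, vt[:2]


def _polygon_area_centroid(verts2d: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed area and area centroid of a simple polygon (shoelace)."""
    x, y = verts2d[:, 0], verts2d[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return area, np.array([cx, cy])


def attachment_centroid(patch_vertices: np.ndarray, method: str,
                        alpha: float | None = None) -> np.ndarray:
    """Centroid of an attachment-site vertex patch under a given method.

    model1_alpha: area centroid of the 2-D alpha shape of the patch
    projected on its best-fit plane (alpha defaults to twice the median
    nearest-neighbour spacing); model2_hull: area centroid of the convex
    hull; model3_arithmetic / model4_volumetric: arithmetic vertex mean.
    Degenerate patches (fewer than 3 points, collinear) fall back to the
    arithmetic mean for every method.
    """
    pts = np.asarray(patch_vertices, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty attachment patch")
    if method in ("model3_arithmetic", "model4_volumetric") or len(pts) < 3:
        return pts.mean(axis=0)
    basis = _plane_basis(pts)
    if basis is None:
        return pts.mean(axis=0)
    origin, B = basis
    p2 = (pts - origin) @ B.T

    if method == "model2_hull":
        hull = ConvexHull(p2)
        _, c2 = _polygon_area_centroid(p2[hull.vertices])
        return origin + c2 @ B

    if method == "model1_alpha":
        if alpha is None:
            d = np.linalg.norm(p2[:, None] - p2[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            alpha = 2.0 * float(np.median(d.min(axis=1)))
        tri = Delaunay(p2)
        areas, centroids = [], []
        for simplex in tri.simplices:
            a, b, c = p2[simplex]
            ab, ac, bc = b - a, c - a, c - b
            area2 = abs(ab[0] * ac[1] - ab[1] * ac[0])
            if area2 < 1e-15:
                continue
            circumradius = (np.linalg.norm(ab) * np.linalg.norm(ac)
                            * np.linalg.norm(bc)) / (2.0 * area2)
            if circumradius <= alpha:
                areas.append(area2 / 2.0)
                centroids.append((a + b + c) / 3.0)
        if not areas:  # alpha too tight: degenerate to the convex hull
            return attachment_centroid(pts, "model2_hull")
        areas = np.array(areas)
        c2 = (areas[:, None] * np.array(centroids)).sum(axis=0) / areas.sum()
        return origin + c2 @ B

    raise ValueError(f"unknown centroid method {method!r}")


# -- architecture scaling and F_max ---------------------------------------

def scale_architecture(row: ArchitectureRow, target_mass: float) -> ArchitectureRow:
    """Geometric-similarity scaling to a target body mass: muscle mass
    scales linearly with body mass, fibre length with its cube root."""
    if target_mass <= 0:
        raise ValueError("target body mass must be positive")
    ratio = target_mass / row.source_body_mass
    return replace(row,
                   muscle_mass=row.muscle_mass * ratio,
                   optimal_fibre_length=row.optimal_fibre_length * ratio ** (1 / 3),
                   source_body_mass=target_mass)


def fmax_from_mass(muscle_mass: float, optimal_fibre_length: float,
                   specific_tension: float = SPECIFIC_TENSION,
                   muscle_density: float = MUSCLE_DENSITY,
                   pennation_deg: float = 0.0) -> float:
    """F_max = sigma * PCSA * cos(pennation), PCSA = m / (rho * l_o)."""
    if optimal_fibre_length <= 0:
        raise ValueError("optimal fibre length must be positive")
    if muscle_mass <= 0 or specific_tension <= 0 or muscle_density <= 0:
        raise ValueError("muscle mass, specific tension and density must be positive")
    if not 0.0 <= pennation_deg <= 45.0:
        raise ValueError("pennation must be within [0, 45] degrees")
    pcsa = muscle_mass / (muscle_density * optimal_fibre_length)
    return specific_tension * pcsa * float(np.cos(np.deg2rad(pennation_deg)))


def parameters_from_architecture(rows: list[ArchitectureRow], method: str,
                                 target_body_mass: float,
                                 specific_tension: float = SPECIFIC_TENSION,
                                 muscle_density: float = MUSCLE_DENSITY,
                                 ) -> dict[str, MuscleParameters]:
    """Body-mass-scaled F_max and l_o for every architecture row."""
    out = {}
    for row in rows:
        scaled = scale_architecture(row, target_body_mass)
        out[row.muscle] = MuscleParameters(
            muscle=row.muscle, method=method,
            f_max=fmax_from_mass(scaled.muscle_mass, scaled.optimal_fibre_length,
                                 specific_tension, muscle_density, scaled.pennation),
            optimal_fibre_length=scaled.optimal_fibre_length)
    return out
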