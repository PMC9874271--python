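"""Roll and pitch moments of the GRF about the whole-body centre of mass.

The moment of the GRF about the COM, tau = r x F with r = COP - COM, is
computed along each COM principal axis two equivalent ways: directly as
the cross product, and geometrically as the signed shortest distance
between two skew lines (the GRF line of action and the axis line through
the COM) scaled by the force component in that axis's plane of rotation.
Both routes must agree to 1e-10 relative.

Sign convention (x cranial, y up, z mediolateral-right): tau_z < 0 is a
nose-down pitch, tau_z > 0 nose-up; tau_x is the roll moment.

The pitch moment is evaluated at a fixed GRF magnitude (default 2 BW)
over the 4 x 4 grid of body and tail angles (0, 25, 50, 75 degrees),
interpolated to a 1-degree surface with tensor-product cubic splines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.spatial import ConvexHull

from .model import SkeletonModel, Pose, composite_mass_properties
from .statics import ExternalLoad

GRID_KNOTS = (0.0, 25.0, 50.0, 75.0)
AXES = {"x": np.array([1.0, 0.0, 0.0]),
        "y": np.array([0.0, 1.0, 0.0]),
        "z": np.array([0.0, 0.0, 1.0])}


@dataclass
class MomentResult:
    """GRF moment about the COM with its per-axis moment arms."""

    torque: np.ndarray  # N m, (tau_x, tau_y, tau_z)
    moment_arms: dict[str, float]  # signed shortest distances, m
    com: np.ndarray
    cop: np.ndarray
    force: np.ndarray

    @property
    def roll(self) -> float:
        return float(self.torque[0])

    @property
    def pitch(self) -> float:
        return float(self.torque[2])


def _axis_moment_skew_lines(com: np.ndarray, cop: np.ndarray, force: np.ndarray,
                            axis: np.ndarray) -> tuple[float, float]:
    """Moment about an axis through the COM via the skew-line geometry.

    Returns (signed moment, signed shortest distance).  The in-plane
    force magnitude is |F x a| for unit axis a; the signed distance
    between the GRF line (through the COP) and the axis line (through
    the COM) along their common normal carries the moment's sign.
    """
    n = np.cross(force, axis)
    n_norm = float(np.linalg.norm(n))
    if n_norm < 1e-300:  # force parallel to the axis: no moment about it
        return 0.0, 0.0
    distance = float((cop - com) @ n) / n_norm
    return distance * n_norm, distance


def com_moment(com: np.ndarray, cop: np.ndarray, force: np.ndarray,
               check_tol: float = 1e-10) -> MomentResult:
    """GRF moment about the COM, cross product and skew-line geometry.

    The two routes are computed independently and must agree to
    `check_tol` relative; disagreement indicates a geometry bug and
    raises.
    """
    com = np.asarray(com, dtype=float).reshape(3)
    cop = np.asarray(cop, dtype=float).reshape(3)
    force = np.asarray(force, dtype=float).reshape(3)
    fmag = np.linalg.norm(force)
    if fmag == 0:
        raise ValueError("zero force: the COM moment is undefined")
    torque = np.cross(cop - com, force)
    scale = max(1.0, float(np.abs(torque).max()),
                fmag * float(np.linalg.norm(cop - com)))
    arms = {}
    for name, axis in AXES.items():
        m_geo, dist = _axis_moment_skew_lines(com, cop, force, axis)
        if abs(m_geo - float(torque @ axis)) > check_tol * scale:
            raise AssertionError(
                f"skew-line and cross-product moments disagree about {name}: "
                f"{m_geo} vs {float(torque @ axis)}")
        arms[name] = dist
    return MomentResult(torque, arms, com, cop, force)


# -- bicubic posture surface ----------------------------------------------

class BicubicSurface:
    """Tensor-product cubic-spline interpolant over the BA x TA knots.

    Built as not-a-knot splines along BA for each TA knot, then a spline
    across TA of those values; exact at the knots.
    """

    def __init__(self, ba_knots, ta_knots, values: np.ndarray) -> None:
        self.ba_knots = np.asarray(ba_knots, dtype=float)
        self.ta_knots = np.asarray(ta_knots, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.ba_knots), len(self.ta_knots)):
            raise ValueError("knot value grid shape mismatch")
        self._ba_splines = CubicSpline(self.ba_knots, self.values, axis=0,
                                       bc_type="not-a-knot")

    def __call__(self, ba: float, ta: float) -> float:
        if not (self.ba_knots[0] - 1e-9 <= ba <= self.ba_knots[-1] + 1e-9
                and self.ta_knots[0] - 1e-9 <= ta <= self.ta_knots[-1] + 1e-9):
            raise ValueError(f"({ba}, {ta}) outside the posture grid")
        along_ta = self._ba_splines(ba)  # values at each TA knot
        return float(CubicSpline(self.ta_knots, along_ta,
                                 bc_type="not-a-knot")(ta))

    def grid(self, step: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ba = np.arange(self.ba_knots[0], self.ba_knots[-1] + 0.5 * step, step)
        ta = np.arange(self.ta_knots[0], self.ta_knots[-1] + 0.5 * step, step)
        at_knot_ta = self._ba_splines(ba)  # len(ba) x len(ta_knots)
        surf = CubicSpline(self.ta_knots, at_knot_ta, axis=1,
                           bc_type="not-a-knot")(ta)
        return ba, ta, surf


@dataclass
class PostureGrid:
    """Pitch (and roll) moments across the body x tail angle grid."""

    ba_knots: tuple
    ta_knots: tuple
    knot_pitch: np.ndarray  # 4 x 4, N m
    knot_roll: np.ndarray
    surface: BicubicSurface
    ba_degrees: np.ndarray
    ta_degrees: np.ndarray
    pitch_surface: np.ndarray  # 76 x 76
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ba in enumerate(self.ba_knots):
            for j, ta in enumerate(self.ta_knots):
                rows.append({"body_angle_deg": ba, "tail_angle_deg": ta,
                             "pitch_moment_nm": self.knot_pitch[i, j],
                             "roll_moment_nm": self.knot_roll[i, j]})
        return pd.DataFrame(rows)


def _summarise(ba, ta, surf, knot_pitch, ba_knots, ta_knots) -> dict:
    i_min = np.unravel_index(np.argmin(surf), surf.shape)
    i_max = np.unravel_index(np.argmax(surf), surf.shape)
    return {
        # spread across tail angles at fixed body angle, and vice versa,
        # reported both on the raw knots and on the 1-degree surface
        "sd_across_ta_knots": float(np.mean(knot_pitch.std(axis=1, ddof=1))),
        "sd_across_ba_knots": float(np.mean(knot_pitch.std(axis=0, ddof=1))),
        "sd_across_ta_surface": float(np.mean(surf.std(axis=1, ddof=1))),
        "sd_across_ba_surface": float(np.mean(surf.std(axis=0, ddof=1))),
        "min_pitch_nm": float(surf[i_min]),
        "min_pitch_at": (float(ba[i_min[0]]), float(ta[i_min[1]])),
        "max_pitch_nm": float(surf[i_max]),
        "max_pitch_at": (float(ba[i_max[0]]), float(ta[i_max[1]])),
    }


def build_posture_grid(model: SkeletonModel, load: ExternalLoad,
                       ba_knots=GRID_KNOTS, ta_knots=GRID_KNOTS,
                       limb_pose: Pose | None = None,
                       segment_overrides: dict | None = None,
                       body_weight_n: float | None = None) -> PostureGrid:
    """Pitch/roll moment at every (BA, TA) knot plus the 1-degree bicubic
    surface.  The limb pose and the COP stay fixed; only the body and
    tail groups re-orient."""
    base = limb_pose if limb_pose is not None else model.default_pose()
    force = load.force_vector if body_weight_n is None else (
        load.magnitude_bw * body_weight_n * load.direction)
    knot_pitch = np.zeros((len(ba_knots), len(ta_knots)))
    knot_roll = np.zeros_like(knot_pitch)
    for i, ba in enumerate(ba_knots):
        for j, ta in enumerate(ta_knots):
            pose = Pose(dict(base.values), body_angle=ba, tail_angle=ta)
            mp = composite_mass_properties(model, pose, segment_overrides)
            res = com_moment(mp.com, load.cop, force)
            knot_pitch[i, j] = res.pitch
            knot_roll[i, j] = res.roll
    surface = BicubicSurface(ba_knots, ta_knots, knot_pitch)
    ba, ta, surf = surface.grid(1.0)
    grid = PostureGrid(tuple(ba_knots), tuple(ta_knots), knot_pitch, knot_roll,
                       surface, ba, ta, surf)
    grid.summary = _summarise(ba, ta, surf, knot_pitch,
                              np.asarray(ba_knots), np.asarray(ta_knots))
    return grid


def find_sign_change(grid: PostureGrid, tail_angle: float,
                     precision: float = 0.5) -> float | None:
    """Smallest body angle at which the interpolated pitch moment changes
    sign along a fixed tail angle; None when it never does."""
    f = lambda ba: grid.surface(ba, tail_angle)
    ba_lo, ba_hi = grid.ba_knots[0], grid.ba_knots[-1]
    scan = np.arange(ba_lo, ba_hi + 1e-9, min(precision, 1.0))
    vals = np.array([f(b) for b in scan])
    signs = np.sign(vals)
    for i in range(len(scan) - 1):
        if signs[i] == 0:
            return float(scan[i])
        if signs[i] * signs[i + 1] < 0:
            return float(brentq(f, scan[i], scan[i + 1], xtol=precision / 10))
    if signs[-1] == 0:
        return float(scan[-1])
    return None


# -- hull sensitivity ------------------------------------------------------

@dataclass
class SensitivityConfig:
    """Hull perturbations: +/-20% segment shape (mass) scaling and
    per-segment COM pushed to the cranial/caudal extremes of its local
    bounding box."""

    shape_scales: tuple = (0.8, 1.2)
    com_extremes: bool = True

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape_scales):
            raise ValueError("shape scale factors must be positive")


@dataclass
class SensitivityResult:
    per_variant: pd.DataFrame
    mean_abs_percent_difference: float
    any_sign_pattern_change: bool
    grids: dict[str, PostureGrid]


def _segment_bbox_x(model: SkeletonModel, segment: str) -> tuple[float, float]:
    spec = model.segments[segment]
    verts = np.vstack([m.vertices for m in spec.body_meshes])
    return float(verts[:, 0].min()), float(verts[:, 0].max())


def _com_extreme_overrides(model: SkeletonModel, direction: str) -> dict:
    out = {}
    for name in model.segments:
        from .model import segment_mass_properties
        mp = segment_mass_properties(model, name)
        lo, hi = _segment_bbox_x(model, name)
        x = hi if direction == "cranial" else lo
        com = mp.com.copy()
        com[0] = x
        out[name] = {"com_local": com}
    return out


def sensitivity_analysis(model: SkeletonModel, load: ExternalLoad,
                         config: SensitivityConfig | None = None,
                         ba_knots=GRID_KNOTS, ta_knots=GRID_KNOTS,
                         limb_pose: Pose | None = None) -> SensitivityResult:
    """Rebuild the pitch-moment grid under hull perturbations and report
    each variant's mean absolute percent difference from the unperturbed
    (optimal) grid and whether its sign pattern changes.

    The GRF magnitude is specified in body weights, so a mass variant's
    force is re-expressed in newtons using that variant's own body
    weight.
    """
    from .model import segment_mass_properties, GRAVITY
    config = config or SensitivityConfig()
    base_mass = sum(segment_mass_properties(model, s).mass for s in model.segments)
    reference = build_posture_grid(model, load, ba_knots, ta_knots, limb_pose,
                                   body_weight_n=base_mass * GRAVITY)
    ref_surf = reference.pitch_surface
    ref_scale = float(np.abs(ref_surf).mean())

    variants: dict[str, tuple[dict | None, float]] = {}
    for s in config.shape_scales:
        overrides = {name: {"mass_scale": s} for name in model.segments}
        variants[f"shape_scale_{s:g}"] = (overrides, base_mass * s)
    if config.com_extremes:
        for direction in ("cranial", "caudal"):
            variants[f"com_{direction}"] = (
                _com_extreme_overrides(model, direction), base_mass)

    rows, grids, any_flip = [], {}, False
    for name, (overrides, mass) in variants.items():
        if mass <= 0:
            continue
        grid = build_posture_grid(model, load, ba_knots, ta_knots, limb_pose,
                                  segment_overrides=overrides,
                                  body_weight_n=mass * GRAVITY)
        diff = float(np.abs(grid.pitch_surface - ref_surf).mean()) / ref_scale * 100
        flipped = bool(np.any(np.sign(grid.pitch_surface) != np.sign(ref_surf)))
        any_flip = any_flip or flipped
        rows.append({"variant": name, "mean_abs_percent_difference": diff,
                     "sign_pattern_changed": flipped})
        grids[name] = grid
    frame = pd.DataFrame(rows)
    return SensitivityResult(frame,
                             float(frame["mean_abs_percent_difference"].mean()),
                             any_flip, grids)


def plot_pitch_heatmap(grid: PostureGrid, path: str,
                       reference_points: list | None = None) -> None:
    """Heat map of the 1-degree pitch-moment surface over body x tail
    angle (nose-up red, nose-down blue), with the simulation knots
    crossed and optional reference postures overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.0, 5.0))
    vmax = float(np.abs(grid.pitch_surface).max())
    im = ax.pcolormesh(grid.ba_degrees, grid.ta_degrees,
                       grid.pitch_surface.T, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, shading="nearest")
    ba, ta = np.meshgrid(grid.ba_knots, grid.ta_knots)
    ax.plot(ba.ravel(), ta.ravel(), "k+", ms=7, label="simulations")
    if reference_points:
        pts = np.asarray(reference_points, dtype=float)
        ax.plot(pts[:, 0], pts[:, 1], "o", mfc="white", mec="black",
                label="reference postures")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("body angle (deg)")
    ax.set_ylabel("tail angle (deg)")
    fig.colorbar(im, ax=ax, label="pitch moment about the COM (N m)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -- reference-posture overlay --------------------------------------------

def overlay_reference_postures(grid: PostureGrid,
                               points: list[tuple[float, float]]) -> pd.DataFrame:
    """Evaluate the interpolated pitch surface at observed (BA, TA)
    posture points (e.g. extant bipedal lizards); out-of-range points are
    flagged and not evaluated.  The convex hull of the in-range points is
    attached as ``frame.attrs['hull_vertices']`` for plotting."""
    rows, in_range = [], []
    for ba, ta in points:
        ok = (grid.ba_knots[0] <= ba <= grid.ba_knots[-1]
              and grid.ta_knots[0] <= ta <= grid.ta_knots[-1])
        rows.append({"body_angle_deg": ba, "tail_angle_deg": ta,
                     "in_range": ok,
                     "pitch_moment_nm": grid.surface(ba, ta) if ok else np.nan})
        if ok:
            in_range.append((ba, ta))
    frame = pd.DataFrame(rows, columns=["body_angle_deg", "tail_angle_deg",
                                        "in_range", "pitch_moment_nm"])
    hull_vertices = []
    unique = np.unique(np.asarray(in_range, dtype=float).reshape(-1, 2), axis=0)
    if len(unique) >= 3:
        try:
            hull = ConvexHull(unique)
            hull_vertices = unique[hull.vertices].tolist()
        except Exception:  # collinear points: no 2-D hull
            hull_vertices = []
    frame.attrs["hull_vertices"] = hull_vertices
    return frame
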