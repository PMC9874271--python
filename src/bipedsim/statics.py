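"""Static optimization of muscle redundancy under a ground reaction force.

At one instant, muscle activations a_m (0..1) and reserve-actuator
activations a_q (-1..1) must satisfy moment equilibrium at every
constrained degree of freedom k,

    sum_i F_max,i * r_i,k * a_i + T_q,k * a_q = M_k,

while minimizing sum a_m^2 + sum a_q^2 (muscle force is activation times
F_max; no force-length-velocity effects).  M_k is the moment the
actuators must supply to hold everything distal to d.f. k static against
the applied GRF and gravity.  Ramping the GRF magnitude in fixed steps
until the program becomes infeasible yields the maximum sustainable load
for a posture.

Only the actuated d.f. are constrained (hip 3, knee 1, ankle 1, MTP 1,
and 2 x 2 tail d.f. in the default model); the six pelvis-to-ground d.f.
carry no actuators and are excluded — a single-instant static analysis
with a prescribed multi-BW GRF cannot close the whole-body equations
without accelerations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import linprog, minimize

from .model import (Pose, SkeletonModel, composite_mass_properties,
                    forward_kinematics, rotation_about_point, rotation_matrix,
                    segment_mass_properties, transform_point, GRAVITY,
                    MEDIOLATERAL_AXIS, _homogeneous, _joint_transform)
from .muscles import MusclePath, MuscleParameters, _posed_points

DEFAULT_TOLERANCE = 1e-6


@dataclass
class ExternalLoad:
    """A GRF: magnitude in body weights, unit direction, centre of
    pressure (world frame) on a stance segment."""

    magnitude_bw: float
    direction: np.ndarray
    cop: np.ndarray
    body_weight_n: float
    stance_segment: str = "toes"
    medial_deg: float = 0.0
    cranial_deg: float = 0.0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("load direction must be a unit vector")
        self.direction = self.direction / n
        self.cop = np.asarray(self.cop, dtype=float).reshape(3)
        if self.magnitude_bw < 0:
            raise ValueError("GRF magnitude must be non-negative")

    @property
    def force_vector(self) -> np.ndarray:
        """The GRF in newtons."""
        return self.magnitude_bw * self.body_weight_n * self.direction

    def with_magnitude(self, magnitude_bw: float) -> "ExternalLoad":
        return ExternalLoad(magnitude_bw, self.direction.copy(), self.cop.copy(),
                            self.body_weight_n, self.stance_segment,
                            self.medial_deg, self.cranial_deg)


def build_load(magnitude_bw: float, medial_deg: float, cranial_deg: float,
               cop: np.ndarray, body_weight_n: float,
               stance_segment: str = "toes") -> ExternalLoad:
    """GRF from its magnitude and direction angles off vertical.

    The direction tilts the vertical unit vector ``cranial_deg`` toward
    cranial (+x) and ``medial_deg`` toward medial (-z for the right
    foot), i.e. direction = normalize(tan(cranial), 1, -tan(medial)).
    """
    if not (-90.0 < medial_deg < 90.0 and -90.0 < cranial_deg < 90.0):
        raise ValueError("direction angles must lie within (-90, 90) degrees")
    d = np.array([np.tan(np.deg2rad(cranial_deg)), 1.0,
                  -np.tan(np.deg2rad(medial_deg))])
    return ExternalLoad(magnitude_bw, d / np.linalg.norm(d), cop,
                        body_weight_n, stance_segment, medial_deg, cranial_deg)


# -- required joint moments -----------------------------------------------

def dof_world_frames(model: SkeletonModel,
                     pose: Pose) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """World anchor point and instantaneous axis of every active d.f.

    Joint coordinates act before the BA/TA group rotations, so a d.f.
    whose child segment belongs to a rotated group has its axis and
    anchor carried along by that group's rigid rotation.
    """
    raw: dict[str, np.ndarray] = {}
    frames: dict[str, tuple] = {}

    for joint in model._joints_in_tree_order():
        T = (np.eye(4) if joint.parent_segment is None
             else raw[joint.parent_segment]) .copy()
        T = T @ _homogeneous(t=joint.location_in_parent)
        for dof in joint.dofs:
            if not dof.locked:
                frames[dof.name] = (T[:3, 3].copy(), T[:3, :3] @ dof.axis,
                                    joint.child_segment, dof.kind)
            value = dof.locked_value if dof.locked else pose.values[dof.name]
            if dof.kind == "rotation":
                T = T @ _homogeneous(R=rotation_matrix(dof.axis, np.deg2rad(value)))
            else:
                T = T @ _homogeneous(t=dof.axis * value)
        raw[joint.child_segment] = T

    # group rigid rotations (same construction as forward_kinematics)
    for angle, pivot_joint, sign, group in (
        (pose.body_angle, model.body_pivot_joint, +1.0, model.body_group),
        (pose.tail_angle, model.tail_pivot_joint, -1.0, model.tail_group),
    ):
        if not group or angle == 0.0:
            continue
        jp = model.joints[pivot_joint]
        pivot = transform_point(raw[jp.parent_segment]
                                if jp.parent_segment else np.eye(4),
                                jp.location_in_parent)
        R = rotation_about_point(MEDIOLATERAL_AXIS, sign * np.deg2rad(angle), pivot)
        for name, (p, a, child, kind) in list(frames.items()):
            if child in group:
                frames[name] = (transform_point(R, p), R[:3, :3] @ a, child, kind)

    return {name: (p, a) for name, (p, a, _c, _k) in frames.items()}


def required_joint_moments(model: SkeletonModel, pose: Pose, load: ExternalLoad,
                           constrained_dofs: list[str],
                           gravity_on: bool = True) -> dict[str, float]:
    """Moment each actuator set must supply at every constrained d.f.

    For d.f. k with world axis a_k through point p_k:
    M_k = -[a_k . ((cop - p_k) x F)  (if the stance segment is distal to k)
            + sum over distal segments s of a_k . ((com_s - p_k) x m_s g)].
    """
    frames = dof_world_frames(model, pose)
    transforms = forward_kinematics(model, pose)
    if load.stance_segment not in model.segments:
        raise ValueError(f"unknown stance segment {load.stance_segment!r}")
    f_grf = load.force_vector
    g_vec = np.array([0.0, -GRAVITY, 0.0])

    limb_dofs = [d for d in constrained_dofs
                 if model.get_dof(d).kind == "rotation"]
    if not any(load.stance_segment in
               model.subtree(model.dof_joint(d).child_segment)
               for d in limb_dofs):
        raise ValueError(
            f"COP segment {load.stance_segment!r} is not distal to any "
            "constrained d.f.; the GRF cannot load the actuated chain")

    moments: dict[str, float] = {}
    for dof_name in constrained_dofs:
        dof = model.get_dof(dof_name)
        if dof.kind != "rotation":
            raise ValueError(f"constrained d.f. {dof_name!r} is translational; "
                             "only rotational d.f. carry actuators here")
        p_k, a_k = frames[dof_name]
        distal = model.subtree(model.dof_joint(dof_name).child_segment)
        total = 0.0
        if load.stance_segment in distal:
            total += float(a_k @ np.cross(load.cop - p_k, f_grf))
        if gravity_on:
            for seg in distal:
                mp = segment_mass_properties(model, seg)
                com_w = transform_point(transforms[seg], mp.com)
                total += float(a_k @ np.cross(com_w - p_k, mp.mass * g_vec))
        moments[dof_name] = -total
    return moments


# -- equilibrium system ----------------------------------------------------

@dataclass
class ReserveActuator:
    name: str
    dof: str
    max_torque: float  # N m


@dataclass
class EquilibriumSystem:
    """The linear equality system of the activation QP."""

    dof_names: list[str]
    matrix: np.ndarray  # K x (N + Q): F_max,i * r_i,k then T_q
    required_moments: np.ndarray  # K
    lower: np.ndarray
    upper: np.ndarray
    muscle_names: list[str]
    reserve_names: list[str]

    @property
    def n_muscles(self) -> int:
        return len(self.muscle_names)


def all_moment_arms(model: SkeletonModel, pose: Pose, muscles: list[MusclePath],
                    dof_names: list[str], step_rad: float = 1e-4) -> np.ndarray:
    """Moment-arm matrix r[k, i] by central differences, two forward-
    kinematics evaluations per d.f. shared across all muscles."""
    r = np.zeros((len(dof_names), len(muscles)))
    h = np.rad2deg(step_rad)
    for k, dof_name in enumerate(dof_names):
        q0 = pose.values[dof_name]
        tp = forward_kinematics(model, pose.with_value(dof_name, q0 + h))
        tm = forward_kinematics(model, pose.with_value(dof_name, q0 - h))
        for i, mus in enumerate(muscles):
            lp = np.linalg.norm(np.diff(_posed_points(tp, mus), axis=0), axis=1).sum()
            lm = np.linalg.norm(np.diff(_posed_points(tm, mus), axis=0), axis=1).sum()
            r[k, i] = -(lp - lm) / (2.0 * step_rad)
    return r


def build_equilibrium_system(model: SkeletonModel, pose: Pose,
                             muscles: list[MusclePath],
                             parameters: dict[str, MuscleParameters],
                             load: ExternalLoad,
                             constrained_dofs: list[str],
                             reserves: list[ReserveActuator],
                             gravity_on: bool = True) -> EquilibriumSystem:
    arms = all_moment_arms(model, pose, muscles, constrained_dofs)
    n, q = len(muscles), len(reserves)
    A = np.zeros((len(constrained_dofs), n + q))
    for i, mus in enumerate(muscles):
        A[:, i] = parameters[mus.name].f_max * arms[:, i]
    for j, res in enumerate(reserves):
        A[constrained_dofs.index(res.dof), n + j] = res.max_torque
    M = required_joint_moments(model, pose, load, constrained_dofs, gravity_on)
    b = np.array([M[d] for d in constrained_dofs])
    lower = np.concatenate([np.zeros(n), -np.ones(q)])
    upper = np.ones(n + q)
    return EquilibriumSystem(list(constrained_dofs), A, b, lower, upper,
                             [m.name for m in muscles], [r.name for r in reserves])


# -- QP solve --------------------------------------------------------------

@dataclass
class StaticSolution:
    feasible: bool
    activations: np.ndarray
    reserve_activations: np.ndarray
    objective: float
    residuals: np.ndarray
    muscle_names: list[str] = field(default_factory=list)
    reserve_names: list[str] = field(default_factory=list)

    @property
    def activation_by_muscle(self) -> dict[str, float]:
        return dict(zip(self.muscle_names, self.activations))


class SolverError(RuntimeError):
    pass


def _feasible_point(system: EquilibriumSystem) -> np.ndarray | None:
    bounds = list(zip(system.lower, system.upper))
    res = linprog(np.zeros(system.matrix.shape[1]), A_eq=system.matrix,
                  b_eq=system.required_moments, bounds=bounds, method="highs")
    return res.x if res.status == 0 else None


def is_feasible(system: EquilibriumSystem) -> bool:
    return _feasible_point(system) is not None


def _polish(system: EquilibriumSystem, x: np.ndarray,
            atol: float = 1e-7) -> np.ndarray | None:
    """Exact minimum-norm resolve on the active set suggested by x."""
    lo, up = system.lower, system.upper
    at_lo = x <= lo + atol
    at_up = x >= up - atol
    free = ~(at_lo | at_up)
    xp = np.where(at_lo, lo, np.where(at_up, up, x)).astype(float)
    A = system.matrix
    if free.any():
        rhs = system.required_moments - A[:, ~free] @ xp[~free]
        xp[free] = np.linalg.pinv(A[:, free]) @ rhs
    if np.any(xp < lo - 1e-9) or np.any(xp > up + 1e-9):
        return None
    return np.clip(xp, lo, up)


def solve_static_optimization(system: EquilibriumSystem,
                              tolerance: float = DEFAULT_TOLERANCE,
                              reserve_warn: float = 0.95) -> StaticSolution:
    """Global minimizer of sum of squared activations subject to moment
    equilibrium and activation bounds, or an infeasible flag.

    Strategy: an LP feasibility probe, SLSQP minimization from a
    deterministic cold start (all-zero clipped into the feasible box) and
    from the LP vertex, then an exact minimum-norm polish on the detected
    active set.  The best bounded candidate meeting the equality
    tolerance wins.
    """
    n, q = len(system.muscle_names), len(system.reserve_names)
    A, b = system.matrix, system.required_moments
    scale = max(1.0, float(np.abs(b).max()))

    x_feas = _feasible_point(system)
    if x_feas is None:
        return StaticSolution(False, np.full(n, np.nan), np.full(q, np.nan),
                              np.inf, np.full(len(b), np.nan),
                              system.muscle_names, system.reserve_names)

    bounds = list(zip(system.lower, system.upper))
    cons = {"type": "eq", "fun": lambda x: A @ x - b, "jac": lambda x: A}
    candidates = []
    for start in (x_feas, np.zeros(n + q)):
        res = minimize(lambda x: x @ x, start, jac=lambda x: 2 * x,
                       bounds=bounds, constraints=[cons], method="SLSQP",
                       options={"maxiter": 300, "ftol": 1e-14})
        if res.x is not None:
            candidates.append(np.clip(res.x, system.lower, system.upper))
            polished = _polish(system, candidates[-1])
            if polished is not None:
                candidates.append(polished)
    candidates.append(x_feas)

    best, best_obj = None, np.inf
    for x in candidates:
        resid = np.abs(A @ x - b).max()
        if resid <= tolerance * scale and x @ x < best_obj:
            best, best_obj = x, float(x @ x)
    if best is None:
        raise SolverError("QP solver failed to meet the equality tolerance "
                          "on a feasible problem")
    if q and np.abs(best[n:]).max() >= reserve_warn:
        warnings.warn("a reserve actuator is near full activation; its torque "
                      "sizing is influencing the solution", stacklevel=2)
    return StaticSolution(True, best[:n], best[n:], best_obj, A @ best - b,
                          system.muscle_names, system.reserve_names)


# -- GRF ramp --------------------------------------------------------------

@dataclass
class RampResult:
    max_grf_bw: float
    solution: StaticSolution | None
    group_means: dict[str, float]
    cap_limited: bool
    magnitudes_tested: list[float]


def default_reserve_torque(model: SkeletonModel, pose_list: list[Pose],
                           load: ExternalLoad, constrained_dofs: list[str],
                           safety: float = 2.0) -> float:
    """Auto-size reserve torques: `safety` times the largest required
    moment magnitude seen across a posture set (the exact value is
    inconsequential provided reserves are never fully activated)."""
    worst = 0.0
    for pose in pose_list:
        M = required_joint_moments(model, pose, load, constrained_dofs)
        worst = max(worst, max(abs(v) for v in M.values()))
    return safety * worst if worst > 0 else 1.0


def ramp_grf(model: SkeletonModel, pose: Pose, muscles: list[MusclePath],
             parameters: dict[str, MuscleParameters], load_template: ExternalLoad,
             constrained_dofs: list[str], reserves: list[ReserveActuator],
             step_bw: float = 0.1, cap_bw: float = 20.0,
             gravity_on: bool = True,
             groups: dict[str, list[str]] | None = None) -> RampResult:
    """Increase GRF magnitude in fixed steps until static equilibrium
    becomes infeasible; report the last sustainable magnitude.

    The moment matrix depends only on the pose, and the required moments
    are affine in the GRF magnitude, so the matrix is built once and
    only the right-hand side is updated per step.
    """
    if step_bw <= 0:
        raise ValueError("ramp step must be positive")
    sys1 = build_equilibrium_system(model, pose, muscles, parameters,
                                    load_template.with_magnitude(1.0),
                                    constrained_dofs, reserves, gravity_on)
    M0 = required_joint_moments(model, pose, load_template.with_magnitude(0.0),
                                constrained_dofs, gravity_on)
    b0 = np.array([M0[d] for d in constrained_dofs])
    b_grf = sys1.required_moments - b0  # moments per 1 BW of GRF

    tested, last_feasible, cap_limited = [], 0.0, False
    mag = step_bw
    while True:
        sys_m = EquilibriumSystem(sys1.dof_names, sys1.matrix, b0 + mag * b_grf,
                                  sys1.lower, sys1.upper, sys1.muscle_names,
                                  sys1.reserve_names)
        tested.append(round(mag, 10))
        if not is_feasible(sys_m):
            break
        last_feasible = mag
        if mag >= cap_bw - 1e-12:
            cap_limited = True
            break
        mag = mag + step_bw

    solution = None
    means: dict[str, float] = {}
    if last_feasible > 0:
        sys_best = EquilibriumSystem(sys1.dof_names, sys1.matrix,
                                     b0 + last_feasible * b_grf, sys1.lower,
                                     sys1.upper, sys1.muscle_names,
                                     sys1.reserve_names)
        solution = solve_static_optimization(sys_best)
        if groups:
            means = group_mean_activations(solution, groups)
    return RampResult(round(last_feasible, 10), solution, means, cap_limited, tested)


def group_mean_activations(solution: StaticSolution,
                           groups: dict[str, list[str]]) -> dict[str, float]:
    """Arithmetic mean activation per muscle group; reserves excluded.
    Empty groups report NaN (not 0)."""
    by_name = solution.activation_by_muscle
    out = {}
    for group, members in groups.items():
        vals = [by_name[m] for m in members if m in by_name]
        out[group] = float(np.mean(vals)) if vals else float("nan")
    return out


# -- posture interpolation -------------------------------------------------

BODY_ANGLE_KNOTS = (0.0, 25.0, 50.0, 75.0)


def interpolate_activation_grid(knot_values: np.ndarray,
                                knots: tuple = BODY_ANGLE_KNOTS,
                                step_deg: float = 1.0) -> np.ndarray:
    """Cubic-spline interpolation of per-posture values at 1-degree body
    angles across [0, 75]; exact at the four knots.  No extrapolation.

    `knot_values` may be a vector per knot (first axis = knots).
    """
    knots = np.asarray(knots, dtype=float)
    if len(knots) != 4 or not np.allclose(knots, BODY_ANGLE_KNOTS):
        raise ValueError("expected exactly the knots (0, 25, 50, 75) degrees")
    values = np.asarray(knot_values, dtype=float)
    if values.shape[0] != 4:
        raise ValueError("one value (or vector) per knot required")
    grid = np.arange(knots[0], knots[-1] + 0.5 * step_deg, step_deg)
    if grid[0] < knots[0] - 1e-12 or grid[-1] > knots[-1] + 1e-12:
        raise ValueError("no extrapolation outside [0, 75] degrees")
    return CubicSpline(knots, values, axis=0, bc_type="not-a-knot")(grid)
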