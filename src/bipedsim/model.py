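"""Articulated skeleton: segments, joints, poses and forward kinematics.

The skeleton is a tree of rigid segments connected by joints whose
degrees of freedom (d.f.) are single-axis rotations or translations.
Rotational coordinates are degrees at the interface and radians
internally; lengths are metres.

Frame convention (right-handed): x craniocaudal (positive cranial),
y vertical (positive up), z mediolateral (positive right).  Pitch is
rotation about z, yaw about y, roll about x.

Whole-body posture is described by two extra angles measured from
horizontal: the body angle BA (rigid rotation of the trunk-and-cranial
segment group about the mediolateral axis through the trunk joint) and
the tail angle TA (likewise for the tail group about the proximal tail
joint).  Positive angles raise the head / the tail tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import MassProperties, MeshBody, combine_mass_properties, net_mass_properties

GRAVITY = 9.81  # m s^-2

MEDIOLATERAL_AXIS = np.array([0.0, 0.0, 1.0])


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _homogeneous(R: np.ndarray = None, t: np.ndarray = None) -> np.ndarray:
    T = np.eye(4)
    if R is not None:
        T[:3, :3] = R
    if t is not None:
        T[:3, 3] = np.asarray(t, dtype=float)
    return T


def rotation_about_point(axis: np.ndarray, angle_rad: float,
                         point: np.ndarray) -> np.ndarray:
    """Homogeneous transform rotating about an axis through a point."""
    R = rotation_matrix(axis, angle_rad)
    p = np.asarray(point, dtype=float)
    return _homogeneous(R, p - R @ p)


def transform_point(T: np.ndarray, p: np.ndarray) -> np.ndarray:
    return T[:3, :3] @ np.asarray(p, dtype=float) + T[:3, 3]


@dataclass
class DoF:
    """A single joint degree of freedom."""

    name: str
    axis: np.ndarray
    kind: str = "rotation"  # rotation | translation
    locked: bool = False
    locked_value: float = 0.0  # degrees (rotation) or metres (translation)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(axis)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError(f"d.f. {self.name!r}: axis must be a unit vector")
        self.axis = axis / n
        if self.kind not in ("rotation", "translation"):
            raise ValueError(f"d.f. {self.name!r}: kind must be rotation|translation")


@dataclass
class JointSpec:
    name: str
    parent_segment: str | None  # None: attached to the world (root joint)
    child_segment: str
    location_in_parent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dofs: list[DoF] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.location_in_parent = np.asarray(self.location_in_parent,
                                             dtype=float).reshape(3)


@dataclass
class SegmentSpec:
    name: str
    parent_joint: str | None
    body_meshes: list[MeshBody] = field(default_factory=list)
    cavity_meshes: list[MeshBody] = field(default_factory=list)
    mass_override: float | None = None


@dataclass
class Pose:
    """Joint coordinates (degrees / metres per active d.f.) plus the
    whole-body BA and TA angles in degrees from horizontal."""

    values: dict[str, float] = field(default_factory=dict)
    body_angle: float = 0.0
    tail_angle: float = 0.0

    def with_value(self, dof: str, value: float) -> "Pose":
        vals = dict(self.values)
        vals[dof] = value
        return Pose(vals, self.body_angle, self.tail_angle)


class SkeletonModel:
    """Posed kinematic tree of segments and joints.

    `body_group` / `tail_group` name the segments rigidly rotated by BA
    and TA; the pivots are the named joints' centres (BA about the trunk
    joint, TA about the proximal tail joint), both rotating about the
    mediolateral axis.
    """

    def __init__(self, segments: list[SegmentSpec], joints: list[JointSpec],
                 body_group: tuple[str, ...] = (), tail_group: tuple[str, ...] = (),
                 body_pivot_joint: str | None = None,
                 tail_pivot_joint: str | None = None,
                 name: str = "model") -> None:
        self.name = name
        self.segments = {s.name: s for s in segments}
        self.joints = {j.name: j for j in joints}
        self.body_group = tuple(body_group)
        self.tail_group = tuple(tail_group)
        self.body_pivot_joint = body_pivot_joint
        self.tail_pivot_joint = tail_pivot_joint
        self._segment_mass_cache: dict[str, MassProperties] = {}
        self._validate_tree()

    # -- structure ---------------------------------------------------------

    def _validate_tree(self) -> None:
        roots = [j.name for j in self.joints.values() if j.parent_segment is None]
        if len(roots) != 1:
            raise ValueError(f"model must have exactly one root joint, found {roots}")
        self.root_joint = roots[0]
        for j in self.joints.values():
            if j.child_segment not in self.segments:
                raise ValueError(f"joint {j.name!r}: unknown child {j.child_segment!r}")
            if j.parent_segment is not None and j.parent_segment not in self.segments:
                raise ValueError(f"joint {j.name!r}: unknown parent {j.parent_segment!r}")
        children = [j.child_segment for j in self.joints.values()]
        if len(set(children)) != len(children):
            raise ValueError("a segment has more than one parent joint")
        if set(children) != set(self.segments):
            orphan = set(self.segments) - set(children)
            raise ValueError(f"segments without a parent joint: {sorted(orphan)}")
        # reject cycles by walking every segment up to the root
        for name in self.segments:
            seen = set()
            while name is not None:
                if name in seen:
                    raise ValueError("segment graph is not a tree (cycle)")
                seen.add(name)
                name = self.parent_joint_of(name).parent_segment

    def parent_joint_of(self, segment: str) -> JointSpec:
        for j in self.joints.values():
            if j.child_segment == segment:
                return j
        raise KeyError(segment)

    def children_of(self, segment: str) -> list[str]:
        return [j.child_segment for j in self.joints.values()
                if j.parent_segment == segment]

    def subtree(self, segment: str) -> list[str]:
        """The segment and everything distal to it."""
        out, stack = [], [segment]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(self.children_of(s))
        return out

    def active_dofs(self) -> list[tuple[str, DoF]]:
        """(joint name, DoF) for every unlocked d.f., in tree order."""
        out = []
        for j in self._joints_in_tree_order():
            out.extend((j.name, d) for d in j.dofs if not d.locked)
        return out

    def _joints_in_tree_order(self) -> list[JointSpec]:
        order, stack = [], [self.root_joint]
        while stack:
            jname = stack.pop(0)
            j = self.joints[jname]
            order.append(j)
            for child in self.children_of(j.child_segment):
                stack.append(self.parent_joint_of(child).name)
        return order

    def dof_joint(self, dof_name: str) -> JointSpec:
        for j in self.joints.values():
            if any(d.name == dof_name for d in j.dofs):
                return j
        raise KeyError(f"unknown d.f. {dof_name!r}")

    def get_dof(self, dof_name: str) -> DoF:
        j = self.dof_joint(dof_name)
        return next(d for d in j.dofs if d.name == dof_name)

    def default_pose(self, body_angle: float = 0.0, tail_angle: float = 0.0) -> Pose:
        return Pose({d.name: 0.0 for _, d in self.active_dofs()},
                    body_angle, tail_angle)


def count_dofs(model: SkeletonModel) -> dict[str, int]:
    """Active and locked degree-of-freedom counts across all joints."""
    active = locked = 0
    for j in model.joints.values():
        for d in j.dofs:
            if d.locked:
                locked += 1
            else:
                active += 1
    return {"active": active, "locked": locked}


def _joint_transform(joint: JointSpec, pose: Pose) -> np.ndarray:
    T = _homogeneous(t=joint.location_in_parent)
    for dof in joint.dofs:
        if dof.locked:
            value = dof.locked_value
        else:
            try:
                value = pose.values[dof.name]
            except KeyError:
                raise KeyError(
                    f"pose is missing a value for active d.f. {dof.name!r}"
                ) from None
        if dof.kind == "rotation":
            T = T @ _homogeneous(R=rotation_matrix(dof.axis, np.deg2rad(value)))
        else:
            T = T @ _homogeneous(t=dof.axis * value)
    return T


def forward_kinematics(model: SkeletonModel, pose: Pose) -> dict[str, np.ndarray]:
    """World transform (4x4) of every segment frame under a pose.

    Joint-coordinate transforms compose parent-to-child down the tree;
    the BA/TA whole-body angles are then applied as rigid rotations of
    the body and tail segment groups about the mediolateral axis through
    their pivot joints.
    """
    transforms: dict[str, np.ndarray] = {}
    for joint in model._joints_in_tree_order():
        parent_T = (np.eye(4) if joint.parent_segment is None
                    else transforms[joint.parent_segment])
        transforms[joint.child_segment] = parent_T @ _joint_transform(joint, pose)

    for angle, group, pivot_joint, sign in (
        (pose.body_angle, model.body_group, model.body_pivot_joint, +1.0),
        (pose.tail_angle, model.tail_group, model.tail_pivot_joint, -1.0),
    ):
        if not group or angle == 0.0:
            continue
        if pivot_joint is None:
            raise ValueError("group angle set but no pivot joint declared")
        jp = model.joints[pivot_joint]
        pivot = transform_point(transforms[jp.parent_segment]
                                if jp.parent_segment else np.eye(4),
                                jp.location_in_parent)
        # +BA raises the head (cranial +x toward +y); +TA raises the tail
        # tip, which points caudally, hence the opposite rotation sense.
        R = rotation_about_point(MEDIOLATERAL_AXIS, sign * np.deg2rad(angle), pivot)
        for seg in group:
            transforms[seg] = R @ transforms[seg]
    return transforms


def segment_mass_properties(model: SkeletonModel, segment: str) -> MassProperties:
    """Net (body - cavity) mass properties of a segment in its own frame.

    Honours `mass_override` by rescaling mass and inertia (shape-derived
    COM kept).  Cached per segment.
    """
    if segment in model._segment_mass_cache:
        return model._segment_mass_cache[segment]
    spec = model.segments[segment]
    mp = net_mass_properties(spec.body_meshes, spec.cavity_meshes, name=segment)
    if spec.mass_override is not None:
        if spec.mass_override <= 0:
            raise ValueError(f"segment {segment!r}: mass_override must be positive")
        mp = mp.scaled(spec.mass_override / mp.mass)
    model._segment_mass_cache[segment] = mp
    return mp


def composite_mass_properties(
    model: SkeletonModel,
    pose: Pose,
    segment_overrides: dict[str, dict] | None = None,
) -> MassProperties:
    """Whole-body mass, COM and inertia (about the COM) at a pose.

    `segment_overrides` supports the hull sensitivity analysis:
    per-segment ``{"mass_scale": float, "com_local": 3-vector}`` entries
    perturb a segment's mass and/or its local COM before composition.
    """
    transforms = forward_kinematics(model, pose)
    parts = []
    for name in model.segments:
        mp = segment_mass_properties(model, name)
        if segment_overrides and name in segment_overrides:
            ov = segment_overrides[name]
            if "mass_scale" in ov:
                mp = mp.scaled(float(ov["mass_scale"]))
            if "com_local" in ov:
                mp = MassProperties(mp.mass,
                                    np.asarray(ov["com_local"], dtype=float),
                                    mp.inertia)
        parts.append(mp.transformed(transforms[name]))
    return combine_mass_properties(parts)


def body_weight_newtons(model: SkeletonModel) -> float:
    """1 BW in newtons: whole-body mass x g (pose-independent)."""
    mass = sum(segment_mass_properties(model, s).mass for s in model.segments)
    return mass * GRAVITY
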