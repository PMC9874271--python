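"""Closed-mesh mass properties and rigid-body composition.

Segment shapes (body hulls) and internal air spaces (lung, trachea,
pharyngeal/sinus cavities) are closed triangle meshes.  Mass, centre of
mass and the inertia tensor are exact polyhedral integrals (divergence
theorem over the oriented triangles); cavities are handled by
negative-mass superposition, which is exact for cavities fully contained
in their segment hull.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


class MeshError(ValueError):
    """Raised for open, degenerate or inconsistently wound meshes."""


@dataclass
class MassProperties:
    """Mass, centre of mass and inertia (about the COM, stated frame)."""

    mass: float
    com: np.ndarray
    inertia: np.ndarray

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)

    def inertia_about(self, point: np.ndarray) -> np.ndarray:
        """Inertia tensor about an arbitrary point (parallel-axis theorem)."""
        d = self.com - np.asarray(point, dtype=float)
        return self.inertia + self.mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))

    def transformed(self, transform: np.ndarray) -> "MassProperties":
        """Mass properties after a rigid transform (4x4 homogeneous)."""
        R = transform[:3, :3]
        com = R @ self.com + transform[:3, 3]
        return MassProperties(self.mass, com, R @ self.inertia @ R.T)

    def scaled(self, mass_scale: float) -> "MassProperties":
        """Scale mass (and inertia proportionally); COM unchanged."""
        return MassProperties(self.mass * mass_scale, self.com.copy(),
                              self.inertia * mass_scale)


@dataclass
class MeshBody:
    """A closed triangle mesh with a density and a role.

    role 'body' contributes positive mass; role 'cavity' is an enclosed
    air space whose displaced tissue mass the caller subtracts.
    """

    vertices: np.ndarray
    faces: np.ndarray
    density: float = 1000.0
    role: str = "body"
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.role not in ("body", "cavity"):
            raise ValueError(f"role must be 'body' or 'cavity', got {self.role!r}")
        if self.density < 0:
            raise ValueError("density must be non-negative")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


def _boundary_edges(mesh: trimesh.Trimesh) -> list[tuple[int, int]]:
    edges, counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)
    bad = edges[counts != 2]
    return [tuple(int(i) for i in e) for e in bad[:20]]


def _validated_trimesh(mesh: MeshBody) -> trimesh.Trimesh:
    if len(mesh.faces) < 4:
        raise MeshError(f"mesh {mesh.name!r}: fewer than 4 faces, cannot be closed")
    tm = mesh.as_trimesh()
    if tm.area < 1e-300:
        raise MeshError(f"mesh {mesh.name!r}: degenerate (zero surface area)")
    if not tm.is_watertight:
        bad = _boundary_edges(tm)
        raise MeshError(
            f"mesh {mesh.name!r} is not closed: edges not shared by exactly two "
            f"faces (first offenders): {bad}"
        )
    if not tm.is_winding_consistent:
        raise MeshError(f"mesh {mesh.name!r}: inconsistent face winding")
    # Orientation normalization: a globally inverted (all-inward-normal) mesh
    # has negative signed volume; flip every face once.
    if tm.volume < 0:
        tm.invert()
    return tm


def mesh_mass_properties(mesh: MeshBody) -> MassProperties:
    """Exact mass, COM and inertia of a closed mesh at its stated density.

    Cavity meshes return the same (positive) magnitudes; the caller
    applies the subtraction.
    """
    tm = _validated_trimesh(mesh)
    tm.density = mesh.density
    # trimesh integrates the divergence-theorem surface integrals exactly;
    # moment_inertia is about the centre of mass in the mesh frame.
    return MassProperties(float(tm.mass), tm.center_mass, tm.moment_inertia)


def combine_mass_properties(parts: list[MassProperties]) -> MassProperties:
    """Compose rigidly-connected parts: summed mass, mass-weighted COM,
    inertia transported to the composite COM by the parallel-axis theorem.

    Parts may carry negative mass (cavity subtraction); the composite
    mass must be positive.
    """
    if not parts:
        raise ValueError("no parts to combine")
    mass = float(sum(p.mass for p in parts))
    if mass <= 0:
        raise ValueError(f"composite mass must be positive, got {mass}")
    com = sum(p.mass * p.com for p in parts) / mass
    inertia = np.zeros((3, 3))
    for p in parts:
        d = p.com - com
        inertia += p.inertia + p.mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
    return MassProperties(mass, com, inertia)


def net_mass_properties(body_meshes: list[MeshBody],
                        cavity_meshes: list[MeshBody],
                        name: str = "") -> MassProperties:
    """Segment mass properties: body hulls minus enclosed cavities.

    Each cavity subtracts the tissue mass its volume displaces, at the
    cavity's stated density (by default the surrounding tissue density).
    """
    parts = [mesh_mass_properties(m) for m in body_meshes]
    for m in cavity_meshes:
        mp = mesh_mass_properties(m)
        parts.append(MassProperties(-mp.mass, mp.com, -mp.inertia))
    total = float(sum(p.mass for p in parts))
    if total <= 0:
        raise ValueError(
            f"segment {name!r}: net mass {total:.6g} kg is not positive "
            "(cavities must not exceed the body hull)"
        )
    return combine_mass_properties(parts)
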