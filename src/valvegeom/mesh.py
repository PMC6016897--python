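"""Triangulated cusp surfaces and the assembled three-cusp valve.

A single cusp is meshed on a structured (θ, zfrac) grid of the fixed
parameter rectangle [0, 2π/n] x [0, 1]; the grid columns at the commissures
(where the free-edge height vanishes) collapse to single points and are
welded away, so the exported mesh carries no degenerate triangles.  The
full valve is the union of n copies of the cusp rotated about the valve
(z) axis by multiples of 2π/n, with coincident commissure vertices merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CuspParameters, DomainError, boundary_height

__all__ = ["SurfaceMesh", "ValveAssembly", "build_cusp_mesh", "rotate_mesh", "assemble_valve"]

#: welding tolerance for coincident vertices, mm
WELD_TOL = 1e-9


@dataclass(frozen=True)
class SurfaceMesh:
    """Indexed triangle mesh: vertices in mm, 0-based CCW faces.

    Winding is counter-clockwise seen from outside the cylinder, so face
    normals point radially outward.
    """

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise DomainError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise DomainError("faces must be an (m, 3) array")
        if not np.all(np.isfinite(v)):
            raise DomainError("vertex coordinates must be finite")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise DomainError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        return v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        """Per-face normals from the CCW winding (outward for cusp meshes)."""
        p0, p1, p2 = self.triangle_corners()
        n = np.cross(p1 - p0, p2 - p0)
        if normalized:
            norms = np.linalg.norm(n, axis=1, keepdims=True)
            n = n / np.where(norms == 0.0, 1.0, norms)
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def area(self) -> float:
        """Total surface area, mm²."""
        return float(np.sum(self.triangle_areas()))

    def weld(self, tol: float = WELD_TOL) -> "SurfaceMesh":
        """Merge vertices closer than ``tol`` and drop collapsed faces."""
        key = np.round(self.vertices / tol).astype(np.int64)
        _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
        faces = inverse[self.faces]
        ok = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 2] != faces[:, 0])
        )
        return SurfaceMesh(vertices=self.vertices[first], faces=faces[ok])

    def transformed(self, matrix: np.ndarray) -> "SurfaceMesh":
        """Apply a 3x3 linear map to the vertices (topology unchanged)."""
        return SurfaceMesh(vertices=self.vertices @ np.asarray(matrix, float).T, faces=self.faces)


@dataclass(frozen=True)
class ValveAssembly:
    """The n identical cusps of one valve and their rotations about the axis.

    Under the symmetry assumption every cusp shares the same parameters and
    cusp i is rotated by i·2π/n; for the tricuspid case the bisecting lines
    of adjacent cusps are 120° apart.
    """

    cusp: CuspParameters

    @property
    def n_cusps(self) -> int:
        return self.cusp.n_cusps

    @property
    def rotation_angles(self) -> np.ndarray:
        """Angles i·2π/n, i = 0..n-1, radians."""
        return np.arange(self.n_cusps) * self.cusp.angular_extent

    def mesh(self, n_theta: int = 128, n_z: int = 64) -> SurfaceMesh:
        return assemble_valve(self.cusp, n_theta, n_z)


def build_cusp_mesh(cusp: CuspParameters, n_theta: int = 128, n_z: int = 64) -> SurfaceMesh:
    """Structured triangulation of one cusp surface.

    The (θ, zfrac) rectangle is divided into ``n_theta x n_z`` quads, each
    split into two triangles with outward (radial) winding.  Grid columns
    collapsing at the commissures are welded; the result has no degenerate
    faces.  Total triangle area converges to 2hW/π at second order in the
    angular step.
    """
    if n_theta < 2 or n_z < 1:
        raise DomainError("need n_theta >= 2 and n_z >= 1")
    theta = np.linspace(0.0, cusp.angular_extent, n_theta + 1)
    zfrac = np.linspace(0.0, 1.0, n_z + 1)
    edge = boundary_height(cusp, theta)  # (n_theta+1,)
    tt = np.repeat(theta, n_z + 1)
    zz = np.tile(zfrac, n_theta + 1) * np.repeat(edge, n_z + 1)
    verts = np.column_stack(
        [cusp.radius * np.cos(tt), cusp.radius * np.sin(tt), zz]
    )

    # quad (i, j): corners at grid nodes, split so both triangles wind CCW
    # seen from outside the cylinder (normals have outward radial component)
    i, j = np.meshgrid(np.arange(n_theta), np.arange(n_z), indexing="ij")
    v00 = (i * (n_z + 1) + j).ravel()
    v10 = ((i + 1) * (n_z + 1) + j).ravel()
    v11 = ((i + 1) * (n_z + 1) + j + 1).ravel()
    v01 = (i * (n_z + 1) + j + 1).ravel()
    faces = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    return SurfaceMesh(vertices=verts, faces=faces).weld()


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotate_mesh(mesh: SurfaceMesh, angle: float) -> SurfaceMesh:
    """Rotate a mesh rigidly about the valve (z) axis.

    An isometry: pairwise distances and z-coordinates are preserved.
    """
    if not math.isfinite(angle):
        raise DomainError(f"angle must be finite, got {angle}")
    return mesh.transformed(_rotation_z(angle))


def assemble_valve(cusp: CuspParameters, n_theta: int = 128, n_z: int = 64) -> SurfaceMesh:
    """Full valve: n rotated copies of the cusp mesh, welded at commissures.

    The assembled area is exactly n times the single-cusp mesh area (up to
    rotation round-off); the assembly is invariant under rotation by 2π/n.
    """
    base = build_cusp_mesh(cusp, n_theta, n_z)
    parts_v, parts_f = [], []
    offset = 0
    for angle in np.arange(cusp.n_cusps) * cusp.angular_extent:
        part = rotate_mesh(base, float(angle))
        parts_v.append(part.vertices)
        parts_f.append(part.faces + offset)
        offset += part.n_vertices
    merged = SurfaceMesh(vertices=np.vstack(parts_v), faces=np.vstack(parts_f))
    return merged.weld()
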