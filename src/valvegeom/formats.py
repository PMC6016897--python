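"""Reading and writing triangle meshes in common interchange formats.

Supported formats and their on-disk conventions:

``obj``
    Wavefront OBJ: ``v x y z`` lines then ``f i j k`` lines with 1-based
    indices (0-based in memory).
``stl-ascii`` / ``stl-binary``
    STL stores an unindexed triangle soup; binary STL coordinates are
    float32 per the format.
``ply``
    ASCII PLY 1.0 with double vertex properties and an index list per face.
``vtk-legacy``
    Legacy VTK ASCII POLYDATA.

Writes are atomic (temp file in the target directory, then rename), so a
failed write never leaves a partial output file.
"""

from __future__ import annotations

import os
import struct
import tempfile
from pathlib import Path

import numpy as np
import trimesh

from .mesh import SurfaceMesh

__all__ = ["FORMATS", "write_mesh", "read_mesh", "infer_format"]

FORMATS = ("stl-binary", "stl-ascii", "obj", "vtk-legacy", "ply")

_EXTENSIONS = {".stl": "stl-binary", ".obj": "obj", ".vtk": "vtk-legacy", ".ply": "ply"}

#: coordinate format for ASCII writers: 17 significant digits round-trips float64
_F = "{:.17g}"


class MeshFormatError(ValueError):
    """Unknown mesh format or malformed mesh file."""


def infer_format(path) -> str:
    ext = Path(path).suffix.lower()
    if ext not in _EXTENSIONS:
        raise MeshFormatError(f"cannot infer mesh format from extension {ext!r}")
    return _EXTENSIONS[ext]


def write_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> Path:
    """Write a mesh to ``path`` in the given (or extension-inferred) format."""
    path = Path(path)
    if fmt is None:
        fmt = infer_format(path)
    if fmt not in FORMATS:
        raise MeshFormatError(f"unknown mesh format {fmt!r}; expected one of {FORMATS}")
    writer = {
        "obj": _write_obj,
        "stl-ascii": _write_stl_ascii,
        "stl-binary": _write_stl_binary,
        "ply": _write_ply,
        "vtk-legacy": _write_vtk,
    }[fmt]
    mode = "wb" if fmt == "stl-binary" else "wt"
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=path.suffix + ".part")
    try:
        with os.fdopen(fd, mode) as fh:
            writer(mesh, fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def read_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Read a mesh back from disk.

    STL/OBJ/PLY go through ``trimesh`` (kept unprocessed, so vertex order
    and soup duplication are preserved); legacy VTK POLYDATA is parsed
    directly since no installed reader covers it.
    """
    path = Path(path)
    if fmt is None:
        fmt = infer_format(path)
    if fmt == "vtk-legacy":
        return _read_vtk(path)
    if fmt not in FORMATS:
        raise MeshFormatError(f"unknown mesh format {fmt!r}; expected one of {FORMATS}")
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
    )


def _write_obj(mesh: SurfaceMesh, fh) -> None:
    for x, y, z in mesh.vertices:
        fh.write(f"v {_F.format(x)} {_F.format(y)} {_F.format(z)}\n")
    for a, b, c in mesh.faces:
        fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


def _write_stl_ascii(mesh: SurfaceMesh, fh) -> None:
    normals = mesh.face_normals()
    p0, p1, p2 = mesh.triangle_corners()
    fh.write("solid valvegeom\n")
    for n, a, b, c in zip(normals, p0, p1, p2):
        fh.write(f"  facet normal {_F.format(n[0])} {_F.format(n[1])} {_F.format(n[2])}\n")
        fh.write("    outer loop\n")
        for v in (a, b, c):
            fh.write(f"      vertex {_F.format(v[0])} {_F.format(v[1])} {_F.format(v[2])}\n")
        fh.write("    endloop\n")
        fh.write("  endfacet\n")
    fh.write("endsolid valvegeom\n")


def _write_stl_binary(mesh: SurfaceMesh, fh) -> None:
    fh.write(b"valvegeom binary STL".ljust(80, b" "))
    fh.write(struct.pack("<I", mesh.n_faces))
    normals = mesh.face_normals().astype("<f4")
    p0, p1, p2 = (c.astype("<f4") for c in mesh.triangle_corners())
    record = np.zeros(
        mesh.n_faces,
        dtype=[("n", "<f4", 3), ("v0", "<f4", 3), ("v1", "<f4", 3), ("v2", "<f4", 3), ("attr", "<u2")],
    )
    record["n"], record["v0"], record["v1"], record["v2"] = normals, p0, p1, p2
    fh.write(record.tobytes())


def _write_ply(mesh: SurfaceMesh, fh) -> None:
    fh.write("ply\nformat ascii 1.0\n")
    fh.write(f"element vertex {mesh.n_vertices}\n")
    fh.write("property double x\nproperty double y\nproperty double z\n")
    fh.write(f"element face {mesh.n_faces}\n")
    fh.write("property list uchar int vertex_indices\nend_header\n")
    for x, y, z in mesh.vertices:
        fh.write(f"{_F.format(x)} {_F.format(y)} {_F.format(z)}\n")
    for a, b, c in mesh.faces:
        fh.write(f"3 {a} {b} {c}\n")


def _write_vtk(mesh: SurfaceMesh, fh) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write("valvegeom surface mesh\n")
    fh.write("ASCII\nDATASET POLYDATA\n")
    fh.write(f"POINTS {mesh.n_vertices} double\n")
    for x, y, z in mesh.vertices:
        fh.write(f"{_F.format(x)} {_F.format(y)} {_F.format(z)}\n")
    fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
    for a, b, c in mesh.faces:
        fh.write(f"3 {a} {b} {c}\n")


def _read_vtk(path: Path) -> SurfaceMesh:
    tokens: list[str] = []
    with open(path, "rt", encoding="ascii") as fh:
        header = fh.readline()
        if not header.startswith("# vtk DataFile Version"):
            raise MeshFormatError(f"{path} is not a legacy VTK file")
        fh.readline()  # title
        if fh.readline().strip().upper() != "ASCII":
            raise MeshFormatError("only ASCII legacy VTK is supported")
        if fh.readline().strip().upper() != "DATASET POLYDATA":
            raise MeshFormatError("only POLYDATA legacy VTK is supported")
        tokens = fh.read().split()
    it = iter(tokens)
    try:
        kw = next(it)
        if kw.upper() != "POINTS":
            raise MeshFormatError("expected POINTS block")
        n_pts = int(next(it))
        next(it)  # dtype
        verts = np.array([float(next(it)) for _ in range(3 * n_pts)]).reshape(n_pts, 3)
        kw = next(it)
        if kw.upper() != "POLYGONS":
            raise MeshFormatError("expected POLYGONS block")
        n_poly = int(next(it))
        next(it)  # list size
        faces = []
        for _ in range(n_poly):
            k = int(next(it))
            idx = [int(next(it)) for _ in range(k)]
            if k != 3:
                raise MeshFormatError("only triangle POLYGONS are supported")
            faces.append(idx)
    except StopIteration as exc:
        raise MeshFormatError(f"truncated VTK file {path}") from exc
    return SurfaceMesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64))
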