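"""Assemble tilings and caps into an indexed triangle mesh; validate and write it.

Vertices shared between adjacent tilings (each contour point appears in the
band below and the band above it, and possibly in a cap) are merged by exact
coordinate equality — contour points are passed through unmodified, never
recomputed, so bitwise comparison is safe and avoids epsilon-welding
pitfalls.  For a sealed, unbranched stack the result is a closed orientable
genus-0 surface: every edge borders exactly two faces and V - E + F = 2.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .contour_model import ContourStack
from .sealing import CapTriangulation
from .tiling import TilingPath


@dataclass
class SurfaceMesh:
    """Indexed triangle mesh with per-face provenance.

    ``provenance[f]`` is ``("tiling", pair_index)``, ``("cap", "bottom")`` or
    ``("cap", "top")`` for face f.
    """

    vertices: np.ndarray  # (V, 3) float64
    faces: np.ndarray  # (F, 3) int64
    provenance: List[Tuple[str, object]] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]


@dataclass
class WatertightReport:
    boundary_edges: int
    non_manifold_edges: int
    euler_characteristic: int
    oriented: bool

    @property
    def is_watertight(self) -> bool:
        return self.boundary_edges == 0 and self.non_manifold_edges == 0 and self.oriented


class _VertexPool:
    """Deduplicates vertices by exact coordinate equality."""

    def __init__(self) -> None:
        self._index: Dict[Tuple[float, float, float], int] = {}
        self.coords: List[Tuple[float, float, float]] = []

    def add(self, p) -> int:
        key = (float(p[0]), float(p[1]), float(p[2]))
        k = self._index.get(key)
        if k is None:
            k = len(self.coords)
            self._index[key] = k
            self.coords.append(key)
        return k


def assemble(
    stack: ContourStack,
    tilings: Sequence[TilingPath],
    caps: Sequence[CapTriangulation] = (),
) -> SurfaceMesh:
    """Merge per-pair tilings and end caps into one indexed mesh.

    Face windings are taken as built (outward for CCW contours with
    increasing z); shared contour vertices collapse to single indices.

    Raises
    ------
    ValueError
        If ``tilings`` is empty or does not cover every consecutive slice
        pair of the stack.
    """
    if not tilings:
        raise ValueError("no tilings to assemble")
    if len(tilings) != len(stack.slices) - 1:
        raise ValueError(
            f"expected {len(stack.slices) - 1} tilings for {len(stack.slices)} slices, "
            f"got {len(tilings)}"
        )
    pool = _VertexPool()
    faces: List[Tuple[int, int, int]] = []
    provenance: List[Tuple[str, object]] = []
    for k, tp in enumerate(tilings):
        for tile in tp.tiles:
            tri = tuple(pool.add(v) for v in tile.vertices)
            if len(set(tri)) < 3:
                continue  # degenerate tile (duplicated bridge points); carries no area
            faces.append(tri)
            provenance.append(("tiling", k))
    z_first = stack.slices[0].z
    for cap in caps:
        pts = cap.contour.points
        tag = ("cap", "bottom" if cap.contour.z == z_first else "top")
        for tri in cap.triangles:
            ids = tuple(pool.add(pts[t]) for t in tri)
            if len(set(ids)) < 3:
                raise ValueError("cap triangle references duplicated vertices")
            faces.append(ids)
            provenance.append(tag)
    return SurfaceMesh(
        vertices=np.array(pool.coords, dtype=np.float64),
        faces=np.array(faces, dtype=np.int64),
        provenance=provenance,
    )


def watertight_report(mesh: SurfaceMesh) -> WatertightReport:
    """Count boundary/non-manifold edges, Euler characteristic, orientation.

    A boundary edge has exactly one incident face; a non-manifold edge more
    than two.  Orientation is consistent iff every 2-face edge is traversed
    in opposite directions by its faces.
    """
    edge_faces: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for tri in mesh.faces:
        a, b, c = (int(v) for v in tri)
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            edge_faces.setdefault(key, []).append((u, v))
    boundary = sum(1 for fs in edge_faces.values() if len(fs) == 1)
    non_manifold = sum(1 for fs in edge_faces.values() if len(fs) > 2)
    oriented = all(
        len(fs) != 2 or fs[0] == (fs[1][1], fs[1][0]) for fs in edge_faces.values()
    )
    euler = mesh.n_vertices - len(edge_faces) + mesh.n_faces
    return WatertightReport(
        boundary_edges=boundary,
        non_manifold_edges=non_manifold,
        euler_characteristic=euler,
        oriented=oriented,
    )


def signed_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume by the divergence theorem (positive for outward winding)."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def _write_stl(mesh: SurfaceMesh, path) -> None:
    v = mesh.vertices
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", mesh.n_faces))
        for tri in mesh.faces:
            a, b, c = v[tri[0]], v[tri[1]], v[tri[2]]
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            fh.write(struct.pack("<3f", *n))
            for p in (a, b, c):
                fh.write(struct.pack("<3f", *p))
            fh.write(struct.pack("<H", 0))


def _write_ply(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


def _write_obj(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {float(x)!r} {float(y)!r} {float(z)!r}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")  # OBJ indices are 1-based


_WRITERS = {"stl": _write_stl, "ply": _write_ply, "obj": _write_obj}


def write_mesh(mesh: SurfaceMesh, path, fmt: str = None) -> None:
    """Write the mesh as binary STL, ascii PLY or ascii OBJ.

    ``fmt`` defaults to the path's suffix.  PLY and OBJ preserve the shared
    vertex indexing; STL necessarily duplicates vertices per facet.
    """
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    writer = _WRITERS.get(fmt)
    if writer is None:
        raise ValueError(f"unknown mesh format {fmt!r}; expected stl, ply or obj")
    writer(mesh, path)
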