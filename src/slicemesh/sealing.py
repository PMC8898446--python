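"""Planar caps closing the first and last slices of the reconstructed surface.

After tiling, the contours on the top and bottom slices leave open gaps; each
is closed with a 2D triangulation of the polygon interior that uses only the
contour's own vertices.  Plain Delaunay triangulation of the vertex set would
spill triangles outside a concave polygon, so a constrained triangulation
honoring the ring edges is used, with ear clipping as fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import shapely
from shapely.geometry import Polygon

from .contour_model import Contour, contour_winding, ensure_ccw


@dataclass
class CapTriangulation:
    """A triangulation of one end contour's interior.

    ``triangles`` are index triples into the contour's points (no new
    vertices); ``orientation`` is "up" (normal +z, top cap) or "down"
    (normal -z, bottom cap), and triangle winding matches it.
    """

    contour: Contour
    triangles: List[Tuple[int, int, int]]
    orientation: str


def _tri_signed_area(xy: np.ndarray, tri: Tuple[int, int, int]) -> float:
    a, b, c = xy[list(tri)]
    return 0.5 * float((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))


def _constrained_delaunay(xy: np.ndarray) -> List[Tuple[int, int, int]]:
    """Constrained Delaunay triangulation of the ring interior, as index triples.

    Returns None if the geometry backend introduces vertices not on the ring
    (should not happen for a simple polygon without Steiner points).
    """
    index = {(float(x), float(y)): k for k, (x, y) in enumerate(xy)}
    tris = shapely.constrained_delaunay_triangles(Polygon(xy))
    out = []
    for geom in tris.geoms:
        coords = list(geom.exterior.coords)[:-1]
        if len(coords) != 3:
            return None
        try:
            out.append(tuple(index[(c[0], c[1])] for c in coords))
        except KeyError:
            return None
    if len(out) != len(xy) - 2:
        return None
    return out


def _ear_clip(xy: np.ndarray) -> List[Tuple[int, int, int]]:
    """Ear-clipping triangulation of a simple CCW polygon (O(n^2))."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def in_triangle(p, a, b, c):
        d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
        return d1 >= 0 and d2 >= 0 and d3 >= 0

    idx = list(range(len(xy)))
    tris: List[Tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 10 * len(xy) ** 2:
            raise ValueError("ear clipping failed; contour may be self-intersecting")
        n = len(idx)
        clipped = False
        for k in range(n):
            a, b, c = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
            if cross(xy[a], xy[b], xy[c]) <= 0:
                continue  # reflex or degenerate corner
            if any(
                in_triangle(xy[q], xy[a], xy[b], xy[c])
                for q in idx
                if q not in (a, b, c)
            ):
                continue
            tris.append((a, b, c))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            raise ValueError("ear clipping stalled; contour may be self-intersecting")
    tris.append(tuple(idx))
    return tris


def seal_cap(contour: Contour, orientation: str) -> CapTriangulation:
    """Triangulate the contour's interior to cap one end of the model.

    Produces exactly n - 2 triangles covering the polygon with no overlap, no
    gap, and no new vertices.  Triangle winding is CCW (viewed from +z) for
    ``orientation="up"`` and CW for ``"down"``, so cap normals point away
    from the model interior.

    Raises
    ------
    ValueError
        For a self-intersecting contour or unknown orientation.
    """
    if orientation not in ("up", "down"):
        raise ValueError(f"orientation must be 'up' or 'down', got {orientation!r}")
    if not Polygon(contour.xy).is_valid:
        raise ValueError("cannot cap a self-intersecting contour")
    c = ensure_ccw(contour)
    # seal_cap indexes the *input* contour; ensure_ccw may have reversed it
    reversed_input = c.xy is not contour.xy and contour_winding(contour) == "cw"
    tris = _constrained_delaunay(c.xy)
    if tris is None:
        tris = _ear_clip(c.xy)
    n = len(c)
    if reversed_input:
        tris = [(n - 1 - a, n - 1 - b, n - 1 - c_) for a, b, c_ in tris]
    oriented = []
    for tri in tris:
        area = _tri_signed_area(contour.xy, tri)
        want_ccw = orientation == "up"
        if (area > 0) != want_ccw:
            tri = (tri[0], tri[2], tri[1])
        oriented.append(tri)
    return CapTriangulation(contour=contour, triangles=oriented, orientation=orientation)
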