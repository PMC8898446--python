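"""Minimal-area triangulation between consecutive contours.

The band of surface between two closed contours is built from elementary
triangular tiles, each using one contour segment (two consecutive points of
one ring) plus a single point of the other ring.  Choosing the best set of
tiles is a shortest-path search: a *span* (i, j) connects lower point i to
upper point j; from span P(i, j) the only legal moves are to P(i+1, j)
(laying a lower-segment tile) or P(i, j+1) (an upper-segment tile), and each
move is weighted by the area of the tile it lays down.  The minimal-weight
monotone path from the start span P(0, 0) to P(n, m) is the minimal-area
tiling.  Because both rings are cyclic the underlying graph is toroidal; it
is cut open at a start span, by default the closest point pair between the
two rings.

Contours may first be normalized — translated so the vertex centroid sits at
(0, 0) and scaled so the bounding rectangle becomes the unit square — so that
the area metric judges shape correspondence rather than absolute position and
size.  Normalization affects only the cost metric; emitted tiles always carry
the original coordinates.  Without it, two identical circles whose centers
are offset a diameter apart tile into a degenerate double cone pinched along
a line instead of the obvious skewed cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .contour_model import Contour, Point


@dataclass(frozen=True)
class Span:
    """An edge from lower-contour point i to upper-contour point j."""

    i: int
    j: int


@dataclass
class Tile:
    """One elementary triangle of the inter-slice band.

    ``kind`` records which ring contributed the contour segment: a "lower"
    tile uses segment (i, i+1) of the lower ring and apex j of the upper
    ring; an "upper" tile the reverse.  ``vertices`` are original (mm)
    coordinates, wound so the face normal points outward (CCW rings,
    increasing z).
    """

    vertices: np.ndarray  # (3, 3) float64
    kind: str  # "lower" | "upper"

    @property
    def area(self) -> float:
        a, b, c = self.vertices
        return triangle_area(a, b, c)


@dataclass
class TilingPath:
    """The optimal monotone path for one slice pair and its tiles.

    ``start`` is the (i, j) span in the rings' original indexing at which the
    toroidal graph was cut; ``moves`` is the sequence of "i"/"j" advances
    from P(0,0) to P(n,m) in the rotated indexing; ``spans`` lists the
    visited spans in original indexing (n + m + 1 entries, first == last
    modulo ring length).  ``total_cost`` is the path weight in the metric
    space used for optimization (normalized coordinates when normalization
    is on), while each tile's ``area`` is the original-space area.
    """

    n: int
    m: int
    start: Tuple[int, int]
    moves: List[str]
    spans: List[Tuple[int, int]]
    tiles: List[Tile]
    total_cost: float

    @property
    def total_area(self) -> float:
        """Summed original-space area of all tiles (mm^2)."""
        return float(sum(t.area for t in self.tiles))


@dataclass
class NormalizationParams:
    """Inverse map of contour normalization: centroid shift and window scale."""

    centroid: Tuple[float, float]
    window: Tuple[float, float]


def triangle_area(a, b, c) -> float:
    """Area of triangle ABC from the cross product: |BA x BC| / 2.

    Accepts 3-vectors (or Points); returns 0 for collinear inputs.
    """
    ba = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    bc = np.asarray(c, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    normal = np.cross(ba, bc)
    return float(np.sqrt(np.dot(normal, normal)) / 2.0)


def normalize_contour(contour: Contour) -> Tuple[Contour, NormalizationParams]:
    """Center the ring on its vertex centroid and scale its window to the unit square.

    x' = (x - cx) / width, y' = (y - cy) / height, where (cx, cy) is the
    arithmetic mean of the ring points and (width, height) the dimensions of
    the axis-aligned bounding rectangle.  z is left untouched.

    Raises
    ------
    ValueError
        If the bounding rectangle has zero width or height.
    """
    xy = contour.xy
    centroid = xy.mean(axis=0)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    window = hi - lo
    if window[0] == 0.0 or window[1] == 0.0:
        raise ValueError("degenerate bounding window; cannot normalize contour")
    out = (xy - centroid) / window
    return (
        Contour(out, contour.z),
        NormalizationParams(centroid=(float(centroid[0]), float(centroid[1])),
                            window=(float(window[0]), float(window[1]))),
    )


def closest_span(lower: Contour, upper: Contour) -> Span:
    """The span minimizing 3D point distance; ties broken by lowest (i, j).

    This is the start span that cuts the toroidal graph open.  It must be
    computed on the same coordinates used for the cost metric, so callers
    optimizing in normalized space pass normalized contours.
    """
    d = np.linalg.norm(lower.points[:, None, :] - upper.points[None, :, :], axis=2)
    i, j = np.argwhere(d == d.min())[0]
    return Span(int(i), int(j))


def _closed(points: np.ndarray) -> np.ndarray:
    """Ring points with the first point appended again (index n == index 0)."""
    return np.concatenate([points, points[:1]], axis=0)


def _dp(lower_pts: np.ndarray, upper_pts: np.ndarray) -> Tuple[float, List[str]]:
    """Shortest monotone path from P(0,0) to P(n,m) on closed point arrays.

    ``lower_pts``/``upper_pts`` have n+1 / m+1 rows with the last row equal
    to the first.  Returns (total cost, move sequence).  When both incoming
    paths to a span tie, the "advance i" (lower-tile) move is preferred, for
    determinism.
    """
    n = lower_pts.shape[0] - 1
    m = upper_pts.shape[0] - 1
    cost = np.full((n + 1, m + 1), np.inf)
    came = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 = from (i-1,j), 2 = from (i,j-1)
    cost[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best, via = np.inf, 0
            if i > 0:
                w = triangle_area(lower_pts[i - 1], lower_pts[i], upper_pts[j])
                c = cost[i - 1, j] + w
                if c < best:
                    best, via = c, 1
            if j > 0:
                w = triangle_area(upper_pts[j - 1], upper_pts[j], lower_pts[i])
                c = cost[i, j - 1] + w
                if c < best:
                    best, via = c, 2
            cost[i, j] = best
            came[i, j] = via
    moves: List[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if came[i, j] == 1:
            moves.append("i")
            i -= 1
        else:
            moves.append("j")
            j -= 1
    moves.reverse()
    return float(cost[n, m]), moves


def _path_from_moves(
    lower: Contour, upper: Contour, i0: int, j0: int, moves: List[str], total_cost: float
) -> TilingPath:
    n, m = len(lower), len(upper)
    lo = _closed(lower.rolled(i0).points)
    up = _closed(upper.rolled(j0).points)
    tiles: List[Tile] = []
    spans: List[Tuple[int, int]] = [(i0 % n, j0 % m)]
    i = j = 0
    for mv in moves:
        if mv == "i":
            # lower segment (i, i+1), apex upper j; CCW rings + increasing z
            # make (L[i], L[i+1], U[j]) the outward winding
            tiles.append(Tile(np.array([lo[i], lo[i + 1], up[j]]), "lower"))
            i += 1
        else:
            tiles.append(Tile(np.array([up[j + 1], up[j], lo[i]]), "upper"))
            j += 1
        spans.append(((i + i0) % n, (j + j0) % m))
    return TilingPath(
        n=n, m=m, start=(i0 % n, j0 % m), moves=list(moves), spans=spans,
        tiles=tiles, total_cost=total_cost,
    )


def tile_pair(
    lower: Contour,
    upper: Contour,
    normalize: bool = True,
    start: str = "closest",
) -> TilingPath:
    """Minimal-area tiling between two consecutive contours.

    Parameters
    ----------
    lower, upper : valid, keyhole-free single contours (branching resolved).
    normalize : optimize the path in normalized coordinates (centroids at
        the origin, windows scaled to the unit square).  Tiles always carry
        original coordinates; ``total_cost`` is the normalized-space optimum
        when this is on.
    start : ``"closest"`` cuts the toroidal graph at the closest point pair
        and runs a single O(nm) sweep; ``"exhaustive"`` re-runs the sweep
        from every upper-ring start offset and keeps the cheapest path,
        approximating the true minimum-cost cycle.

    Raises
    ------
    ValueError
        If either ring has fewer than 3 points or ``start`` is unknown.
    """
    n, m = len(lower), len(upper)
    if n < 3 or m < 3:
        raise ValueError("tiling needs at least 3 points on each contour")
    if normalize:
        cost_lower, _ = normalize_contour(lower)
        cost_upper, _ = normalize_contour(upper)
    else:
        cost_lower, cost_upper = lower, upper

    if start == "closest":
        s = closest_span(cost_lower, cost_upper)
        lo = _closed(cost_lower.rolled(s.i).points)
        up = _closed(cost_upper.rolled(s.j).points)
        total, moves = _dp(lo, up)
        return _path_from_moves(lower, upper, s.i, s.j, moves, total)
    if start == "exhaustive":
        best = None
        for j0 in range(m):
            lo = _closed(cost_lower.points)
            up = _closed(cost_upper.rolled(j0).points)
            total, moves = _dp(lo, up)
            if best is None or total < best[0]:
                best = (total, j0, moves)
        total, j0, moves = best
        return _path_from_moves(lower, upper, 0, j0, moves, total)
    raise ValueError(f"unknown start strategy: {start!r}")


def tile_stack(
    stack, normalize: bool = True, start: str = "closest"
) -> List[TilingPath]:
    """Tile every consecutive slice pair of a single-contour-per-slice stack."""
    tilings = []
    for k in range(len(stack.slices) - 1):
        lo_s, up_s = stack.slices[k], stack.slices[k + 1]
        if len(lo_s.contours) != 1 or len(up_s.contours) != 1:
            raise ValueError(
                f"slice pair ({k}, {k + 1}) does not hold one contour per slice; "
                "resolve branching first"
            )
        tilings.append(tile_pair(lo_s.contours[0], up_s.contours[0],
                                 normalize=normalize, start=start))
    return tilings
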