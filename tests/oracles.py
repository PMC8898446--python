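"""Independent oracles used to check the package's results.

These deliberately avoid the implementation's code paths: exhaustive
enumeration instead of dynamic programming, Heron's formula instead of the
cross product, shoelace sums, and O(n^2) scans.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def heron_area(a, b, c) -> float:
    """Triangle area from its side lengths (numerically stable variant)."""
    x = float(np.linalg.norm(np.subtract(b, a)))
    y = float(np.linalg.norm(np.subtract(c, b)))
    z = float(np.linalg.norm(np.subtract(a, c)))
    x, y, z = sorted((x, y, z), reverse=True)  # x >= y >= z
    under = (x + (y + z)) * (z - (x - y)) * (z + (x - y)) * (x + (y - z))
    return math.sqrt(max(under, 0.0)) / 4.0


def enumerate_min_tiling_cost(lower_pts: np.ndarray, upper_pts: np.ndarray) -> float:
    """Minimum tiling cost over ALL C(n+m, n) monotone paths, by brute force.

    ``lower_pts`` (n+1, 3) and ``upper_pts`` (m+1, 3) are closed rings (last
    row equals the first), already rotated to the fixed start span.
    """
    n = lower_pts.shape[0] - 1
    m = upper_pts.shape[0] - 1
    # area of every possible tile, computed independently of the package
    w_lo = np.empty((n, m + 1))
    for i in range(n):
        for j in range(m + 1):
            w_lo[i, j] = heron_area(lower_pts[i], lower_pts[i + 1], upper_pts[j])
    w_up = np.empty((m, n + 1))
    for j in range(m):
        for i in range(n + 1):
            w_up[j, i] = heron_area(upper_pts[j], upper_pts[j + 1], lower_pts[i])
    best = math.inf
    for i_steps in itertools.combinations(range(n + m), n):
        i_set = set(i_steps)
        i = j = 0
        total = 0.0
        for step in range(n + m):
            if step in i_set:
                total += w_lo[i, j]
                i += 1
            else:
                total += w_up[j, i]
                j += 1
        best = min(best, total)
    return best


def brute_force_nearest_pair(pts_a: np.ndarray, pts_b: np.ndarray):
    """Nearest cross pair by explicit double loop; lowest (i, j) on ties."""
    best = (math.inf, None)
    for i in range(len(pts_a)):
        for j in range(len(pts_b)):
            d = float(np.linalg.norm(pts_a[i] - pts_b[j]))
            if d < best[0]:
                best = (d, (i, j))
    return best[1], best[0]


def shoelace_area(xy: np.ndarray) -> float:
    """Absolute polygon area by direct shoelace summation."""
    total = 0.0
    n = len(xy)
    for k in range(n):
        x1, y1 = xy[k]
        x2, y2 = xy[(k + 1) % n]
        total += x1 * y2 - x2 * y1
    return abs(total) / 2.0


def point_in_polygon(p, xy: np.ndarray) -> bool:
    """Ray-casting point-in-polygon test."""
    x, y = p
    inside = False
    n = len(xy)
    for k in range(n):
        x1, y1 = xy[k]
        x2, y2 = xy[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            t = (y - y1) / (y2 - y1)
            if x < x1 + t * (x2 - x1):
                inside = not inside
    return inside


def min_nonadjacent_distance(xy: np.ndarray, window: int = 2) -> float:
    """Smallest distance between ring points more than ``window`` indices apart."""
    n = len(xy)
    best = math.inf
    for i in range(n):
        for j in range(i + 1, n):
            if min(j - i, n - (j - i)) <= window:
                continue
            best = min(best, float(np.linalg.norm(xy[i] - xy[j])))
    return best
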