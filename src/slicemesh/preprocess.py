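"""Branching resolution and keyhole removal, applied before tiling.

Branching: when adjacent slices hold different numbers of contours for the
same object (m contours facing n, m != n, n > 0), the side with more contours
has its co-planar contours bridged into one composite ring by a single edge
between their globally nearest points.  Complex branching (topology change
through saddle surfaces, holes) is out of scope.

Keyholes: a narrow channel where non-adjacent ring points come within a
threshold distance of each other destabilizes tiling; the points inside the
channel are removed and the ring re-closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon

from .contour_model import Contour, ContourStack, Slice

# Ring points at index distance <= ADJACENCY_WINDOW are "adjacent" and never
# in keyhole conflict; <= 2 avoids flagging every short edge pair on dense
# contours while still catching genuine channels.
ADJACENCY_WINDOW = 2


@dataclass
class BranchPlan:
    """The merges needed to equalize contour counts across one slice pair.

    ``side`` names the slice ("lower" or "upper") whose contours are merged;
    each merge records the pair of contour indices joined (indices into the
    working contour list at the time of that merge) and the bridge as a
    (point index in first contour, point index in second contour) pair.
    """

    slice_pair: Tuple[int, int] = (0, 1)
    side: Optional[str] = None
    merges: List[Tuple[Tuple[int, int], Tuple[int, int]]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.merges


@dataclass
class KeyholeReport:
    """What keyhole removal did to one contour.

    ``conflicts`` lists the (i, j) original-index pairs found within the
    threshold; ``removed`` lists the original indices of points deleted from
    inside the channel(s).
    """

    contour_index: Optional[int] = None
    threshold: float = 0.0
    conflicts: List[Tuple[int, int]] = field(default_factory=list)
    removed: List[int] = field(default_factory=list)


def nearest_point_pair(a: Contour, b: Contour) -> Tuple[int, int, float]:
    """Globally nearest point pair between two contours.

    Returns ``(i, j, distance)`` with i indexing ``a`` and j indexing ``b``,
    minimizing 3D Euclidean distance; ties broken by lowest (i, j)
    lexicographically.
    """
    d = np.linalg.norm(a.points[:, None, :] - b.points[None, :, :], axis=2)
    # argwhere scans row-major, so the first minimal entry is the
    # lexicographically smallest (i, j) pair
    i, j = np.argwhere(d == d.min())[0]
    return int(i), int(j), float(d[i, j])


def merge_branch_contours(contours: Sequence[Contour]) -> Contour:
    """Join co-planar contours into one composite ring bridged at nearest points.

    For two contours the composite traverses contour 1 up to its nearest
    point p, bridges to the nearest point q of contour 2, traverses all of
    contour 2 returning to q, bridges back to p, and completes contour 1;
    p and q each appear twice, so the composite has n1 + n2 + 2 points.
    With more than two contours the two closest contours are merged first,
    repeatedly.  A single contour is returned unchanged.

    Raises
    ------
    ValueError
        If any two of the contours overlap (the bridge construction assumes
        disjoint regions), or if their z coordinates differ.
    """
    working = list(contours)
    if not working:
        raise ValueError("no contours to merge")
    zs = {c.z for c in working}
    if len(zs) > 1:
        raise ValueError("contours to merge must share the same slice z")
    for a in range(len(working)):
        for b in range(a + 1, len(working)):
            if Polygon(working[a].xy).intersects(Polygon(working[b].xy)):
                raise ValueError(f"contours {a} and {b} overlap; cannot bridge")
    while len(working) > 1:
        (a, b), _ = _closest_contour_pair(working)
        merged = _merge_two(working[a], working[b])
        working = [c for k, c in enumerate(working) if k not in (a, b)] + [merged]
    return working[0]


def _closest_contour_pair(contours: Sequence[Contour]) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Pair of contour indices at minimal cross point distance, with its bridge."""
    best = None
    for a in range(len(contours)):
        for b in range(a + 1, len(contours)):
            i, j, d = nearest_point_pair(contours[a], contours[b])
            if best is None or d < best[0]:
                best = (d, (a, b), (i, j))
    assert best is not None
    return best[1], best[2]


def _merge_two(c1: Contour, c2: Contour) -> Contour:
    p, q, _ = nearest_point_pair(c1, c2)
    xy1, xy2 = c1.xy, c2.xy
    ring2 = np.roll(xy2, -q, axis=0)  # starts at q
    parts = [
        xy1[: p + 1],          # contour 1 up to and including p
        ring2,                 # all of contour 2 starting at q ...
        ring2[:1],             # ... returning to q
        xy1[p:],               # bridge back to p, complete contour 1
    ]
    return Contour(np.concatenate(parts, axis=0), c1.z)


def plan_branching(lower: Slice, upper: Slice, slice_pair: Tuple[int, int] = (0, 1)) -> BranchPlan:
    """Decide which contours to merge so both slices hold equally many.

    Equal counts produce an empty plan; otherwise the side with more contours
    is merged, closest pair of contours first, until counts match.

    Raises
    ------
    ValueError
        If either slice has zero contours (branching is only defined for
        n > 0 on both sides).
    """
    m, n = len(lower.contours), len(upper.contours)
    if m == 0 or n == 0:
        raise ValueError("branching requires at least one contour on each slice")
    plan = BranchPlan(slice_pair=slice_pair)
    if m == n:
        return plan
    side = "lower" if m > n else "upper"
    working = list(lower.contours if m > n else upper.contours)
    target = min(m, n)
    plan.side = side
    while len(working) > target:
        (a, b), bridge = _closest_contour_pair(working)
        plan.merges.append(((a, b), bridge))
        merged = _merge_two(working[a], working[b])
        working = [c for k, c in enumerate(working) if k not in (a, b)] + [merged]
    return plan


def resolve_branching(stack: ContourStack) -> ContourStack:
    """Sweep slice pairs in z order, merging the richer side until counts match.

    Returns a new stack; slices are shared where untouched.  Sweeping in
    order lets a merge on one slice propagate to the next pair, so a stack
    that branches once (e.g. one contour splitting into two) collapses to a
    single composite contour per slice.
    """
    slices = [Slice(z=s.z, contours=list(s.contours)) for s in stack.slices]
    for k in range(len(slices) - 1):
        lo, up = slices[k], slices[k + 1]
        plan = plan_branching(lo, up, slice_pair=(k, k + 1))
        if plan.is_empty:
            continue
        target = slices[k + 1] if plan.side == "upper" else slices[k]
        keep = min(len(lo.contours), len(up.contours))
        merged = _merge_until(target.contours, keep)
        target.contours = merged
    return ContourStack(slices=slices)


def _merge_until(contours: Sequence[Contour], target: int) -> List[Contour]:
    working = list(contours)
    while len(working) > target:
        (a, b), _ = _closest_contour_pair(working)
        merged = _merge_two(working[a], working[b])
        working = [c for k, c in enumerate(working) if k not in (a, b)] + [merged]
    return working


def _ring_index_distance(i: int, j: int, n: int) -> int:
    d = abs(i - j)
    return min(d, n - d)


def _find_conflicts(xy: np.ndarray, threshold: float) -> List[Tuple[int, int]]:
    """All non-adjacent index pairs strictly within the threshold distance."""
    n = xy.shape[0]
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if _ring_index_distance(i, j, n) <= ADJACENCY_WINDOW:
                continue
            if d[i, j] < threshold:
                out.append((i, j))
    return out


def default_keyhole_threshold(contour: Contour) -> float:
    """1.5x the median edge length of the ring — adapts to contour density."""
    edges = np.linalg.norm(contour.xy - np.roll(contour.xy, -1, axis=0), axis=1)
    return 1.5 * float(np.median(edges))


def remove_keyholes(
    contour: Contour,
    threshold: float,
    contour_index: Optional[int] = None,
) -> Tuple[Contour, KeyholeReport]:
    """Delete the points inside keyhole channels and re-close the ring.

    Every pair of non-adjacent ring points closer than ``threshold`` is in
    conflict.  Conflicts are resolved lowest-(i, j) first: the shorter of the
    two arcs between the conflicting points (by point count; ties remove the
    forward arc) is deleted and the points joined directly.  The scan repeats
    until no conflict remains, so the operation is idempotent and the output
    satisfies: every non-adjacent pair is at distance >= threshold.

    Raises
    ------
    ValueError
        If threshold < 0, or removal would leave fewer than 3 points.
    """
    if threshold < 0:
        raise ValueError("keyhole threshold must be >= 0")
    report = KeyholeReport(contour_index=contour_index, threshold=threshold)
    orig = list(range(len(contour)))  # original index of each surviving point
    xy = contour.xy.copy()
    while True:
        n = xy.shape[0]
        if n < 3:
            raise ValueError(
                "keyhole removal left fewer than 3 points; threshold too large for this contour"
            )
        conflicts = _find_conflicts(xy, threshold)
        if not conflicts:
            break
        for i, j in conflicts:
            pair = (orig[i], orig[j])
            if pair not in report.conflicts:
                report.conflicts.append(pair)
        i, j = conflicts[0]
        forward = [(k % n) for k in range(i + 1, i + (j - i))]  # strictly between, i->j
        backward = [(k % n) for k in range(j + 1, j + (n - (j - i)))]
        arc = forward if len(forward) <= len(backward) else backward
        report.removed.extend(orig[k] for k in sorted(arc))
        keep = sorted(set(range(n)) - set(arc))
        xy = xy[keep]
        orig = [orig[k] for k in keep]
    return Contour(xy, contour.z), report


def remove_stack_keyholes(
    stack: ContourStack, threshold: Optional[float] = None
) -> Tuple[ContourStack, List[KeyholeReport]]:
    """Apply keyhole removal to every contour of the stack.

    ``threshold=None`` uses :func:`default_keyhole_threshold` per contour.
    """
    reports: List[KeyholeReport] = []
    slices = []
    flat_index = 0
    for sl in stack.slices:
        contours = []
        for c in sl.contours:
            t = default_keyhole_threshold(c) if threshold is None else threshold
            cleaned, rep = remove_keyholes(c, t, contour_index=flat_index)
            contours.append(cleaned)
            reports.append(rep)
            flat_index += 1
        slices.append(Slice(z=sl.z, contours=contours))
    return ContourStack(slices=slices), reports
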