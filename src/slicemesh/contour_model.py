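"""Core geometric types for contour stacks and the canonical JSON file format.

A segmented object (e.g. a femur from CT) is stored as an ordered stack of
parallel slices, each slice holding one or more closed polygonal contours at
a constant z coordinate.  All coordinates are millimetres.

Conventions (applied uniformly across the package):

* A contour ring is *implicitly* closed: the edge from the last point back to
  the first is implied and the first point is never repeated at the end, so a
  contour of ``n`` points has exactly ``n`` contour segments.
* Winding is counter-clockwise (CCW) when viewed from +z; :func:`read_stack`
  normalizes winding on load so outward surface normals are consistent.
* All indexing is 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, NamedTuple, Sequence

import numpy as np
from shapely.geometry import LinearRing, Polygon


class Point(NamedTuple):
    """A 3D point; x and y lie on the slice plane, z is the slice position (mm)."""

    x: float
    y: float
    z: float


@dataclass
class Contour:
    """An ordered, implicitly closed ring of points at constant z.

    Parameters
    ----------
    xy : (n, 2) array of in-plane coordinates, in ring order.
    z : the slice coordinate shared by every point of the ring.
    """

    xy: np.ndarray
    z: float

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError(f"contour xy must be (n, 2), got {self.xy.shape}")
        self.z = float(self.z)

    def __len__(self) -> int:
        return self.xy.shape[0]

    @property
    def points(self) -> np.ndarray:
        """The ring as an (n, 3) array of 3D coordinates."""
        n = len(self)
        out = np.empty((n, 3))
        out[:, :2] = self.xy
        out[:, 2] = self.z
        return out

    def point(self, i: int) -> Point:
        """The i-th ring point (index taken modulo ring length) as a Point."""
        x, y = self.xy[i % len(self)]
        return Point(float(x), float(y), self.z)

    def reversed(self) -> "Contour":
        """Same ring traversed in the opposite direction (winding flipped)."""
        return Contour(self.xy[::-1].copy(), self.z)

    def rolled(self, k: int) -> "Contour":
        """Same ring re-indexed so current index ``k`` becomes index 0."""
        return Contour(np.roll(self.xy, -k, axis=0), self.z)


@dataclass
class Slice:
    """One constant-z plane holding the closed contours segmented on it."""

    z: float
    contours: List[Contour] = field(default_factory=list)


@dataclass
class ContourStack:
    """Ordered slices at strictly increasing z; the input to reconstruction."""

    slices: List[Slice] = field(default_factory=list)


def signed_area(contour: Contour) -> float:
    """Shoelace signed area of the ring projected onto the slice plane.

    Positive for CCW winding viewed from +z, negative for CW.
    """
    xy = contour.xy
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def contour_winding(contour: Contour) -> str:
    """Return ``"ccw"`` or ``"cw"`` from the sign of the shoelace area.

    Raises
    ------
    ValueError
        If the ring has fewer than 3 points or zero signed area (degenerate,
        e.g. collinear points), making the winding undefined.
    """
    if len(contour) < 3:
        raise ValueError("winding undefined for a ring with fewer than 3 points")
    a = signed_area(contour)
    if a == 0.0:
        raise ValueError("degenerate contour: zero signed area")
    return "ccw" if a > 0 else "cw"


def ensure_ccw(contour: Contour) -> Contour:
    """Return the contour with CCW winding, reversing point order if needed."""
    return contour if contour_winding(contour) == "ccw" else contour.reversed()


def _ring_is_simple(contour: Contour) -> bool:
    try:
        return bool(LinearRing(contour.xy).is_simple)
    except Exception:
        return False


def validate_stack(stack: ContourStack) -> List[str]:
    """Check every stack/slice/contour invariant; return one message per violation.

    Diagnostic only: never raises on bad geometry.  An empty list means the
    stack is valid input for the reconstruction pipeline.
    """
    problems: List[str] = []
    if len(stack.slices) < 2:
        problems.append("stack has fewer than 2 slices; no tiling is defined")
    prev_z = None
    for si, sl in enumerate(stack.slices):
        if prev_z is not None and sl.z <= prev_z:
            problems.append(f"slice {si}: z={sl.z} not greater than previous z={prev_z}")
        prev_z = sl.z
        if not sl.contours:
            problems.append(f"slice {si}: has no contours")
        for ci, c in enumerate(sl.contours):
            tag = f"slice {si} contour {ci}"
            if len(c) < 3:
                problems.append(f"{tag}: fewer than 3 points")
                continue
            if not np.all(np.isfinite(c.xy)) or not np.isfinite(c.z):
                problems.append(f"{tag}: non-finite coordinate")
                continue
            if c.z != sl.z:
                problems.append(f"{tag}: contour z={c.z} differs from slice z={sl.z}")
            dup = np.all(c.xy == np.roll(c.xy, -1, axis=0), axis=1)
            if np.any(dup):
                problems.append(f"{tag}: consecutive identical points")
                continue
            try:
                if contour_winding(c) != "ccw":
                    problems.append(f"{tag}: clockwise winding")
            except ValueError:
                problems.append(f"{tag}: degenerate (zero signed area)")
                continue
            if not _ring_is_simple(c):
                problems.append(f"{tag}: self-intersecting ring")
        # pairwise disjointness of contours within the slice
        for a in range(len(sl.contours)):
            for b in range(a + 1, len(sl.contours)):
                ca, cb = sl.contours[a], sl.contours[b]
                if len(ca) < 3 or len(cb) < 3:
                    continue
                try:
                    if Polygon(ca.xy).intersects(Polygon(cb.xy)):
                        problems.append(f"slice {si}: contours {a} and {b} intersect")
                except Exception:
                    pass
    return problems


def stack_to_dict(stack: ContourStack) -> dict:
    """Canonical JSON-serializable form of a stack (see :func:`write_stack`)."""
    return {
        "slices": [
            {
                "z": sl.z,
                "contours": [[[float(x), float(y)] for x, y in c.xy] for c in sl.contours],
            }
            for sl in stack.slices
        ]
    }


def stack_from_dict(data: dict) -> ContourStack:
    """Build a stack from the canonical dict form, normalizing winding to CCW."""
    if not isinstance(data, dict) or "slices" not in data:
        raise ValueError("contour-stack file: missing top-level 'slices' field")
    slices = []
    for si, sd in enumerate(data["slices"]):
        if "z" not in sd:
            raise ValueError(f"contour-stack file: slice {si} missing 'z' field")
        if "contours" not in sd:
            raise ValueError(f"contour-stack file: slice {si} missing 'contours' field")
        z = float(sd["z"])
        contours = []
        for ci, ring in enumerate(sd["contours"]):
            xy = np.asarray(ring, dtype=np.float64)
            if xy.ndim != 2 or xy.shape[1] != 2:
                raise ValueError(
                    f"contour-stack file: slice {si} contour {ci} is not a list of [x, y] pairs"
                )
            c = Contour(xy, z)
            if len(c) >= 3 and signed_area(c) != 0.0:
                c = ensure_ccw(c)
            contours.append(c)
        slices.append(Slice(z=z, contours=contours))
    return ContourStack(slices=slices)


def read_stack(path) -> ContourStack:
    """Read a contour stack from its canonical JSON file.

    The file schema is ``{"slices": [{"z": number,
    "contours": [[[x, y], ...], ...]}, ...]}`` with coordinates in mm.
    Winding is normalized to CCW on load.
    """
    with open(path) as fh:
        data = json.load(fh)
    return stack_from_dict(data)


def write_stack(stack: ContourStack, path) -> None:
    """Write a stack as canonical JSON; read-back reproduces coordinates bit-exactly."""
    with open(path, "w") as fh:
        json.dump(stack_to_dict(stack), fh, indent=1)
        fh.write("\n")
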