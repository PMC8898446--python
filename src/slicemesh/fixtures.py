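"""Deterministic synthetic contour stacks emulating segmented bone cross-sections.

No external or medical data is needed anywhere in the package: these
generators produce the geometries each pipeline stage is exercised on —
straight and skewed cylinders, cones, a Y-branch (one contour splitting into
two), a C-shaped contour with a narrow keyhole channel, and seeded random
convex sections.  The same spec and seed always produce a bitwise-identical
stack.

Circle-like contours are sampled at uniform angles starting at angle 0 for
index 0, so expected point correspondences are predictable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .contour_model import Contour, ContourStack, Slice

KINDS = ("cylinder", "skewed_cylinder", "cone", "y_branch", "keyhole_c", "random_convex")

# channel width of the keyhole_c fixture and the threshold documented to
# detect it (channel < threshold < everything else)
KEYHOLE_CHANNEL_WIDTH = 0.2
KEYHOLE_THRESHOLD = 0.5


@dataclass
class FixtureSpec:
    """Parameters of one synthetic stack; same spec + seed is reproducible."""

    kind: str
    n_points: int = 32
    n_slices: int = 5
    spacing: float = 2.0  # mm, within the 1-5 mm range typical of CT stacks
    radius: float = 10.0  # mm
    offset: Optional[float] = None  # per-slice center shift (skewed_cylinder)
    channel_width: float = KEYHOLE_CHANNEL_WIDTH  # mm (keyhole_c)
    seed: int = 0


def _circle(radius: float, n: int, center=(0.0, 0.0), z: float = 0.0) -> Contour:
    theta = 2.0 * np.pi * np.arange(n) / n
    xy = np.column_stack([center[0] + radius * np.cos(theta),
                          center[1] + radius * np.sin(theta)])
    return Contour(xy, z)


def _cylinder(spec: FixtureSpec) -> ContourStack:
    return ContourStack([
        Slice(z=k * spec.spacing,
              contours=[_circle(spec.radius, spec.n_points, z=k * spec.spacing)])
        for k in range(spec.n_slices)
    ])


def _skewed_cylinder(spec: FixtureSpec) -> ContourStack:
    offset = 2.0 * spec.radius if spec.offset is None else spec.offset
    return ContourStack([
        Slice(z=k * spec.spacing,
              contours=[_circle(spec.radius, spec.n_points,
                                center=(k * offset, 0.0), z=k * spec.spacing)])
        for k in range(spec.n_slices)
    ])


def _cone(spec: FixtureSpec) -> ContourStack:
    k_max = spec.n_slices - 1
    slices = []
    for k in range(spec.n_slices):
        # shrink linearly to 30% of the base radius; never to a point, so
        # every slice keeps a valid ring
        r = spec.radius * (1.0 - 0.7 * k / max(k_max, 1))
        slices.append(Slice(z=k * spec.spacing,
                            contours=[_circle(r, spec.n_points, z=k * spec.spacing)]))
    return ContourStack(slices)


def _y_branch(spec: FixtureSpec) -> ContourStack:
    if spec.n_slices < 2:
        raise ValueError("y_branch needs at least 2 slices")
    split = spec.n_slices // 2  # slices [0, split) single, [split, end] double
    slices = []
    r_small = spec.radius * 0.4
    dx = spec.radius * 0.55
    for k in range(spec.n_slices):
        z = k * spec.spacing
        if k < split:
            contours = [_circle(spec.radius, spec.n_points, z=z)]
        else:
            contours = [
                _circle(r_small, spec.n_points, center=(-dx, 0.0), z=z),
                _circle(r_small, spec.n_points, center=(dx, 0.0), z=z),
            ]
        slices.append(Slice(z=z, contours=contours))
    return ContourStack(slices)


def _keyhole_c_ring(radius: float, width: float, z: float) -> Contour:
    """A disk with a narrow radial slit: the classic keyhole channel.

    The slit walls sit at y = +-width/2 and reach 60% of the way to the
    center; wall points face each other across the channel at distance
    ``width``, far below the spacing of the outer arc points.
    """
    n_arc = 40
    n_wall = 4
    theta0 = np.arcsin((width / 2.0) / radius)
    theta = np.linspace(theta0, 2.0 * np.pi - theta0, n_arc)
    outer = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    x_outer = radius * np.cos(theta0)
    x_inner = radius * 0.4
    xs = np.linspace(x_outer, x_inner, n_wall + 1)[1:]  # exclude the arc endpoint
    lower_wall = np.column_stack([xs, np.full(n_wall, -width / 2.0)])
    upper_wall = np.column_stack([xs[::-1], np.full(n_wall, width / 2.0)])
    xy = np.concatenate([outer, lower_wall, upper_wall], axis=0)
    return Contour(xy, z)


def _keyhole_c(spec: FixtureSpec) -> ContourStack:
    return ContourStack([
        Slice(z=k * spec.spacing,
              contours=[_keyhole_c_ring(spec.radius, spec.channel_width,
                                        z=k * spec.spacing)])
        for k in range(spec.n_slices)
    ])


def random_convex_contour(
    n: int, radius: float, rng: np.random.Generator, z: float = 0.0
) -> Contour:
    """A seeded random convex ring of exactly n points.

    Points are sampled on the convex curve r(t) = R (1 + 0.3 sin(t + phi))
    at jittered uniform angles; the curve's curvature stays positive for the
    0.3 amplitude, so any inscribed polygon is convex.
    """
    phi = rng.uniform(0.0, 2.0 * np.pi)
    jitter = rng.uniform(-0.3, 0.3, size=n)
    theta = 2.0 * np.pi * (np.arange(n) + jitter) / n
    r = radius * (1.0 + 0.3 * np.sin(theta + phi))
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Contour(xy, z)


def _random_convex(spec: FixtureSpec) -> ContourStack:
    rng = np.random.default_rng(spec.seed)
    return ContourStack([
        Slice(z=k * spec.spacing,
              contours=[random_convex_contour(spec.n_points, spec.radius, rng,
                                              z=k * spec.spacing)])
        for k in range(spec.n_slices)
    ])


_BUILDERS = {
    "cylinder": _cylinder,
    "skewed_cylinder": _skewed_cylinder,
    "cone": _cone,
    "y_branch": _y_branch,
    "keyhole_c": _keyhole_c,
    "random_convex": _random_convex,
}


def make_fixture(spec: FixtureSpec) -> ContourStack:
    """Build the synthetic stack described by ``spec``.

    Raises
    ------
    ValueError
        For an unknown kind or invalid parameter ranges.
    """
    if spec.kind not in _BUILDERS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; expected one of {KINDS}")
    if spec.n_points < 3:
        raise ValueError("n_points must be >= 3")
    if spec.n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    if spec.spacing <= 0 or spec.radius <= 0:
        raise ValueError("spacing and radius must be positive")
    if spec.channel_width <= 0:
        raise ValueError("channel_width must be positive")
    return _BUILDERS[spec.kind](spec)
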