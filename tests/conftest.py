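import numpy as np
import pytest

from slicemesh.contour_model import Contour, ContourStack, Slice


def square_contour(side=1.0, center=(0.0, 0.0), z=0.0) -> Contour:
    h = side / 2.0
    cx, cy = center
    xy = np.array([[cx - h, cy - h], [cx + h, cy - h],
                   [cx + h, cy + h], [cx - h, cy + h]])
    return Contour(xy, z)


def square_prism_stack(side=1.0, spacing=1.0, n_slices=3) -> ContourStack:
    return ContourStack([
        Slice(z=k * spacing, contours=[square_contour(side, z=k * spacing)])
        for k in range(n_slices)
    ])


def star_contour(rng: np.random.Generator, n: int, radius=10.0, z=0.0) -> Contour:
    """Random simple (star-shaped, possibly concave) ring of exactly n points."""
    jitter = rng.uniform(-0.3, 0.3, size=n)
    theta = 2.0 * np.pi * (np.arange(n) + jitter) / n
    r = radius * rng.uniform(0.5, 1.0, size=n)
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Contour(xy, z)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
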