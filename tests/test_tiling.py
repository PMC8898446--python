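import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slicemesh.contour_model import Contour
from slicemesh.fixtures import FixtureSpec, make_fixture, random_convex_contour
from slicemesh.tiling import (
    _closed, closest_span, normalize_contour, tile_pair, triangle_area,
)

from conftest import square_contour
from oracles import enumerate_min_tiling_cost, heron_area


class TestTriangleArea:
    def test_unit_right_triangle(self):
        assert triangle_area((0, 0, 0), (1, 0, 0), (0, 1, 0)) == 0.5

    def test_collinear_is_zero(self):
        assert triangle_area((0, 0, 0), (1, 1, 1), (2, 2, 2)) == 0.0

    def test_matches_herons_formula_on_random_triples(self, rng):
        pts = rng.uniform(-50, 50, size=(1000, 3, 3))
        for a, b, c in pts:
            expect = heron_area(a, b, c)
            got = triangle_area(a, b, c)
            assert got == pytest.approx(expect, rel=1e-9, abs=1e-12)


class TestNormalizeContour:
    def test_already_unit_is_identity(self):
        c = Contour([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]], 0.0)
        out, params = normalize_contour(c)
        assert np.allclose(out.xy, c.xy)
        assert params.window == (1.0, 1.0)

    def test_translation_invariance(self, rng):
        c = random_convex_contour(12, 5.0, rng)
        shifted = Contour(c.xy + np.array([17.0, -4.0]), c.z)
        out1, _ = normalize_contour(c)
        out2, _ = normalize_contour(shifted)
        assert np.allclose(out1.xy, out2.xy)

    def test_ellipse_window_and_mapped_point(self):
        # ellipse semi-axes (2, 1) centered at (5, 7), dense uniform sampling
        t = 2 * np.pi * np.arange(400) / 400
        xy = np.column_stack([5 + 2 * np.cos(t), 7 + np.sin(t)])
        out, params = normalize_contour(Contour(xy, 0.0))
        assert params.window == pytest.approx((4.0, 2.0))
        assert params.centroid == pytest.approx((5.0, 7.0), abs=1e-9)
        # rightmost point (7, 7) maps to (0.5, 0)
        assert out.xy[0] == pytest.approx([0.5, 0.0], abs=1e-9)

    def test_centroid_moves_to_origin(self, rng):
        c = random_convex_contour(15, 8.0, rng)
        out, _ = normalize_contour(c)
        assert np.allclose(out.xy.mean(axis=0), 0.0, atol=1e-12)

    def test_degenerate_window_rejected(self):
        c = Contour([[0, 0], [1, 0], [2, 0]], 0.0)
        with pytest.raises(ValueError):
            normalize_contour(c)


class TestClosestSpan:
    def test_aligned_squares_start_at_origin_span(self):
        lo = square_contour(z=0.0)
        up = square_contour(z=1.0)
        s = closest_span(lo, up)
        assert (s.i, s.j) == (0, 0)

    def test_matches_exhaustive_scan(self, rng):
        lo = random_convex_contour(12, 10.0, rng, z=0.0)
        up = random_convex_contour(15, 9.0, rng, z=2.0)
        s = closest_span(lo, up)
        d = np.linalg.norm(lo.points[:, None] - up.points[None, :], axis=2)
        assert d[s.i, s.j] == d.min()
        ties = np.argwhere(d == d.min())
        assert (s.i, s.j) == tuple(ties[0])

    def test_rotated_ring_shifts_the_start(self):
        lo = square_contour(z=0.0)
        up = Contour(np.roll(square_contour(z=1.0).xy, 1, axis=0), 1.0)
        s = closest_span(lo, up)
        assert lo.point(s.i).x == up.point(s.j).x
        assert lo.point(s.i).y == up.point(s.j).y


class TestTilePair:
    def test_square_prism_closed_form(self):
        lo = square_contour(z=0.0)
        up = square_contour(z=1.0)
        tp = tile_pair(lo, up, normalize=False)
        assert len(tp.tiles) == 8
        assert tp.total_area == pytest.approx(4.0)
        assert tp.total_cost == pytest.approx(4.0)

    def test_tile_count_and_segment_coverage(self, rng):
        lo = random_convex_contour(9, 10.0, rng, z=0.0)
        up = random_convex_contour(13, 8.0, rng, z=2.0)
        tp = tile_pair(lo, up)
        assert len(tp.tiles) == 9 + 13
        assert sum(t.kind == "lower" for t in tp.tiles) == 9
        assert sum(t.kind == "upper" for t in tp.tiles) == 13
        assert tp.moves.count("i") == 9 and tp.moves.count("j") == 13

    @pytest.mark.parametrize("n", [8, 32, 128])
    def test_inscribed_prism_closed_form(self, n):
        r, h = 10.0, 3.0
        spec = FixtureSpec("cylinder", n_points=n, n_slices=2, spacing=h, radius=r)
        stack = make_fixture(spec)
        tp = tile_pair(stack.slices[0].contours[0], stack.slices[1].contours[0],
                       normalize=False)
        expect = 2 * n * r * np.sin(np.pi / n) * h
        assert tp.total_area == pytest.approx(expect, rel=1e-9)

    def test_doubling_spacing_doubles_lateral_area(self, rng):
        c = random_convex_contour(20, 10.0, rng)
        a1 = tile_pair(Contour(c.xy, 0.0), Contour(c.xy, 1.0), normalize=False).total_area
        a2 = tile_pair(Contour(c.xy, 0.0), Contour(c.xy, 2.0), normalize=False).total_area
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_congruent_aligned_contours_use_identity_matching(self, rng):
        c = random_convex_contour(16, 10.0, rng)
        tp = tile_pair(Contour(c.xy, 0.0), Contour(c.xy, 2.0), normalize=False)
        assert {(k, k) for k in range(16)} <= set(tp.spans)

    def test_skewed_circles_normalized_match_aligned_correspondence(self):
        n = 24
        aligned = make_fixture(FixtureSpec("cylinder", n_points=n, n_slices=2))
        skewed = make_fixture(FixtureSpec("skewed_cylinder", n_points=n, n_slices=2))
        ta = tile_pair(aligned.slices[0].contours[0], aligned.slices[1].contours[0],
                       normalize=True)
        ts = tile_pair(skewed.slices[0].contours[0], skewed.slices[1].contours[0],
                       normalize=True)
        assert ta.start == ts.start
        # both correspondences are the identity matching: all diagonal
        # spans visited, path within one step of the diagonal
        for tp in (ta, ts):
            assert {(k, k) for k in range(n)} <= set(tp.spans)
            i = j = 0
            for mv in tp.moves:
                i, j = (i + 1, j) if mv == "i" else (i, j + 1)
                assert abs(i - j) <= 1

    def test_cost_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 8))
            m = int(rng.integers(3, 8))
            lo = random_convex_contour(n, 10.0, rng, z=0.0)
            up = random_convex_contour(m, 8.0, rng, z=2.0)
            tp = tile_pair(lo, up, normalize=False)
            s = closest_span(lo, up)
            expect = enumerate_min_tiling_cost(
                _closed(lo.rolled(s.i).points), _closed(up.rolled(s.j).points)
            )
            assert tp.total_cost == pytest.approx(expect, rel=1e-12, abs=1e-12)

    def test_exhaustive_start_never_worse_than_closest(self, rng):
        lo = random_convex_contour(10, 10.0, rng, z=0.0)
        up = random_convex_contour(12, 6.0, rng, z=2.0)
        a = tile_pair(lo, up, start="closest")
        b = tile_pair(lo, up, start="exhaustive")
        assert b.total_cost <= a.total_cost + 1e-12

    def test_small_rings_rejected(self):
        lo = square_contour(z=0.0)
        bad = Contour([[0, 0], [1, 0]], 1.0)
        with pytest.raises(ValueError):
            tile_pair(lo, bad)
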