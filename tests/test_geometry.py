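import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipcongruency.errors import InvalidPolygonError, ParameterError
from hipcongruency.geometry import (
    CircleSpec,
    Point2D,
    Polygon2D,
    circle_circle_overlap_area,
    circle_polygon,
    grid_overlap_oracle,
    intersection_area,
    polygon_area,
    polygon_intersection,
)
from tests.conftest import random_simple_polygon

LENS_R1_D1 = 2.0 * math.acos(0.5) - 0.5 * math.sqrt(3.0)  # unit circles, centers 1 apart


class TestPolygonValidation:
    def test_too_few_vertices(self):
        with pytest.raises(InvalidPolygonError):
            Polygon2D([(0, 0), (1, 0)])

    def test_nonfinite_coordinate(self):
        with pytest.raises(InvalidPolygonError):
            Polygon2D([(0, 0), (1, float("nan")), (1, 1)])
        with pytest.raises(InvalidPolygonError):
            Point2D(float("inf"), 0.0)

    def test_consecutive_duplicates_rejected(self):
        with pytest.raises(InvalidPolygonError):
            Polygon2D([(0, 0), (0, 0), (1, 0), (1, 1)])

    def test_closing_duplicate_dropped(self):
        p = Polygon2D([(0, 0), (1, 0), (1, 1), (0, 0)])
        assert len(p) == 3

    def test_self_intersection_rejected(self):
        with pytest.raises(InvalidPolygonError):
            Polygon2D([(0, 0), (1, 1), (1, 0), (0, 1)])  # bowtie


class TestPolygonArea:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == 1.0

    def test_right_triangle(self):
        assert polygon_area(Polygon2D([(0, 0), (4, 0), (0, 3)])) == 6.0

    def test_regular_1024gon_closed_form(self):
        n, r = 1024, 100.0
        expected = 0.5 * n * r * r * math.sin(2 * math.pi / n)
        p = circle_polygon(CircleSpec(Point2D(37.0, -12.5), r), n)
        assert polygon_area(p) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_cyclic_rotation_and_reversal(self, rng):
        p = random_simple_polygon(rng)
        a = polygon_area(p)
        coords = p.coords
        rolled = Polygon2D(np.roll(coords, 3, axis=0))
        reversed_ = Polygon2D(coords[::-1])
        assert polygon_area(rolled) == pytest.approx(a, rel=1e-12)
        assert polygon_area(reversed_) == pytest.approx(a, rel=1e-12)

    @given(s=st.floats(min_value=0.01, max_value=100.0), seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_scales_quadratically(self, s, seed):
        p = random_simple_polygon(np.random.default_rng(seed))
        assert polygon_area(p.scaled(s)) == pytest.approx(s * s * polygon_area(p), rel=1e-9)


class TestPolygonIntersection:
    def test_offset_squares(self, unit_square):
        other = unit_square.translated(0.5, 0.5)
        pieces = polygon_intersection(unit_square, other)
        assert len(pieces) == 1
        assert polygon_area(pieces[0]) == pytest.approx(0.25)

    def test_disjoint_empty(self, unit_square):
        assert polygon_intersection(unit_square, unit_square.translated(5, 5)) == []

    def test_boundary_touch_is_empty(self, unit_square):
        assert polygon_intersection(unit_square, unit_square.translated(1.0, 0.0)) == []

    def test_circle_lens_closed_form(self):
        a = circle_polygon(CircleSpec(Point2D(0, 0), 1.0), 2048)
        b = circle_polygon(CircleSpec(Point2D(1, 0), 1.0), 2048)
        pieces = polygon_intersection(a, b)
        assert len(pieces) == 1
        assert polygon_area(pieces[0]) == pytest.approx(LENS_R1_D1, rel=1e-3)

    def test_nonconvex_supported(self):
        # C-shaped polygon clipped by a square crossing both arms: two pieces
        c_shape = Polygon2D(
            [(0, 0), (4, 0), (4, 1), (1, 1), (1, 3), (4, 3), (4, 4), (0, 4)]
        )
        band = Polygon2D([(2, -1), (5, -1), (5, 5), (2, 5)])
        pieces = polygon_intersection(c_shape, band)
        assert len(pieces) == 2
        assert sum(polygon_area(p) for p in pieces) == pytest.approx(4.0)

    def test_deterministic_order(self, rng):
        a = random_simple_polygon(rng)
        b = random_simple_polygon(rng)
        p1 = polygon_intersection(a, b)
        p2 = polygon_intersection(a, b)
        assert [tuple(map(tuple, p.coords)) for p in p1] == [
            tuple(map(tuple, p.coords)) for p in p2
        ]


class TestIntersectionArea:
    def test_self_identity(self, rng):
        p = random_simple_polygon(rng)
        assert intersection_area(p, p) == pytest.approx(polygon_area(p), rel=1e-9)

    def test_disjoint_zero(self, unit_square):
        assert intersection_area(unit_square, unit_square.translated(3, 0)) == 0.0

    def test_half_overlap(self, unit_square):
        assert intersection_area(unit_square, unit_square.translated(0.5, 0)) == pytest.approx(0.5)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = random_simple_polygon(rng)
        b = random_simple_polygon(rng)
        ab = intersection_area(a, b)
        ba = intersection_area(b, a)
        assert ab == pytest.approx(ba, abs=1e-9 * max(polygon_area(a), polygon_area(b)))
        assert ab <= min(polygon_area(a), polygon_area(b)) + 1e-9 * max(
            polygon_area(a), polygon_area(b)
        )

    def test_scaling_quadratic(self, rng):
        a = random_simple_polygon(rng)
        b = a.translated(5.0, -3.0)
        base = intersection_area(a, b)
        s = 3.7
        assert intersection_area(a.scaled(s), b.scaled(s)) == pytest.approx(
            s * s * base, rel=1e-9
        )

    def test_discretized_circles_match_closed_form(self, rng):
        for _ in range(20):
            r1, r2 = rng.uniform(0.5, 2.0, size=2)
            d = rng.uniform(0.05, (r1 + r2) * 0.95)
            c1 = CircleSpec(Point2D(0, 0), r1)
            c2 = CircleSpec(Point2D(d, 0), r2)
            exact = circle_circle_overlap_area(c1, c2)
            approx = intersection_area(circle_polygon(c1, 1024), circle_polygon(c2, 1024))
            assert approx == pytest.approx(exact, rel=0.01)


class TestCirclePolygon:
    def test_min_vertices_enforced(self):
        with pytest.raises(ParameterError):
            circle_polygon(CircleSpec(Point2D(0, 0), 1.0), 7)

    def test_relaxed_precondition_square(self):
        p = circle_polygon(CircleSpec(Point2D(0, 0), 1.0), 4, min_vertices=4)
        assert len(p) == 4
        assert np.allclose(np.hypot(p.coords[:, 0], p.coords[:, 1]), 1.0)

    def test_first_vertex_at_angle_zero(self):
        p = circle_polygon(CircleSpec(Point2D(2.0, 3.0), 5.0), 16)
        assert tuple(p.coords[0]) == pytest.approx((7.0, 3.0))

    def test_area_increases_to_pi(self):
        areas = [
            polygon_area(circle_polygon(CircleSpec(Point2D(0, 0), 1.0), n))
            for n in (8, 16, 64, 256, 1024)
        ]
        assert all(a1 < a2 for a1, a2 in zip(areas, areas[1:]))
        assert all(a < math.pi for a in areas)
        assert areas[-1] == pytest.approx(math.pi, rel=1e-4)

    def test_translation_equivariance(self):
        a = circle_polygon(CircleSpec(Point2D(0, 0), 2.0), 32)
        b = circle_polygon(CircleSpec(Point2D(7.5, -2.25), 2.0), 32)
        assert np.allclose(b.coords - a.coords, [7.5, -2.25])

    def test_radius_must_be_positive(self):
        with pytest.raises(ParameterError):
            CircleSpec(Point2D(0, 0), 0.0)


class TestCircleCircleOverlap:
    def test_identical_circles(self):
        c = CircleSpec(Point2D(3, 4), 2.5)
        assert circle_circle_overlap_area(c, c) == pytest.approx(math.pi * 2.5**2)

    def test_contained_circle(self):
        big = CircleSpec(Point2D(0, 0), 5.0)
        small = CircleSpec(Point2D(1, 0), 1.0)
        assert circle_circle_overlap_area(big, small) == pytest.approx(math.pi)

    def test_disjoint(self):
        a = CircleSpec(Point2D(0, 0), 1.0)
        b = CircleSpec(Point2D(2.0, 0), 1.0)
        assert circle_circle_overlap_area(a, b) == 0.0

    def test_unit_lens(self):
        a = CircleSpec(Point2D(0, 0), 1.0)
        b = CircleSpec(Point2D(1, 0), 1.0)
        assert circle_circle_overlap_area(a, b) == pytest.approx(LENS_R1_D1, abs=1e-12)


def _square_region(x0, y0, x1, y1):
    return lambda X, Y: (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)


def _disc_region(cx, cy, r):
    return lambda X, Y: (X - cx) ** 2 + (Y - cy) ** 2 <= r * r


class TestGridOverlapOracle:
    def test_identical_unit_squares(self):
        sq = _square_region(0, 0, 1, 1)
        res = grid_overlap_oracle(sq, sq, (-0.5, -0.5, 1.5, 1.5), 1000)
        assert res.area == pytest.approx(1.0, abs=0.01)

    def test_disjoint_regions(self):
        a = _square_region(0, 0, 1, 1)
        b = _square_region(2, 2, 3, 3)
        assert grid_overlap_oracle(a, b, (-1, -1, 4, 4), 500).area == 0.0

    def test_lens_matches_closed_form(self):
        a = _disc_region(0, 0, 1.0)
        b = _disc_region(1.0, 0, 1.0)
        res = grid_overlap_oracle(a, b, (-1.2, -1.2, 2.2, 1.2), 2000)
        assert res.area == pytest.approx(LENS_R1_D1, rel=0.005)

    def test_error_shrinks_with_resolution(self):
        a = _disc_region(0, 0, 1.0)
        b = _disc_region(1.0, 0, 1.0)
        bbox = (-1.2, -1.2, 2.2, 1.2)
        err500 = abs(grid_overlap_oracle(a, b, bbox, 500).area - LENS_R1_D1)
        err2000 = abs(grid_overlap_oracle(a, b, bbox, 2000).area - LENS_R1_D1)
        assert err2000 < err500 / 2.0

    def test_error_bound_covers_truth(self):
        a = _disc_region(0, 0, 1.0)
        b = _disc_region(1.0, 0, 1.0)
        res = grid_overlap_oracle(a, b, (-1.2, -1.2, 2.2, 1.2), 800)
        assert abs(res.area - LENS_R1_D1) <= res.error_bound

    def test_degenerate_bbox(self):
        sq = _square_region(0, 0, 1, 1)
        with pytest.raises(ParameterError):
            grid_overlap_oracle(sq, sq, (0, 0, 0, 1), 500)

    def test_resolution_floor(self):
        sq = _square_region(0, 0, 1, 1)
        with pytest.raises(ParameterError):
            grid_overlap_oracle(sq, sq, (0, 0, 1, 1), 50)
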