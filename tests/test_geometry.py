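import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_line
from implantpath.geometry import (
    DegenerateGeometryError,
    OrientedBox,
    Point,
    angle_between,
    angle_bisectors,
    box_from_corners,
    canonicalize,
    lateral_edge_lines,
    line_direction_deg,
    line_from_points,
    line_through,
    long_axis,
    obb_corners,
    point_line_distance,
    rotate_line,
)


class TestLineConstruction:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            ((0, 0), (0, 1), (1.0, 0.0, 0.0)),  # vertical axis
            ((0, 0), (1, 1), (math.sqrt(0.5), -math.sqrt(0.5), 0.0)),  # diagonal
        ],
    )
    def test_canonical_two_point_lines(self, p1, p2, expected):
        line = line_from_points(Point(*p1), Point(*p2))
        assert (line.A, line.B, line.C) == pytest.approx(expected, abs=1e-12)

    def test_both_points_satisfy_implicit_form(self):
        p1, p2 = Point(1, 2), Point(3, 6)
        line = line_from_points(p1, p2)
        assert abs(line.eval(p1)) < 1e-9
        assert abs(line.eval(p2)) < 1e-9

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            line_from_points(Point(2, 3), Point(2, 3))

    @pytest.mark.parametrize(
        "abc, expected",
        [
            ((2, 0, 4), (1.0, 0.0, 2.0)),
            ((0, -3, 6), (0.0, 1.0, -2.0)),
            ((3, 4, 10), (0.6, 0.8, 2.0)),
        ],
    )
    def test_canonicalize(self, abc, expected):
        line = canonicalize(*abc)
        assert (line.A, line.B, line.C) == pytest.approx(expected, abs=1e-12)

    def test_canonicalize_rejects_null_normal(self):
        with pytest.raises(DegenerateGeometryError):
            canonicalize(0.0, 0.0, 5.0)

    @given(
        a=st.floats(-100, 100), b=st.floats(-100, 100), c=st.floats(-100, 100)
    )
    @settings(derandomize=True, max_examples=200)
    def test_canonicalize_idempotent(self, a, b, c):
        if math.hypot(a, b) < 1e-3:
            return
        once = canonicalize(a, b, c)
        twice = canonicalize(once.A, once.B, once.C)
        assert (once.A, once.B, once.C) == pytest.approx(
            (twice.A, twice.B, twice.C), abs=1e-12
        )


class TestOrientedBox:
    def test_corners_axis_aligned(self):
        pts = obb_corners(OrientedBox(0, 0, 2, 4, 0))
        assert sorted((round(p.x), round(p.y)) for p in pts) == [
            (-1, -2), (-1, 2), (1, -2), (1, 2)
        ]

    def test_corners_quarter_turn_swaps_extents(self):
        pts = obb_corners(OrientedBox(0, 0, 2, 4, 90))
        assert sorted((round(p.x, 6), round(p.y, 6)) for p in pts) == [
            (-2, -1), (-2, 1), (2, -1), (2, 1)
        ]

    def test_corners_square_45(self):
        pts = obb_corners(OrientedBox(0, 0, 2, 2, 45))
        got = sorted((round(p.x, 9), round(p.y, 9)) for p in pts)
        s = round(math.sqrt(2), 9)
        assert got == [(-s, 0.0), (0.0, -s), (0.0, s), (s, 0.0)]

    def test_corner_centroid_and_side_lengths(self, rng):
        for _ in range(50):
            b = OrientedBox(
                float(rng.uniform(-50, 50)), float(rng.uniform(-50, 50)),
                float(rng.uniform(0.5, 30)), float(rng.uniform(0.5, 30)),
                float(rng.uniform(0, 180)),
            )
            pts = obb_corners(b)
            cx = sum(p.x for p in pts) / 4
            cy = sum(p.y for p in pts) / 4
            assert (cx, cy) == pytest.approx((b.cx, b.cy), abs=1e-9)
            dists = [
                math.dist(pts[i], pts[(i + 1) % 4]) for i in range(4)
            ]
            assert dists == pytest.approx([b.w, b.h, b.w, b.h], abs=1e-9)

    def test_box_roundtrip_through_corners(self, rng):
        for _ in range(100):
            b = OrientedBox(
                float(rng.uniform(-50, 50)), float(rng.uniform(-50, 50)),
                float(rng.uniform(0.5, 30)), float(rng.uniform(0.5, 30)),
                float(rng.uniform(0, 180)),
            )
            r = box_from_corners(obb_corners(b))
            assert (r.cx, r.cy, r.w, r.h) == pytest.approx(
                (b.cx, b.cy, b.w, b.h), abs=1e-6
            )
            assert min(abs(r.theta - b.theta), 180 - abs(r.theta - b.theta)) < 1e-6

    def test_box_from_corners_rejects_non_rectangle(self):
        with pytest.raises(DegenerateGeometryError):
            box_from_corners([(0, 0), (2, 0), (2.3, 1), (0, 1)])

    def test_theta_reduced_mod_180(self):
        assert OrientedBox(0, 0, 1, 1, 270).theta == 90.0


class TestLongAxisAndEdges:
    def test_tall_box_axis_vertical(self):
        line = long_axis(OrientedBox(0, 0, 10, 40, 0))
        assert (line.A, line.B) == pytest.approx((1.0, 0.0), abs=1e-12)
        assert abs(line.C) < 1e-12

    def test_rotated_quarter_turn_axis_horizontal(self):
        line = long_axis(OrientedBox(5, 5, 10, 40, 90))
        assert (line.A, line.B, line.C) == pytest.approx((0.0, 1.0, -5.0), abs=1e-9)

    def test_tilted_axis_matches_rotated_direction(self):
        line = long_axis(OrientedBox(0, 0, 10, 40, 30))
        # theta=0 axis is vertical (90 deg); rotating the box by 30 adds 30
        assert line_direction_deg(line) == pytest.approx(120.0, abs=1e-9)

    def test_square_box_warns(self):
        with pytest.warns(UserWarning, match="square"):
            long_axis(OrientedBox(0, 0, 5, 5, 0))

    def test_edge_lines_axis_aligned(self):
        lo, hi = lateral_edge_lines(OrientedBox(0, 0, 10, 40, 0))
        assert (lo.A, lo.B, lo.C) == pytest.approx((1, 0, -5), abs=1e-9)
        assert (hi.A, hi.B, hi.C) == pytest.approx((1, 0, 5), abs=1e-9)

    def test_long_axis_is_edge_midline(self):
        b = OrientedBox(0, 0, 10, 40, 0)
        lo, hi = lateral_edge_lines(b)
        mid, flag = angle_bisectors(lo, hi)
        assert flag is None  # parallel pair -> midline
        axis = long_axis(b)
        assert (mid.A, mid.B, mid.C) == pytest.approx(
            (axis.A, axis.B, axis.C), abs=1e-9
        )

    def test_edge_lines_offset_from_axis(self):
        b = OrientedBox(0, 0, 10, 40, 30)
        axis = long_axis(b)
        for edge in lateral_edge_lines(b):
            assert angle_between(edge, axis) < 1e-9
            # any point on the edge is 5 px from the axis
            p = Point(-edge.C * edge.A, -edge.C * edge.B)
            assert point_line_distance(p, axis) == pytest.approx(5.0, abs=1e-9)


class TestBisectors:
    def test_coordinate_axes(self):
        b1, b2 = angle_bisectors(canonicalize(1, 0, 0), canonicalize(0, 1, 0))
        dirs = sorted([line_direction_deg(b1), line_direction_deg(b2)])
        assert dirs == pytest.approx([45.0, 135.0], abs=1e-9)

    def test_symmetric_wedge_gives_axis_pair(self):
        l1 = line_through(Point(0, 0), 60.0)  # +30 from vertical
        l2 = line_through(Point(0, 0), 120.0)  # -30 from vertical
        b1, b2 = angle_bisectors(l1, l2)
        dirs = sorted([line_direction_deg(b1), line_direction_deg(b2)])
        assert dirs == pytest.approx([0.0, 90.0], abs=1e-9)

    def test_slanted_pair_equal_angles(self):
        l1 = canonicalize(3, 4, 0)
        l2 = canonicalize(1, 0, 0)
        for bis in angle_bisectors(l1, l2):
            assert angle_between(bis, l1) == pytest.approx(
                angle_between(bis, l2), abs=1e-9
            )

    def test_identical_lines_rejected(self):
        l = canonicalize(1, 2, 3)
        with pytest.raises(DegenerateGeometryError):
            angle_bisectors(l, l)

    def test_parallel_lines_yield_midline_sentinel(self):
        mid, flag = angle_bisectors(canonicalize(1, 0, -2), canonicalize(1, 0, 6))
        assert flag is None
        assert (mid.A, mid.B, mid.C) == pytest.approx((1, 0, 2), abs=1e-12)

    def test_equal_angle_and_perpendicularity_bulk(self, rng):
        for _ in range(500):
            l1, l2 = random_line(rng), random_line(rng)
            if angle_between(l1, l2) < 1e-6:
                continue
            b1, b2 = angle_bisectors(l1, l2)
            assert abs(angle_between(b1, l1) - angle_between(b1, l2)) < 1e-9
            assert abs(angle_between(b2, l1) - angle_between(b2, l2)) < 1e-9
            assert angle_between(b1, b2) == pytest.approx(90.0, abs=1e-9)

    def test_rotation_equivariance(self, rng):
        for _ in range(100):
            l1, l2 = random_line(rng), random_line(rng)
            if angle_between(l1, l2) < 1e-6:
                continue
            phi = float(rng.uniform(0, 180))
            b1, b2 = angle_bisectors(l1, l2)
            r1, r2 = angle_bisectors(rotate_line(l1, phi), rotate_line(l2, phi))
            got = sorted([line_direction_deg(r1), line_direction_deg(r2)])
            want = sorted(
                [(line_direction_deg(b1) + phi) % 180, (line_direction_deg(b2) + phi) % 180]
            )
            for g, w in zip(got, want):
                assert min(abs(g - w), 180 - abs(g - w)) < 1e-9


class TestAngles:
    @pytest.mark.parametrize(
        "d1, d2, expected",
        [(90, 90, 0.0), (90, 0, 90.0), (10, 13, 3.0), (175, 5, 10.0)],
    )
    def test_angle_between_directions(self, d1, d2, expected):
        l1 = line_through(Point(0, 0), d1)
        l2 = line_through(Point(3, 1), d2)
        assert angle_between(l1, l2) == pytest.approx(expected, abs=1e-9)

    def test_parallel_offset_lines_have_zero_angle(self):
        assert angle_between(canonicalize(1, 0, 0), canonicalize(1, 0, -3)) == 0.0

    @pytest.mark.parametrize(
        "abc, expected",
        [((0, 1, 0), 0.0), ((1, 0, 0), 90.0), ((1, -1, 0), 45.0)],
    )
    def test_line_direction(self, abc, expected):
        assert line_direction_deg(canonicalize(*abc)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_direction_matches_box_theta_convention(self, rng):
        for _ in range(50):
            d = float(rng.uniform(0, 180))
            line = line_through(Point(1, 2), d)
            got = line_direction_deg(line)
            assert min(abs(got - d), 180 - abs(got - d)) < 1e-9
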