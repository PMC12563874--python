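"""2-D line and oriented-box primitives for implant-pathway derivation.

Conventions (used identically across the whole package):

* Image coordinates are 0-based, y-down, with pixel centers at integer
  coordinates.
* Angles are in degrees, measured counter-clockwise from the image x-axis
  in coordinate space, and reduced modulo 180 where only a direction
  (not an orientation) is meaningful.
* Lines are stored in implicit form ``A*x + B*y + C = 0`` and kept in a
  canonical scaling: ``A**2 + B**2 == 1`` with ``A > 0``, or ``A == 0``
  and ``B > 0``.  The canonical form makes the signed point-line distance
  ``A*x + B*y + C`` a true Euclidean distance and makes the two branches
  of the angle-bisector equation

      (A1*x + B1*y + C1) / sqrt(A1^2 + B1^2)
          = +/- (A2*x + B2*y + C2) / sqrt(A2^2 + B2^2)

  deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Point",
    "Line",
    "OrientedBox",
    "HorizontalBox",
    "line_from_points",
    "canonicalize",
    "obb_corners",
    "long_axis",
    "lateral_edge_lines",
    "angle_bisectors",
    "angle_between",
    "line_direction_deg",
    "line_through",
    "intersect_lines",
    "point_line_distance",
    "box_from_corners",
]

_EPS = 1e-12
#: two canonical lines are treated as parallel when the cross product of
#: their unit normals falls below this
_PARALLEL_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised for coincident points, identical lines, zero-size boxes etc."""


class Point(NamedTuple):
    x: float
    y: float


@dataclass(frozen=True)
class Line:
    """Implicit 2-D line ``A*x + B*y + C = 0`` in canonical form."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.A, self.B, self.C)):
            raise DegenerateGeometryError("line coefficients must be finite")
        if self.A * self.A + self.B * self.B < _EPS:
            raise DegenerateGeometryError("A and B may not both be zero")

    def eval(self, p: Point) -> float:
        """Signed value ``A*x + B*y + C`` (a distance when canonical)."""
        return self.A * p[0] + self.B * p[1] + self.C

    def direction(self) -> tuple[float, float]:
        """A unit vector along the line."""
        return (self.B, -self.A)

    def normal(self) -> tuple[float, float]:
        return (self.A, self.B)


def canonicalize(A: float, B: float, C: float) -> Line:
    """Scale ``(A, B, C)`` to unit normal with the package sign convention.

    Raises :class:`DegenerateGeometryError` if ``A == B == 0``.
    """
    norm = math.hypot(A, B)
    if norm < _EPS:
        raise DegenerateGeometryError("invalid line: A = B = 0")
    A, B, C = A / norm, B / norm, C / norm
    # sign convention: A > 0, or A == 0 and B > 0
    if A < -_EPS or (abs(A) <= _EPS and B < 0):
        A, B, C = -A, -B, -C
    if abs(A) <= _EPS:
        A = 0.0
    # +0.0 folds negative zeros so reprs and equality are stable
    return Line(A + 0.0, B + 0.0, C + 0.0)


def line_from_points(p1: Point, p2: Point) -> Line:
    """Line through two distinct points, canonicalized."""
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    if math.hypot(dx, dy) < 1e-9:
        raise DegenerateGeometryError(f"coincident points {p1} and {p2}")
    A, B = dy, -dx
    C = -(A * p1[0] + B * p1[1])
    return canonicalize(A, B, C)


def line_through(p: Point, direction_deg: float) -> Line:
    """Line through ``p`` with the given direction angle in degrees."""
    d = math.radians(direction_deg)
    ux, uy = math.cos(d), math.sin(d)
    A, B = -uy, ux
    C = -(A * p[0] + B * p[1])
    return canonicalize(A, B, C)


def point_line_distance(p: Point, line: Line) -> float:
    return abs(line.eval(p))


def intersect_lines(l1: Line, l2: Line) -> Point:
    """Intersection point of two non-parallel lines."""
    det = l1.A * l2.B - l2.A * l1.B
    if abs(det) < _PARALLEL_TOL:
        raise DegenerateGeometryError("lines are parallel; no unique intersection")
    x = (l1.B * l2.C - l2.B * l1.C) / det
    y = (l2.A * l1.C - l1.A * l2.C) / det
    return Point(x, y)


def line_direction_deg(line: Line) -> float:
    """Direction of the line in degrees, reduced to ``[0, 180)``.

    Consistent with the OrientedBox theta convention (CCW from x-axis).
    """
    dx, dy = line.direction()
    ang = math.degrees(math.atan2(dy, dx)) % 180.0
    if ang >= 180.0 - 1e-12:  # fold 180-epsilon artifacts onto 0
        ang = 0.0
    return ang


def angle_between(l1: Line, l2: Line) -> float:
    """Unsigned angle between two lines in degrees, in ``[0, 90]``.

    Uses atan2 of |cross| and |dot| of the unit normals, which stays
    accurate near 0 and 90 degrees (acos does not).
    """
    cross = l1.A * l2.B - l2.A * l1.B
    dot = l1.A * l2.A + l1.B * l2.B
    return math.degrees(math.atan2(abs(cross), abs(dot)))


def angle_bisectors(l1: Line, l2: Line) -> tuple[Line, Line | None]:
    """The two angle bisectors of ``l1`` and ``l2``.

    For non-parallel inputs returns a pair of mutually perpendicular
    lines, each making equal angles with both inputs; these are the two
    branches ``n1 - n2`` and ``n1 + n2`` of the +/- bisector equation on
    unit normals.

    For parallel (but not identical) inputs the geometric bisector set
    collapses to the single midline; it is returned as ``(midline, None)``
    — the ``None`` sentinel flags the degenerate case.  Identical lines
    raise :class:`DegenerateGeometryError`.
    """
    cross = l1.A * l2.B - l2.A * l1.B
    if abs(cross) < _PARALLEL_TOL:
        # canonical parallel lines share (A, B) exactly up to sign flips at A≈0
        dot = l1.A * l2.A + l1.B * l2.B
        c2 = l2.C if dot >= 0 else -l2.C
        if abs(l1.C - c2) < 1e-9:
            raise DegenerateGeometryError("identical lines have no bisector")
        return canonicalize(l1.A, l1.B, (l1.C + c2) / 2.0), None
    plus = canonicalize(l1.A + l2.A, l1.B + l2.B, l1.C + l2.C)
    minus = canonicalize(l1.A - l2.A, l1.B - l2.B, l1.C - l2.C)
    return plus, minus


# ---------------------------------------------------------------------------
# boxes


@dataclass(frozen=True)
class HorizontalBox:
    """Axis-aligned box: center ``(cx, cy)``, full side lengths ``w, h``."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise DegenerateGeometryError("box sides must be positive")


@dataclass(frozen=True)
class OrientedBox:
    """Rotated box: center, full side lengths and rotation ``theta``.

    ``theta`` is in degrees, counter-clockwise from the image x-axis, and
    is reduced modulo 180 on construction.  At ``theta == 0`` the ``w``
    side runs along x and the ``h`` side along y.
    """

    cx: float
    cy: float
    w: float
    h: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise DegenerateGeometryError("box sides must be positive")
        object.__setattr__(self, "theta", float(self.theta) % 180.0)

    @property
    def long_side(self) -> float:
        return max(self.w, self.h)

    @property
    def short_side(self) -> float:
        return min(self.w, self.h)

    def as_horizontal(self) -> HorizontalBox:
        """Axis-aligned bounding box of the rotated rectangle."""
        xs, ys = zip(*obb_corners(self))
        return HorizontalBox(self.cx, self.cy, max(xs) - min(xs), max(ys) - min(ys))


def obb_corners(b: OrientedBox) -> list[Point]:
    """Corners in a fixed order: local ``(-w/2, -h/2)`` first, then CCW in
    local coordinates (``(+w/2, -h/2)``, ``(+w/2, +h/2)``, ``(-w/2, +h/2)``),
    each rotated by ``theta`` about the center."""
    t = math.radians(b.theta)
    c, s = math.cos(t), math.sin(t)
    hw, hh = b.w / 2.0, b.h / 2.0
    out = []
    for lx, ly in ((-hw, -hh), (hw, -hh), (hw, hh), (-hw, hh)):
        out.append(Point(b.cx + c * lx - s * ly, b.cy + s * lx + c * ly))
    return out


def box_from_corners(corners) -> OrientedBox:
    """Reconstruct an OrientedBox from four corners in `obb_corners` order.

    The first edge (corner 0 -> 1) is taken as the ``w`` side.  Raises if
    the quadrilateral is not a rectangle within a relative tolerance of
    1e-3 (non-perpendicular adjacent edges or unequal opposite sides).
    """
    pts = [Point(float(x), float(y)) for x, y in corners]
    if len(pts) != 4:
        raise DegenerateGeometryError("need exactly four corners")
    e1 = (pts[1].x - pts[0].x, pts[1].y - pts[0].y)
    e2 = (pts[2].x - pts[1].x, pts[2].y - pts[1].y)
    e3 = (pts[3].x - pts[2].x, pts[3].y - pts[2].y)
    w = math.hypot(*e1)
    h = math.hypot(*e2)
    if w < _EPS or h < _EPS:
        raise DegenerateGeometryError("degenerate rectangle (zero-length edge)")
    scale = max(w, h)
    perp = abs(e1[0] * e2[0] + e1[1] * e2[1]) / (w * h)
    opposite = math.hypot(e1[0] + e3[0], e1[1] + e3[1]) / scale
    if perp > 1e-3 or opposite > 1e-3:
        raise DegenerateGeometryError("corners do not form a rectangle")
    cx = sum(p.x for p in pts) / 4.0
    cy = sum(p.y for p in pts) / 4.0
    theta = math.degrees(math.atan2(e1[1], e1[0])) % 180.0
    return OrientedBox(cx, cy, w, h, theta)


def long_axis(b: OrientedBox) -> Line:
    """Line through the box center along the longer side.

    If ``h >= w`` the axis runs along the ``h`` side (direction
    ``theta + 90``), else along the ``w`` side (direction ``theta``).
    A square box is an ill-defined "long axis of a tooth"; the ``h`` axis
    is used and a warning is emitted.
    """
    if b.w == b.h:
        warnings.warn(
            "square box: long axis is ill-defined, using the h-side axis",
            stacklevel=2,
        )
    direction = (b.theta + 90.0) % 180.0 if b.h >= b.w else b.theta
    return line_through(Point(b.cx, b.cy), direction)


def lateral_edge_lines(b: OrientedBox) -> tuple[Line, Line]:
    """The two box edge lines parallel to the long axis.

    Both are offset ``short_side / 2`` from :func:`long_axis`, which is
    their midline.  Returned in deterministic order (ascending C).
    """
    axis = long_axis(b)
    off = b.short_side / 2.0
    lo = canonicalize(axis.A, axis.B, axis.C - off)
    hi = canonicalize(axis.A, axis.B, axis.C + off)
    return (lo, hi) if lo.C <= hi.C else (hi, lo)


def rotate_line(line: Line, phi_deg: float, about: Point = Point(0.0, 0.0)) -> Line:
    """Rotate a line by ``phi_deg`` (CCW) about a point. Test/analysis helper."""
    t = math.radians(phi_deg)
    c, s = math.cos(t), math.sin(t)
    # rotate the normal; rotate C so distances from `about` are preserved
    A = c * line.A - s * line.B
    B = s * line.A + c * line.B
    d = line.eval(about)
    C = d - (A * about.x + B * about.y)
    return canonicalize(A, B, C)


def boxes_as_array(boxes) -> np.ndarray:
    """(n, 5) float array of (cx, cy, w, h, theta); convenience for vector ops."""
    return np.array([[b.cx, b.cy, b.w, b.h, b.theta] for b in boxes], dtype=float)
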