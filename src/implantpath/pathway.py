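"""Implant-pathway orientation from the two teeth flanking a single gap.

The clinical recipe: the two teeth adjacent to a single-tooth edentulous
gap are detected as oriented boxes; auxiliary lines are extended along the
box edges facing the gap; the *internal* angle bisector of those auxiliary
lines — the line making equal angles with both, whose direction lies
inside the wedge spanned by the two tooth long axes — is the recommended
implant insertion direction.  It splits the mesiodistal corridor evenly,
keeping the implant clear of both roots.

By default the auxiliary lines fed to the bisector are the *gap-facing
lateral edge lines* of the boxes (they bound the corridor the implant
must clear); ``use_edges=False`` switches to the central long axes.
Either way each auxiliary line is parallel to its tooth's long axis, so
the derived direction is identical — the choice moves only the pathway's
*position* across the gap.

When the two teeth are perfectly parallel the bisector degenerates; the
midline between the auxiliary lines is used, flagged on the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .geometry import (
    DegenerateGeometryError,
    Line,
    OrientedBox,
    Point,
    angle_between,
    angle_bisectors,
    intersect_lines,
    lateral_edge_lines,
    line_direction_deg,
    line_from_points,
    long_axis,
    obb_corners,
)

__all__ = ["ToothPair", "Pathway", "derive_pathway", "select_internal_bisector",
           "pathway_segment", "internal_bisector_direction"]


class InvalidToothPairError(ValueError):
    """Overlapping or otherwise unusable adjacent-teeth configuration."""


def _boxes_overlap(a: OrientedBox, b: OrientedBox) -> bool:
    from shapely.geometry import Polygon

    pa = Polygon(obb_corners(a))
    pb = Polygon(obb_corners(b))
    return pa.intersection(pb).area > 1e-9 * min(pa.area, pb.area)


def _contains_center(a: OrientedBox, b: OrientedBox) -> bool:
    from shapely.geometry import Point as ShPoint, Polygon

    return Polygon(obb_corners(a)).contains(ShPoint(b.cx, b.cy))


@dataclass(frozen=True)
class ToothPair:
    """The two teeth flanking the gap, ordered left/right by center x.

    ``gap_center`` is the midpoint, along the segment joining the two box
    centers, between the two gap-facing edge lines; it is computed lazily
    when not supplied.
    """

    left: OrientedBox
    right: OrientedBox
    gap_center: Point | None = None
    crest: str = "up"  # which end of the gap-facing edges is coronal: smaller y ("up") or larger ("down")

    def __post_init__(self) -> None:
        if self.left.cx > self.right.cx:
            l, r = self.right, self.left
            object.__setattr__(self, "left", l)
            object.__setattr__(self, "right", r)
        if self.crest not in ("up", "down"):
            raise ValueError("crest must be 'up' or 'down'")
        if _boxes_overlap(self.left, self.right):
            raise InvalidToothPairError("adjacent tooth boxes overlap")
        if _contains_center(self.left, self.right) or _contains_center(self.right, self.left):
            raise InvalidToothPairError("one box contains the other's center")


def gap_facing_edges(pair: ToothPair) -> tuple[Line, Line]:
    """Of each tooth's two lateral edge lines, the one nearer the other
    tooth's center (the edge bounding the edentulous corridor)."""
    lc = Point(pair.left.cx, pair.left.cy)
    rc = Point(pair.right.cx, pair.right.cy)
    le = min(lateral_edge_lines(pair.left), key=lambda l: abs(l.eval(rc)))
    re = min(lateral_edge_lines(pair.right), key=lambda l: abs(l.eval(lc)))
    return le, re


def _crest_corner(box: OrientedBox, edge: Line, crest: str) -> Point:
    """Corner of `box` on `edge` at the coronal end (min or max y)."""
    corners = sorted(obb_corners(box), key=lambda p: abs(edge.eval(p)))[:2]
    key = min if crest == "up" else max
    return key(corners, key=lambda p: p.y)


def _compute_gap_center(pair: ToothPair, le: Line, re: Line) -> Point:
    centers = line_from_points(
        Point(pair.left.cx, pair.left.cy), Point(pair.right.cx, pair.right.cy)
    )
    try:
        p1 = intersect_lines(centers, le)
        p2 = intersect_lines(centers, re)
    except DegenerateGeometryError:
        # an edge parallel to the center line: fall back to center midpoint
        return Point((pair.left.cx + pair.right.cx) / 2.0,
                     (pair.left.cy + pair.right.cy) / 2.0)
    return Point((p1.x + p2.x) / 2.0, (p1.y + p2.y) / 2.0)


@dataclass(frozen=True)
class Pathway:
    """Derived implant pathway: the line, its direction angle in [0, 180),
    the entry point on the crest segment, and a drawable segment."""

    line: Line
    entry_point: Point
    angle_deg: float
    segment: tuple[Point, Point]
    parallel_fallback: bool = False
    auxiliary_lines: tuple[Line, Line] | None = field(default=None, compare=False)


def internal_bisector_direction(d1_deg: float, d2_deg: float) -> float:
    """Direction (deg, mod 180) at the angular midpoint of the short wedge
    between two line directions.  Uses the doubled-angle embedding so the
    mod-180 wraparound is handled exactly."""
    a1 = math.radians(2.0 * d1_deg)
    a2 = math.radians(2.0 * d2_deg)
    x = math.cos(a1) + math.cos(a2)
    y = math.sin(a1) + math.sin(a2)
    if math.hypot(x, y) < 1e-12:
        # directions 90 deg apart: wedge midpoint ambiguous
        return (min(d1_deg, d2_deg) + 45.0) % 180.0
    return (math.degrees(math.atan2(y, x)) / 2.0) % 180.0


def _angular_dist_mod180(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def select_internal_bisector(b1: Line, b2: Line, axes: tuple[Line, Line]) -> Line:
    """Pick, from the perpendicular bisector pair, the internal one.

    Internal means: direction inside the closed wedge (span < 90 deg)
    between the two axis directions.  A wedge of exactly 90 deg is a tie;
    the member closer to vertical (90 deg) is taken and a warning issued.
    """
    d1 = line_direction_deg(axes[0])
    d2 = line_direction_deg(axes[1])
    span = _angular_dist_mod180(d1, d2)
    mid = internal_bisector_direction(d1, d2)
    cands = [b1, b2]
    dists = [_angular_dist_mod180(line_direction_deg(c), mid) for c in cands]
    if abs(span - 90.0) < 1e-9:
        warnings.warn(
            "axis wedge is exactly 90 deg; tie-broken toward the vertical bisector",
            stacklevel=2,
        )
        verticality = [_angular_dist_mod180(line_direction_deg(c), 90.0) for c in cands]
        return cands[verticality.index(min(verticality))]
    return cands[dists.index(min(dists))]


def pathway_segment(line: Line, entry: Point, extent: float) -> tuple[Point, Point]:
    """Segment of total length ``2 * extent`` centered on ``entry`` along
    ``line`` (for overlay rendering)."""
    ux, uy = line.direction()
    return (
        Point(entry.x - extent * ux, entry.y - extent * uy),
        Point(entry.x + extent * ux, entry.y + extent * uy),
    )


def derive_pathway(
    pair: ToothPair,
    use_edges: bool = True,
    extent: float | None = None,
) -> Pathway:
    """Derive the implant pathway for a single-tooth gap.

    Parameters
    ----------
    pair : ToothPair
        The two adjacent-teeth boxes.
    use_edges : bool
        Feed the gap-facing lateral edge lines to the bisector (default);
        ``False`` uses the central long axes instead.
    extent : float, optional
        Half-length in px of the drawable segment; defaults to the mean
        long side of the two boxes.
    """
    axes = (long_axis(pair.left), long_axis(pair.right))
    le, re = gap_facing_edges(pair)
    aux = (le, re) if use_edges else axes

    first, second = angle_bisectors(aux[0], aux[1])
    if second is None:  # parallel teeth: midline fallback
        path_line = first
        fallback = True
    else:
        path_line = select_internal_bisector(first, second, axes)
        fallback = False

    crest_l = _crest_corner(pair.left, le, pair.crest)
    crest_r = _crest_corner(pair.right, re, pair.crest)
    try:
        crest_line = line_from_points(crest_l, crest_r)
        entry = intersect_lines(path_line, crest_line)
    except DegenerateGeometryError:
        entry = pair.gap_center or _compute_gap_center(pair, le, re)

    if extent is None:
        extent = (pair.left.long_side + pair.right.long_side) / 2.0
    return Pathway(
        line=path_line,
        entry_point=entry,
        angle_deg=line_direction_deg(path_line),
        segment=pathway_segment(path_line, entry, extent),
        parallel_fallback=fallback,
        auxiliary_lines=aux,
    )
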