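"""Readers/writers for label files, pathway JSON, images and overlays.

Interchange formats (the de-facto normalized text dialects):

* OBB labels  — one object per line: ``class x1 y1 x2 y2 x3 y3 x4 y4``,
  the four corner coordinates normalized to [0, 1] by image width/height.
* HBB labels  — one object per line: ``class cx cy w h``, normalized.
* Dentist ground-truth pathways — a JSON sidecar mapping image id to two
  line endpoints (pixels): ``{"img": {"endpoints": [[x1,y1],[x2,y2]]}}``.
* Pathway output — JSON with the implicit line coefficients, direction
  angle, entry point and a drawable segment; floats fixed to 6 decimals
  so repeated runs are byte-identical.

Coordinates everywhere are 0-based, pixel-center, y-down.  An optional
trailing confidence token is accepted on label lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import disk, line as draw_line, polygon_perimeter

from .geometry import (
    HorizontalBox,
    OrientedBox,
    Point,
    box_from_corners,
    obb_corners,
)
from .pathway import Pathway

__all__ = [
    "LabelRecord",
    "AnnotationSet",
    "LabelParseError",
    "read_obb_labels",
    "write_obb_labels",
    "read_hbb_labels",
    "write_hbb_labels",
    "read_image",
    "write_image",
    "pathway_to_dict",
    "write_pathway_json",
    "read_pathway_json",
    "read_truth_lines",
    "write_truth_lines",
    "fit_min_area_rect",
    "fit_teeth_from_image",
    "render_overlay",
]


class LabelParseError(ValueError):
    """Malformed label line; message carries the file and line number."""


@dataclass(frozen=True)
class LabelRecord:
    class_id: int
    box: OrientedBox | HorizontalBox
    confidence: float | None = None


@dataclass
class AnnotationSet:
    image_id: str
    records: list[LabelRecord] = field(default_factory=list)
    truth_endpoints: tuple[Point, Point] | None = None

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValueError("image id must be non-empty")

    def boxes(self) -> list[OrientedBox | HorizontalBox]:
        return [r.box for r in self.records]


def _parse_floats(tokens, path, lineno):
    vals = []
    for t in tokens:
        try:
            v = float(t)
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: non-numeric token {t!r}") from exc
        if not np.isfinite(v):
            raise LabelParseError(f"{path}:{lineno}: non-finite coordinate {t!r}")
        vals.append(v)
    return vals


def _check_norm(vals, path, lineno):
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise LabelParseError(
                f"{path}:{lineno}: normalized coordinate {v} outside [0, 1]"
            )


def read_obb_labels(
    path: str | Path, image_size: tuple[int, int], image_id: str | None = None
) -> AnnotationSet:
    """Read a normalized OBB label file.

    ``image_size`` is ``(width, height)`` in pixels, used to de-normalize.
    Corners are converted to an :class:`OrientedBox` via the ordered-corner
    rectangle fit (rectangularity enforced to 1e-3 relative).
    """
    path = Path(path)
    w_img, h_img = image_size
    ann = AnnotationSet(image_id or path.stem)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        toks = raw.split()
        if not toks:
            continue
        if len(toks) not in (9, 10):
            raise LabelParseError(
                f"{path}:{lineno}: expected 9 or 10 tokens, got {len(toks)}"
            )
        cls = _parse_int(toks[0], path, lineno)
        vals = _parse_floats(toks[1:9], path, lineno)
        _check_norm(vals, path, lineno)
        conf = None
        if len(toks) == 10:
            (conf,) = _parse_floats(toks[9:], path, lineno)
        corners = [
            (vals[2 * i] * w_img, vals[2 * i + 1] * h_img) for i in range(4)
        ]
        try:
            box = box_from_corners(corners)
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: {exc}") from exc
        ann.records.append(LabelRecord(cls, box, conf))
    return ann


def _parse_int(tok, path, lineno) -> int:
    try:
        return int(tok)
    except ValueError as exc:
        raise LabelParseError(f"{path}:{lineno}: bad class id {tok!r}") from exc


def write_obb_labels(
    ann: AnnotationSet, path: str | Path, image_size: tuple[int, int]
) -> None:
    """Write normalized OBB labels (6-decimal fixed point; lossless round
    trip to 1e-6 of normalized units)."""
    w_img, h_img = image_size
    lines = []
    for rec in ann.records:
        box = rec.box
        if isinstance(box, HorizontalBox):
            box = OrientedBox(box.cx, box.cy, box.w, box.h, 0.0)
        coords = []
        for p in obb_corners(box):
            coords += [p.x / w_img, p.y / h_img]
        toks = [str(rec.class_id)] + [f"{c:.6f}" for c in coords]
        if rec.confidence is not None:
            toks.append(f"{rec.confidence:.6f}")
        lines.append(" ".join(toks))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_hbb_labels(
    path: str | Path, image_size: tuple[int, int], image_id: str | None = None
) -> AnnotationSet:
    """Read a normalized ``class cx cy w h`` label file."""
    path = Path(path)
    w_img, h_img = image_size
    ann = AnnotationSet(image_id or path.stem)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        toks = raw.split()
        if not toks:
            continue
        if len(toks) not in (5, 6):
            raise LabelParseError(
                f"{path}:{lineno}: expected 5 or 6 tokens, got {len(toks)}"
            )
        cls = _parse_int(toks[0], path, lineno)
        vals = _parse_floats(toks[1:5], path, lineno)
        _check_norm(vals, path, lineno)
        conf = None
        if len(toks) == 6:
            (conf,) = _parse_floats(toks[5:], path, lineno)
        cx, cy, w, h = vals
        ann.records.append(
            LabelRecord(cls, HorizontalBox(cx * w_img, cy * h_img, w * w_img, h * h_img), conf)
        )
    return ann


def write_hbb_labels(
    ann: AnnotationSet, path: str | Path, image_size: tuple[int, int]
) -> None:
    w_img, h_img = image_size
    lines = []
    for rec in ann.records:
        b = rec.box
        if isinstance(b, OrientedBox):
            b = b.as_horizontal()
        toks = [
            str(rec.class_id),
            f"{b.cx / w_img:.6f}",
            f"{b.cy / h_img:.6f}",
            f"{b.w / w_img:.6f}",
            f"{b.h / h_img:.6f}",
        ]
        if rec.confidence is not None:
            toks.append(f"{rec.confidence:.6f}")
        lines.append(" ".join(toks))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def write_image(img: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, np.asarray(img))


# ---------------------------------------------------------------------------
# pathway / truth JSON


def _r6(x: float) -> float:
    return round(float(x), 6)


def pathway_to_dict(pw: Pathway, image_id: str) -> dict:
    return {
        "image": image_id,
        "line": {"A": _r6(pw.line.A), "B": _r6(pw.line.B), "C": _r6(pw.line.C)},
        "angle_deg": _r6(pw.angle_deg),
        "entry": [_r6(pw.entry_point.x), _r6(pw.entry_point.y)],
        "segment": [
            [_r6(pw.segment[0].x), _r6(pw.segment[0].y)],
            [_r6(pw.segment[1].x), _r6(pw.segment[1].y)],
        ],
        "parallel_fallback": pw.parallel_fallback,
    }


def write_pathway_json(pw: Pathway, image_id: str, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pathway_to_dict(pw, image_id), indent=2) + "\n")


def read_pathway_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_truth_lines(path: str | Path) -> dict[str, tuple[Point, Point]]:
    """Dentist ground-truth pathway endpoints, keyed by image id."""
    data = json.loads(Path(path).read_text())
    out = {}
    for image_id, entry in data.items():
        (x1, y1), (x2, y2) = entry["endpoints"]
        out[image_id] = (Point(float(x1), float(y1)), Point(float(x2), float(y2)))
    return out


def write_truth_lines(
    truths: dict[str, tuple[Point, Point]], path: str | Path, extra: dict | None = None
) -> None:
    data = {
        image_id: {"endpoints": [[_r6(a.x), _r6(a.y)], [_r6(b.x), _r6(b.y)]],
                   **(extra.get(image_id, {}) if extra else {})}
        for image_id, (a, b) in truths.items()
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# geometry fitting and overlay rendering


def fit_min_area_rect(points: np.ndarray) -> OrientedBox:
    """Minimum-area oriented rectangle of a 2-D point cloud.

    Returns the canonical tall representation (``h >= w``), so the long
    axis is the ``h`` side.  Used to re-fit tooth boxes from thresholded
    image masks.
    """
    from shapely import MultiPoint

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need an (n, 2) array with n >= 3")
    mrr = MultiPoint(pts).minimum_rotated_rectangle
    coords = list(mrr.exterior.coords)[:4]
    box = box_from_corners(coords)
    if box.w > box.h:  # normalize: long side as h
        box = OrientedBox(box.cx, box.cy, box.h, box.w, (box.theta + 90.0) % 180.0)
    return box


def fit_teeth_from_image(
    img: np.ndarray, threshold: float | None = None
) -> tuple[OrientedBox, OrientedBox]:
    """Re-estimate the two tooth boxes from a rendered scene.

    A deliberately simple detector stand-in: threshold (midway between
    the image min and max unless given), take the two largest connected
    bright components, and fit each with a minimum-area rectangle.
    Returns the boxes ordered left-to-right by center x.
    """
    from scipy import ndimage

    arr = np.asarray(img, dtype=float)
    if threshold is None:
        threshold = (arr.min() + arr.max()) / 2.0
    mask = arr > threshold
    labels, n = ndimage.label(mask)
    if n < 2:
        raise ValueError("could not find two tooth components above threshold")
    sizes = ndimage.sum(mask, labels, range(1, n + 1))
    keep = np.argsort(sizes)[-2:] + 1
    boxes = []
    for k in keep:
        ys, xs = np.nonzero(labels == k)
        boxes.append(fit_min_area_rect(np.column_stack([xs, ys])))
    boxes.sort(key=lambda b: b.cx)
    return boxes[0], boxes[1]


COLOR_PATHWAY = (0, 200, 0)
COLOR_AUX = ((255, 220, 0), (60, 120, 255))  # yellow, blue
COLOR_BOX = (255, 80, 80)
COLOR_DOT = (255, 0, 255)


def _draw_segment(rgb: np.ndarray, p0: Point, p1: Point, color, thickness: int = 1) -> None:
    h, w = rgb.shape[:2]
    r0, c0 = int(round(p0.y)), int(round(p0.x))
    r1, c1 = int(round(p1.y)), int(round(p1.x))
    # clip endpoints crudely to a padded frame, then mask
    rr, cc = draw_line(r0, c0, r1, c1)
    for dr in range(-(thickness // 2), thickness // 2 + 1):
        for dc in range(-(thickness // 2), thickness // 2 + 1):
            r, c = rr + dr, cc + dc
            ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
            rgb[r[ok], c[ok]] = color


def render_overlay(
    img: np.ndarray,
    ann: AnnotationSet | None = None,
    pw: Pathway | None = None,
    stroke: int = 3,
) -> np.ndarray:
    """RGB overlay: detected boxes in red, auxiliary lines in yellow/blue,
    the pathway segment in green, entry point as a dot.  The input image
    is not modified."""
    gray = np.asarray(img)
    rgb = np.stack([gray, gray, gray], axis=-1).astype(np.uint8)
    h, w = gray.shape

    if ann is not None:
        for rec in ann.records:
            box = rec.box
            if isinstance(box, HorizontalBox):
                box = OrientedBox(box.cx, box.cy, box.w, box.h, 0.0)
            pts = obb_corners(box)
            rr, cc = polygon_perimeter(
                [p.y for p in pts], [p.x for p in pts], shape=(h, w), clip=True
            )
            rgb[rr, cc] = COLOR_BOX

    if pw is not None:
        if pw.auxiliary_lines is not None:
            half = max(h, w)
            for aux_line, color in zip(pw.auxiliary_lines, COLOR_AUX):
                ux, uy = aux_line.direction()
                # a point on the line: foot of perpendicular from image center
                d = aux_line.eval(Point(w / 2.0, h / 2.0))
                fx, fy = w / 2.0 - d * aux_line.A, h / 2.0 - d * aux_line.B
                _draw_segment(
                    rgb,
                    Point(fx - half * ux, fy - half * uy),
                    Point(fx + half * ux, fy + half * uy),
                    color,
                    1,
                )
        _draw_segment(rgb, pw.segment[0], pw.segment[1], COLOR_PATHWAY, stroke)
        er, ec = int(round(pw.entry_point.y)), int(round(pw.entry_point.x))
        if 0 <= er < h and 0 <= ec < w:
            rr, cc = disk((er, ec), max(2, stroke), shape=(h, w))
            rgb[rr, cc] = COLOR_DOT
    return rgb
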