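"""Detection metrics and pathway angular-deviation reporting.

Covers the usual object-detection scoreboard (confusion counts at an IoU
threshold, precision / recall / accuracy, AP and mAP at IoU 0.5) for
oriented or horizontal boxes, plus the clinical end-point: the unsigned
angle, in degrees, between each predicted implant pathway and the
dentist-annotated reference line, and its mean over a validation set.

Notes on detection accounting: true negatives are undefined for
open-image object detection (there is no enumerable set of correctly
rejected boxes), so ``TN = 0`` throughout and "accuracy"
``(TP+TN)/(TP+TN+FP+FN)`` degenerates to ``TP/(TP+FP+FN)``.  Metrics
with a zero denominator return ``None`` (an undefined-metric sentinel)
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

from shapely.geometry import Polygon

from .geometry import HorizontalBox, Line, OrientedBox, angle_between, obb_corners
from .pathway import Pathway

__all__ = [
    "ConfusionCounts",
    "Detection",
    "EvalReport",
    "rotated_iou",
    "match_detections",
    "precision_recall_accuracy",
    "average_precision_50",
    "mean_average_precision_50",
    "angular_deviation_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Detection:
    box: OrientedBox | HorizontalBox
    class_id: int = 0
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


def _as_polygon(box: OrientedBox | HorizontalBox) -> Polygon:
    if isinstance(box, HorizontalBox):
        box = OrientedBox(box.cx, box.cy, box.w, box.h, 0.0)
    return Polygon(obb_corners(box))


def rotated_iou(a: OrientedBox | HorizontalBox, b: OrientedBox | HorizontalBox) -> float:
    """Intersection-over-union of two (possibly rotated) boxes.

    Symmetric; 1 for identical point sets, 0 for disjoint interiors.
    Exact convex-polygon intersection, so it reduces to the familiar
    axis-aligned IoU when both rotations are zero.
    """
    pa, pb = _as_polygon(a), _as_polygon(b)
    inter = pa.intersection(pb).area
    if inter <= 0.0:
        return 0.0
    union = pa.area + pb.area - inter
    return inter / union


def match_detections(
    dets: list[Detection],
    gts: list[OrientedBox | HorizontalBox],
    iou_thr: float = 0.5,
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Greedy one-to-one matching in descending confidence.

    A detection is a TP if its best-IoU *unmatched* ground truth reaches
    ``iou_thr``; IoU ties break by ground-truth index.  Unmatched
    detections are FPs, unmatched ground truths FNs; TN is fixed at 0.
    Returns the counts and the matched ``(det_index, gt_index)`` pairs.
    """
    if not 0.0 < iou_thr < 1.0:
        raise ValueError("iou_thr must be in (0, 1)")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    taken = [False] * len(gts)
    pairs: list[tuple[int, int]] = []
    for di in order:
        best_iou, best_gi = 0.0, -1
        for gi, gt in enumerate(gts):
            if taken[gi]:
                continue
            iou = rotated_iou(dets[di].box, gt)
            if iou > best_iou:  # strict: ties keep the earlier gt index
                best_iou, best_gi = iou, gi
        if best_gi >= 0 and best_iou >= iou_thr:
            taken[best_gi] = True
            pairs.append((di, best_gi))
    tp = len(pairs)
    return ConfusionCounts(tp=tp, tn=0, fp=len(dets) - tp, fn=len(gts) - tp), pairs


def precision_recall_accuracy(
    c: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """Exact rational precision, recall and accuracy from the counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    accuracy = (TP+TN)/(TP+TN+FP+FN).  ``None`` where the denominator
    is zero.
    """

    def frac(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return (
        frac(c.tp, c.tp + c.fp),
        frac(c.tp, c.tp + c.fn),
        frac(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn),
    )


def average_precision_50(
    dets: list[Detection],
    gts: list[OrientedBox | HorizontalBox],
    iou_thr: float = 0.5,
    interpolation: str = "continuous",
) -> float | None:
    """Average precision at the given IoU threshold for one class.

    ``interpolation='continuous'`` integrates the precision envelope over
    all recall change-points (the all-points AP used by modern detection
    benchmarks); ``'11point'`` averages the interpolated precision at
    recalls 0, 0.1, ..., 1.0.  Returns ``None`` when there is no ground
    truth (undefined), 0.0 when there are no detections.
    """
    if not gts:
        return None
    if not dets:
        return 0.0
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    taken = [False] * len(gts)
    tp_flags: list[bool] = []
    for di in order:
        best_iou, best_gi = 0.0, -1
        for gi, gt in enumerate(gts):
            if taken[gi]:
                continue
            iou = rotated_iou(dets[di].box, gt)
            if iou > best_iou:
                best_iou, best_gi = iou, gi
        if best_gi >= 0 and best_iou >= iou_thr:
            taken[best_gi] = True
            tp_flags.append(True)
        else:
            tp_flags.append(False)

    n_gt = len(gts)
    recalls, precisions = [], []
    tp = fp = 0
    for flag in tp_flags:
        tp += flag
        fp += not flag
        recalls.append(tp / n_gt)
        precisions.append(tp / (tp + fp))

    # precision envelope: best precision at recall >= r
    env = precisions[:]
    for i in range(len(env) - 2, -1, -1):
        env[i] = max(env[i], env[i + 1])

    if interpolation == "11point":
        total = 0.0
        for r in [i / 10.0 for i in range(11)]:
            ps = [p for rec, p in zip(recalls, env) if rec >= r - 1e-12]
            total += max(ps) if ps else 0.0
        return total / 11.0
    if interpolation != "continuous":
        raise ValueError("interpolation must be 'continuous' or '11point'")
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return ap


def mean_average_precision_50(
    dets: list[Detection],
    gts: list[tuple[OrientedBox | HorizontalBox, int]],
    iou_thr: float = 0.5,
    interpolation: str = "continuous",
) -> float | None:
    """mAP50: mean of per-class APs (classes present in the ground truth)."""
    classes = sorted({cid for _, cid in gts})
    if not classes:
        return None
    aps = []
    for cid in classes:
        ap = average_precision_50(
            [d for d in dets if d.class_id == cid],
            [b for b, c in gts if c == cid],
            iou_thr,
            interpolation,
        )
        aps.append(ap if ap is not None else 0.0)
    return fmean(aps)


@dataclass(frozen=True)
class EvalReport:
    counts: ConfusionCounts | None = None
    precision: float | None = None
    recall: float | None = None
    accuracy: float | None = None
    map50: float | None = None
    per_image_deviation_deg: tuple[float, ...] = field(default_factory=tuple)
    mean_deviation_deg: float | None = None


def angular_deviation_report(
    pred: list[Pathway | Line],
    truth: list[Line],
) -> EvalReport:
    """Per-image unsigned angular deviation (degrees, in [0, 90]) between
    predicted pathway lines and reference lines, and their arithmetic mean.
    """
    if len(pred) != len(truth):
        raise ValueError(f"pairing error: {len(pred)} predictions vs {len(truth)} truths")
    devs = tuple(
        angle_between(p.line if isinstance(p, Pathway) else p, t)
        for p, t in zip(pred, truth)
    )
    return EvalReport(
        per_image_deviation_deg=devs,
        mean_deviation_deg=fmean(devs) if devs else None,
    )
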