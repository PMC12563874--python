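"""Score oriented-box detections against ground truth.

Builds a tiny detection problem with one dead-on, one displaced and one
spurious box, then prints the confusion counts, precision/recall and
AP50 the evaluation module computes.
"""

from implantpath import (
    Detection,
    OrientedBox,
    average_precision_50,
    match_detections,
    precision_recall_accuracy,
    rotated_iou,
)

gts = [OrientedBox(60, 80, 34, 90, 170), OrientedBox(160, 80, 34, 90, 10)]
dets = [
    Detection(OrientedBox(60, 80, 34, 90, 170), confidence=0.95),  # exact hit
    Detection(OrientedBox(150, 84, 36, 88, 14), confidence=0.80),  # close hit
    Detection(OrientedBox(40, 20, 30, 30, 0), confidence=0.60),    # spurious
]

print(f"IoU of the close hit: {rotated_iou(dets[1].box, gts[1]):.3f}")
counts, pairs = match_detections(dets, gts, iou_thr=0.5)
print(f"counts: tp={counts.tp} fp={counts.fp} fn={counts.fn}")
precision, recall, accuracy = precision_recall_accuracy(counts)
print(f"precision={precision:.3f} recall={recall:.3f} accuracy={accuracy:.3f}")
print(f"AP50={average_precision_50(dets, gts):.3f}")

# Matching is greedy one-to-one in confidence order at IoU >= 0.5; the
# spurious box becomes the single false positive, and AP integrates the
# precision envelope over recall.
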