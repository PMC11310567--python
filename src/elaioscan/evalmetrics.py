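"""Evaluation metrics for instance detection and segmentation.

Pixel-level confusion counts and the derived classification metrics
(accuracy, recall, specificity, precision, F1), box and mask IoU, all-point
interpolated average precision with the 0.50:0.95 threshold sweep, mAP, and
the stage-similarity statistic used to compare prediction sets.

AP follows the standard convention: detections sorted by descending score
(ties broken by annotation id), greedily matched one-to-one to ground truths
at or above the IoU threshold, and

    AP = sum_n (R_{n+1} - R_n) * p_interp(R_{n+1}),
    p_interp(r) = max_{r' >= r} p(r'),

reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

IOU_SWEEP = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    precision: float
    recall: float
    specificity: float
    f1: float
    accuracy: float


@dataclass(frozen=True)
class APResult:
    per_threshold: dict      # {tau: AP percent}
    ap50: float
    ap75: float
    ap50_95: float
    curve: list              # (recall, interpolated precision) samples at tau=0.5


def box_iou(a, b) -> float:
    """IoU of two (x, y, w, h) boxes on continuous geometry."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if min(aw, ah, bw, bh) < 0:
        raise ValueError("negative box size")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel-count IoU; 0 by convention when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion of one predicted mask against ground truth."""
    p = np.asarray(pred_mask, bool)
    g = np.asarray(gt_mask, bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def accumulate_confusion(pairs) -> ConfusionCounts:
    """Sum pixel confusion over (pred, gt) mask pairs."""
    total = ConfusionCounts(0, 0, 0, 0)
    for p, g in pairs:
        total = total + confusion_counts(p, g)
    return total


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, recall, specificity, precision and F1 from pixel counts.

    A metric whose denominator is zero is reported as NaN (undefined), not 0.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    specificity = ratio(c.tn, c.tn + c.fp)
    accuracy = (c.tp + c.tn) / c.total
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else float("nan"))
    return ClassificationMetrics(precision=precision, recall=recall,
                                 specificity=specificity, f1=f1,
                                 accuracy=accuracy)


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def _match_detections(detections, ground_truths, iou_threshold, iou_fn):
    """Greedy COCO-style matching.

    ``detections``: (image_id, ann_id, score, geometry); ``ground_truths``:
    (image_id, geometry).  Returns a TP/FP flag per detection, in the order
    of descending score (ties by ann_id ascending).
    """
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i][2], detections[i][1]))
    unmatched = {}
    for gi, (img, _) in enumerate(ground_truths):
        unmatched.setdefault(img, []).append(gi)
    flags = []
    for i in order:
        img, _, _, geom = detections[i]
        best, best_iou = None, 0.0
        for gi in unmatched.get(img, ()):
            iou = iou_fn(geom, ground_truths[gi][1])
            if iou > best_iou:
                best, best_iou = gi, iou
        if best is not None and best_iou >= iou_threshold:
            flags.append(True)
            unmatched[img].remove(best)
        else:
            flags.append(False)
    return flags


def _interp_ap(flags, n_gt):
    """All-point interpolated AP (fraction, not percent) from ordered flags."""
    tp = np.cumsum(flags)
    fp = np.cumsum(~np.asarray(flags, bool))
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope: max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    samples = []
    for r, p in zip(recall, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            samples.append((float(r), float(p)))
            prev_r = r
    return ap, samples


def average_precision(detections, ground_truths, iou_threshold: float,
                      iou_kind: str = "mask") -> float:
    """Interpolated AP in percent at one IoU threshold.

    ``detections`` are (image_id, ann_id, score, geometry) tuples and
    ``ground_truths`` are (image_id, geometry), where geometry is a bbox for
    ``iou_kind='box'`` or a boolean mask for ``iou_kind='mask'``.
    """
    if not ground_truths:
        raise ValueError("empty ground truth")
    if not detections:
        return 0.0
    iou_fn = box_iou if iou_kind == "box" else mask_iou
    flags = _match_detections(detections, ground_truths, iou_threshold, iou_fn)
    ap, _ = _interp_ap(flags, len(ground_truths))
    return 100.0 * ap


def ap_sweep(detections, ground_truths, iou_kind: str = "mask") -> APResult:
    """AP at IoU thresholds 0.50:0.95 (step 0.05) plus their mean (AP50:95)."""
    if not ground_truths:
        raise ValueError("empty ground truth")
    iou_fn = box_iou if iou_kind == "box" else mask_iou
    per = {}
    curve = []
    for tau in IOU_SWEEP:
        if detections:
            flags = _match_detections(detections, ground_truths, tau, iou_fn)
            ap, samples = _interp_ap(flags, len(ground_truths))
        else:
            ap, samples = 0.0, []
        per[float(tau)] = 100.0 * ap
        if tau == 0.5:
            curve = samples
    vals = list(per.values())
    return APResult(per_threshold=per, ap50=per[0.5], ap75=per[0.75],
                    ap50_95=float(np.mean(vals)), curve=curve)


def mean_ap(per_class_ap) -> float:
    """mAP: arithmetic mean of per-class AP values."""
    vals = list(per_class_ap)
    if not vals:
        raise ValueError("no classes")
    return float(np.mean(vals))
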