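"""Stage-wise semi-automatic labeling (self-training) protocol.

An initial detector is trained on a small ground-truth-labeled set; at each
later stage the current model predicts on the entire unlabeled pool, the
correct predictions are selected (automatically against synthetic ground
truth, or via a user-supplied accept list standing in for manual checking),
a larger training set is sampled from the selections, and the detector is
retrained from scratch.  After every stage the model is evaluated on a fixed
held-out test split, and prediction sets of different stages are compared
with the similarity statistic

    similarity = ycount / (ycount + ncount),

where a reference detection counts toward ycount when the paired mask IoU
exceeds 0.9 and toward ncount otherwise (including reference images where the
other set has no detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import detector as _baseline
from .detector import Detection
from .evalmetrics import (APResult, accumulate_confusion, ap_sweep,
                          classification_metrics, mask_iou)
from .preprocess import SeedCrop


@dataclass
class PoolItem:
    """One crop in the self-training pool."""

    item_id: int
    crop: SeedCrop
    gt_elaiosome: np.ndarray  # bool mask; ground truth (synthetic) label


@dataclass(frozen=True)
class StageConfig:
    stage_sizes: tuple[int, ...] = (10, 20, 40, 80)
    selection_mode: str = "auto"            # "auto" | "accept_list"
    selection_iou_threshold: float = 0.9
    score_threshold: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.stage_sizes:
            raise ValueError("stage_sizes is empty")
        if any(b <= a for a, b in zip(self.stage_sizes, self.stage_sizes[1:])):
            raise ValueError("stage_sizes must be strictly increasing")
        for t in (self.selection_iou_threshold, self.score_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.selection_mode not in ("auto", "accept_list"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")


@dataclass
class StageRecord:
    stage_index: int
    n_train: int
    selected_ids: list[int]
    train_ids: list[int]
    metrics: dict                 # classification metrics + AP sweep on test
    params: object                # detector parameter snapshot
    pool_predictions: dict        # item_id -> Detection (for similarity)


@dataclass(frozen=True)
class SimilarityResult:
    similarity: float
    ycount: int
    ncount: int


def select_correct(predictions: dict, references: dict | None,
                   mode: str = "auto", iou_threshold: float = 0.9,
                   score_threshold: float = 0.5,
                   accept_list: set | None = None) -> dict:
    """Keep the "correct" predictions as new training labels.

    ``predictions`` maps item id -> Detection.  In auto mode a prediction is
    kept when its score exceeds ``score_threshold`` and its mask IoU with the
    ground-truth reference exceeds ``iou_threshold``; in accept_list mode the
    ids in ``accept_list`` are kept (the manual-curation stand-in).
    """
    if mode == "auto":
        if references is None:
            raise ValueError("auto selection requires reference masks")
        return {
            i: det for i, det in predictions.items()
            if det.score > score_threshold
            and i in references
            and mask_iou(det.mask, references[i]) > iou_threshold
        }
    if mode == "accept_list":
        accept = accept_list or set()
        return {i: det for i, det in predictions.items() if i in accept}
    raise ValueError(f"unknown selection mode {mode!r}")


def _evaluate(params, items: list[PoolItem], predict_fn) -> dict:
    """Held-out evaluation: mask/box AP sweep plus pixel confusion metrics."""
    detections, gts, pairs = [], [], []
    for it in items:
        gts.append((it.item_id, it.gt_elaiosome))
        dets = predict_fn(params, it.crop)
        pred_mask = np.zeros_like(it.gt_elaiosome)
        if dets:
            d = dets[0]
            detections.append((it.item_id, it.item_id, d.score, d.mask))
            if d.score > 0.5:
                pred_mask = d.mask
        pairs.append((pred_mask, it.gt_elaiosome))
    mask_ap = ap_sweep(detections, gts, iou_kind="mask")
    box_dets = [(img, aid, sc, _tight_box(m)) for img, aid, sc, m in detections]
    box_gts = [(img, _tight_box(m)) for img, m in gts]
    box_ap = ap_sweep(box_dets, box_gts, iou_kind="box")
    cls = classification_metrics(accumulate_confusion(pairs))
    return {"mask_ap": mask_ap, "box_ap": box_ap, "classification": cls}


def _tight_box(mask):
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return (0.0, 0.0, 0.0, 0.0)
    x0, y0 = float(xs.min()), float(ys.min())
    return (x0, y0, float(xs.max()) + 1 - x0, float(ys.max()) + 1 - y0)


def run_protocol(pool: list[PoolItem], test_items: list[PoolItem],
                 config: StageConfig = StageConfig(),
                 fit_fn=_baseline.fit, predict_fn=_baseline.predict,
                 accept_lists: list[set] | None = None,
                 log=None) -> list[StageRecord]:
    """Run the full multi-stage protocol; returns one StageRecord per stage.

    Stage 0 trains on ``stage_sizes[0]`` ground-truth-labeled pool items
    (seeded sample).  Every later stage predicts on the whole pool, selects
    correct predictions, samples its stage size from the selection (all of it
    when fewer were selected), retrains from scratch, and is evaluated on the
    fixed ``test_items``.
    """
    config.validate()
    if not pool:
        raise ValueError("empty pool")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, 17]))
    say = log or (lambda *_: None)

    records: list[StageRecord] = []
    ids = sorted(it.item_id for it in pool)
    by_id = {it.item_id: it for it in pool}

    for stage, size in enumerate(config.stage_sizes):
        if stage == 0:
            n0 = min(size, len(ids))
            train_ids = sorted(rng.choice(ids, size=n0, replace=False).tolist())
            labels = {i: by_id[i].gt_elaiosome for i in train_ids}
            selected_ids: list[int] = []
        else:
            prev = records[-1]
            if config.selection_mode == "auto":
                refs = {i: by_id[i].gt_elaiosome for i in ids}
                sel = select_correct(prev.pool_predictions, refs, "auto",
                                     config.selection_iou_threshold,
                                     config.score_threshold)
            else:
                accept = (accept_lists[stage - 1]
                          if accept_lists and stage - 1 < len(accept_lists)
                          else set())
                sel = select_correct(prev.pool_predictions, None,
                                     "accept_list", accept_list=accept)
            selected_ids = sorted(sel)
            n = min(size, len(selected_ids))
            if n < size:
                say(f"stage {stage}: only {n} selected predictions available "
                    f"for requested {size}")
            train_ids = sorted(rng.choice(selected_ids, size=n,
                                          replace=False).tolist())
            labels = {i: sel[i].mask for i in train_ids}
        if not labels:
            raise ValueError(f"stage {stage}: empty training set")

        params = fit_fn([(by_id[i].crop, labels[i]) for i in train_ids])
        pool_preds = {}
        for i in ids:
            dets = predict_fn(params, by_id[i].crop)
            if dets:
                pool_preds[i] = dets[0]
        metrics = _evaluate(params, test_items, predict_fn)
        say(f"stage {stage}: n_train={len(train_ids)} "
            f"selected={len(selected_ids)} "
            f"mask AP50:95={metrics['mask_ap'].ap50_95:.2f}")
        records.append(StageRecord(
            stage_index=stage, n_train=len(train_ids),
            selected_ids=selected_ids, train_ids=train_ids,
            metrics=metrics, params=params, pool_predictions=pool_preds))
    return records


def stage_similarity(preds_ref: dict, preds_other: dict,
                     iou_threshold: float = 0.9) -> SimilarityResult:
    """Similarity of two prediction sets over shared image ids.

    For every reference detection, the paired detection's mask IoU above the
    threshold counts toward ycount, otherwise (including a missing detection
    in the other set) toward ncount; similarity = ycount / (ycount + ncount).
    """
    if not preds_ref:
        raise ValueError("empty reference prediction set")

    def mask_of(p):
        return p.mask if isinstance(p, Detection) else np.asarray(p, bool)

    y = n = 0
    for img_id, ref in preds_ref.items():
        other = preds_other.get(img_id)
        if other is None:
            n += 1
            continue
        if mask_iou(mask_of(ref), mask_of(other)) > iou_threshold:
            y += 1
        else:
            n += 1
    return SimilarityResult(similarity=y / (y + n), ycount=y, ncount=n)
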