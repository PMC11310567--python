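"""Unit tests for IoU, confusion metrics and interpolated average precision."""

import numpy as np
import pytest

from elaioscan.evalmetrics import (ConfusionCounts, accumulate_confusion,
                                   ap_sweep, average_precision, box_iou,
                                   classification_metrics, confusion_counts,
                                   mask_iou, mean_ap)


def brute_force_ap(flags, n_gt):
    """Independent oracle: interpolated precision evaluated at every achieved
    recall by direct max-scan over the raw precision/recall sequence."""
    flags = list(flags)
    tps = np.cumsum(flags)
    fps = np.cumsum([not f for f in flags])
    recalls = tps / n_gt
    precisions = tps / (tps + fps)
    achieved = sorted(set(recalls[recalls > 0]))
    ap = 0.0
    prev = 0.0
    for r in achieved:
        p_interp = max(p for rr, p in zip(recalls, precisions) if rr >= r)
        ap += (r - prev) * p_interp
        prev = r
    return 100.0 * ap


class TestIoU:
    def test_box_identity_and_arithmetic(self):
        assert box_iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
        assert box_iou((0, 0, 10, 10), (5, 0, 10, 10)) == pytest.approx(1 / 3)
        assert box_iou((0, 0, 10, 10), (20, 20, 5, 5)) == 0.0
        assert box_iou((0, 0, 0, 0), (0, 0, 0, 0)) == 0.0

    def test_mask_iou_identity_containment_symmetry(self):
        rng = np.random.default_rng(0)
        a = np.zeros((20, 20), bool)
        a[:5, :20] = True  # 100 px
        b = np.zeros((20, 20), bool)
        b[:5, :10] = True  # nested 50 px
        assert mask_iou(a, a) == 1.0
        assert mask_iou(a, b) == 0.5
        assert mask_iou(b, ~a & b) == 0.0  # disjoint from itself minus a
        for _ in range(100):
            x = rng.random((12, 12)) < 0.5
            y = rng.random((12, 12)) < 0.5
            assert mask_iou(x, y) == mask_iou(y, x)
        assert mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 0.0
        with pytest.raises(ValueError):
            mask_iou(np.zeros((4, 4), bool), np.zeros((5, 4), bool))


class TestConfusion:
    def test_perfect_and_miss_cases(self):
        gt = np.zeros((170, 170), bool)
        gt[10:20, 10:20] = True  # 100 px
        c = confusion_counts(gt, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (100, 0, 0, 170 * 170 - 100)
        c = confusion_counts(np.zeros_like(gt), gt)
        assert (c.tp, c.fp, c.fn) == (0, 0, 100)

    def test_conservation_and_formulas_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random((31, 17)) < rng.random()
            g = rng.random((31, 17)) < rng.random()
            c = confusion_counts(p, g)
            assert c.total == 31 * 17
            m = classification_metrics(c)
            # independent spreadsheet-style recomputation
            assert m.accuracy == pytest.approx(
                (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn), abs=1e-12)
            if c.tp + c.fn:
                assert m.recall == pytest.approx(c.tp / (c.tp + c.fn), abs=1e-12)
            if c.tn + c.fp:
                assert m.specificity == pytest.approx(
                    c.tn / (c.tn + c.fp), abs=1e-12)
            if c.tp + c.fp:
                assert m.precision == pytest.approx(
                    c.tp / (c.tp + c.fp), abs=1e-12)

    def test_worked_example(self):
        m = classification_metrics(ConfusionCounts(tp=50, fp=10, tn=930, fn=10))
        assert m.precision == pytest.approx(5 / 6)
        assert m.recall == pytest.approx(5 / 6)
        assert m.specificity == pytest.approx(93 / 94)
        assert m.accuracy == pytest.approx(0.98)
        assert m.f1 == pytest.approx(5 / 6)

    def test_accumulate_sums_pairs(self):
        g = np.zeros((10, 10), bool)
        g[:2] = True
        total = accumulate_confusion([(g, g), (np.zeros_like(g), g)])
        assert (total.tp, total.fn, total.total) == (20, 20, 200)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))


def _boxes_for_flags(flags):
    """Build detections/ground truths realizing a TP/FP sequence at IoU 0.5."""
    gts = []
    dets = []
    n_gt = sum(flags)
    for i, f in enumerate(flags):
        if f:
            gts.append((0, (10.0 * len(gts), 0.0, 5.0, 5.0)))
    k = 0
    for i, f in enumerate(flags):
        if f:
            dets.append((0, i, 0.9 - 0.01 * i, gts[k][1]))
            k += 1
        else:
            dets.append((0, i, 0.9 - 0.01 * i, (1000.0 + 10 * i, 0.0, 5.0, 5.0)))
    return dets, gts


class TestAveragePrecision:
    def test_worked_interpolation_example(self):
        # TP, FP, TP against 2 ground truths -> AP = 0.5*1 + 0.5*(2/3)
        dets, gts = _boxes_for_flags([True, False, True])
        ap = average_precision(dets, gts, 0.5, iou_kind="box")
        assert ap == pytest.approx(100 * (0.5 + 0.5 * 2 / 3), abs=1e-9)

    def test_perfect_and_all_fp(self):
        dets, gts = _boxes_for_flags([True, True, True])
        assert average_precision(dets, gts, 0.5, "box") == pytest.approx(100.0)
        dets, gts = _boxes_for_flags([True, True])
        bad = [(img, i, s, (500.0, 500.0, 2.0, 2.0)) for img, i, s, _ in dets]
        assert average_precision(bad, gts, 0.5, "box") == 0.0
        assert average_precision([], gts, 0.5, "box") == 0.0
        with pytest.raises(ValueError):
            average_precision(dets, [], 0.5, "box")

    def test_matches_brute_force_oracle_on_random_flag_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 21))
            flags = (rng.random(n) < 0.5).tolist()
            if not any(flags):
                flags[0] = True
            dets, gts = _boxes_for_flags(flags)
            ap = average_precision(dets, gts, 0.5, "box")
            assert ap == pytest.approx(brute_force_ap(flags, len(gts)),
                                       abs=1e-9)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        flags = (rng.random(12) < 0.6).tolist()
        dets, gts = _boxes_for_flags(flags)
        ap1 = average_precision(dets, gts, 0.5, "box")
        squashed = [(img, i, 0.5 + 0.4 * np.tanh(s), g)
                    for img, i, s, g in dets]
        ap2 = average_precision(squashed, gts, 0.5, "box")
        assert ap1 == pytest.approx(ap2, abs=1e-12)


class TestApSweep:
    def _iou_masks(self, iou):
        """gt/pred mask pair with exact pixel IoU."""
        gt = np.zeros((40, 40), bool)
        gt[:10, :10] = True  # 100 px
        k = int(round(100 * iou))
        pred = np.zeros_like(gt)
        pred[np.nonzero(gt)[0][:k], np.nonzero(gt)[1][:k]] = True
        return pred, gt

    def test_perfect_detections(self):
        gt = np.zeros((20, 20), bool)
        gt[5:15, 5:15] = True
        res = ap_sweep([(0, 1, 0.9, gt)], [(0, gt)], "mask")
        assert all(v == pytest.approx(100.0) for v in res.per_threshold.values())
        assert res.ap50_95 == pytest.approx(100.0)

    def test_threshold_step_construction(self):
        # all detections at IoU exactly 0.6: matched for tau in {.50,.55,.60}
        pred, gt = self._iou_masks(0.6)
        assert mask_iou(pred, gt) == pytest.approx(0.6)
        res = ap_sweep([(0, 1, 0.9, pred)], [(0, gt)], "mask")
        for tau, ap in res.per_threshold.items():
            assert ap == (pytest.approx(100.0) if tau <= 0.6 else 0.0)
        assert res.ap50_95 == pytest.approx(30.0)

    def test_ap50_not_below_ap75_on_random_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(1, 8))
            dets, gts = [], []
            for i in range(n):
                pred, gt = self._iou_masks(float(rng.uniform(0.3, 1.0)))
                gts.append((i, gt))
                dets.append((i, i, float(rng.uniform(0.55, 1.0)), pred))
            res = ap_sweep(dets, gts, "mask")
            assert res.ap50 >= res.ap75 - 1e-12


def test_mean_ap():
    assert mean_ap([80.0]) == 80.0
    assert mean_ap([100.0, 0.0]) == 50.0
    with pytest.raises(ValueError):
        mean_ap([])
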