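"""Loss and metric exactness, confusion counting, dataset aggregation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridgeseg.metrics import (ConfusionCounts, confusion_counts,
                              cross_entropy_loss, evaluate_dataset,
                              metrics_from_counts)

RNG = np.random.default_rng(777)


class TestCrossEntropy:
    def test_symmetric_logits_give_log_k(self):
        for label in (0, 1):
            assert cross_entropy_loss(np.array([0.0, 0.0]),
                                      np.array(label)) == pytest.approx(np.log(2), abs=1e-6)

    def test_single_pixel_direct_evaluation(self):
        # -x[0] + log(e^2 + e^1) = log(1 + e^-1)
        assert cross_entropy_loss(np.array([2.0, 1.0]),
                                  np.array(0)) == pytest.approx(np.log(1 + np.exp(-1)),
                                                                abs=1e-6)

    def test_shift_invariance(self):
        logits = RNG.normal(size=(2, 6, 5))
        labels = RNG.integers(0, 2, (6, 5))
        a = cross_entropy_loss(logits, labels)
        b = cross_entropy_loss(logits + 137.5, labels)
        assert a == pytest.approx(b, abs=1e-9)

    def test_agrees_with_naive_unstabilised_form(self):
        logits = RNG.normal(size=(3, 2, 4, 4))
        labels = RNG.integers(0, 2, (3, 4, 4))
        naive = np.mean(
            [-logits[n, labels[n, i, j], i, j] + np.log(np.exp(logits[n, :, i, j]).sum())
             for n in range(3) for i in range(4) for j in range(4)])
        assert cross_entropy_loss(logits, labels) == pytest.approx(naive, abs=1e-6)

    def test_stable_under_large_logits(self):
        val = cross_entropy_loss(np.array([1000.0, 0.0]), np.array(0))
        assert np.isfinite(val) and val >= 0

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            cross_entropy_loss(RNG.normal(size=(2, 3, 3)),
                               np.full((3, 3), 2))


class TestConfusionCounts:
    def test_perfect_agreement(self):
        truth = np.zeros((10, 10), dtype=int)
        truth[:3] = 1  # 30 positives
        c = confusion_counts(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (30, 70, 0, 0)

    def test_complement_prediction(self):
        truth = RNG.integers(0, 2, (8, 8))
        c = confusion_counts(1 - truth, truth)
        assert c.tp == 0 and c.tn == 0
        assert c.total == 64

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_per_pixel_loop_oracle(self, seed):
        r = np.random.default_rng(seed)
        pred = r.integers(0, 2, (8, 8))
        truth = r.integers(0, 2, (8, 8))
        c = confusion_counts(pred, truth, positive_class=1)
        tp = fp = fn = tn = 0
        for i in range(8):
            for j in range(8):
                if pred[i, j] == 1 and truth[i, j] == 1:
                    tp += 1
                elif pred[i, j] == 1:
                    fp += 1
                elif truth[i, j] == 1:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_shape_mismatch_and_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="labels"):
            confusion_counts(np.full((2, 2), 2), np.zeros((2, 2)))


class TestMetricsFromCounts:
    def test_hand_arithmetic_example(self):
        acc, pr, re, iou = metrics_from_counts(ConfusionCounts(50, 10, 10, 30))
        assert acc == pytest.approx(80.0)
        assert pr == pytest.approx(83.33, abs=0.01)
        assert re == pytest.approx(83.33, abs=0.01)
        assert iou == pytest.approx(71.43, abs=0.01)

    def test_perfect_prediction_scores_100(self):
        assert metrics_from_counts(ConfusionCounts(40, 0, 0, 60)) == (100, 100, 100, 100)

    def test_perfectly_absent_class_policy(self):
        acc, pr, re, iou = metrics_from_counts(ConfusionCounts(0, 0, 0, 50))
        assert (acc, pr, re, iou) == (100.0, 100.0, 100.0, 100.0)

    def test_zero_denominators_never_raise(self):
        assert metrics_from_counts(ConfusionCounts(0, 0, 5, 5))[1] == 0.0  # no preds
        assert metrics_from_counts(ConfusionCounts(0, 5, 0, 5))[2] == 0.0  # no truths

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds_and_iou_dominated_by_pr_and_re(self, seed):
        r = np.random.default_rng(seed)
        c = ConfusionCounts(*[int(x) for x in r.integers(0, 50, 4)])
        if c.total == 0:
            return
        acc, pr, re, iou = metrics_from_counts(c)
        assert all(0 <= v <= 100 for v in (acc, pr, re, iou))
        assert iou <= pr + 1e-9 and iou <= re + 1e-9

    def test_accuracy_symmetric_under_class_swap(self):
        pred = RNG.integers(0, 2, (9, 9))
        truth = RNG.integers(0, 2, (9, 9))
        a0 = metrics_from_counts(confusion_counts(pred, truth, 0))[0]
        a1 = metrics_from_counts(confusion_counts(pred, truth, 1))[0]
        assert a0 == pytest.approx(a1)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(ConfusionCounts())


class _FixedPredictor:
    """Returns queued masks; lets dataset evaluation be driven exactly."""

    def __init__(self, masks):
        self.masks = list(masks)
        self.i = 0

    def predict(self, img):
        mask = self.masks[self.i]
        self.i += 1
        return mask


class TestEvaluateDataset:
    def _img(self, h=4, w=4):
        return np.zeros((h, w, 3), dtype=np.uint8)

    def test_per_image_mean_averages_image_scores(self):
        truth = np.zeros((4, 4), dtype=int)
        wrong = np.ones((4, 4), dtype=int)
        wrong[:2] = 0  # 50% accurate
        model = _FixedPredictor([truth.copy(), wrong])
        report = evaluate_dataset(model, [(self._img(), truth), (self._img(), truth)])
        assert report.accuracy == pytest.approx(75.0)
        assert report.n_images == 2

    def test_single_image_mean_equals_pooled(self):
        truth = RNG.integers(0, 2, (6, 6))
        pred = RNG.integers(0, 2, (6, 6))
        r1 = evaluate_dataset(_FixedPredictor([pred]), [(self._img(6, 6), truth)],
                              aggregation="per_image_mean")
        r2 = evaluate_dataset(_FixedPredictor([pred]), [(self._img(6, 6), truth)],
                              aggregation="pooled")
        assert r1.miou == pytest.approx(r2.miou)
        assert r1.per_class[1].iou == pytest.approx(r2.per_class[1].iou)

    def test_background_predictor_on_background_dataset_is_perfect(self):
        truth = np.zeros((4, 4), dtype=int)
        model = _FixedPredictor([truth.copy(), truth.copy()])
        report = evaluate_dataset(model, [(self._img(), truth)] * 2)
        assert report.accuracy == pytest.approx(100.0)
        assert report.miou == pytest.approx(100.0)

    def test_miou_is_mean_of_class_ious_when_pooled(self):
        truth = RNG.integers(0, 2, (8, 8))
        pred = RNG.integers(0, 2, (8, 8))
        rep = evaluate_dataset(_FixedPredictor([pred]), [(self._img(8, 8), truth)],
                               aggregation="pooled")
        assert rep.miou == pytest.approx(
            (rep.per_class[0].iou + rep.per_class[1].iou) / 2)

    def test_report_table_has_per_image_rows_plus_aggregate(self):
        truth = np.zeros((4, 4), dtype=int)
        model = _FixedPredictor([truth.copy(), truth.copy()])
        frame = evaluate_dataset(model, [(self._img(), truth)] * 2).to_frame()
        assert len(frame) == 3
        assert frame.iloc[-1]["image"] == "aggregate"

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_dataset(_FixedPredictor([]), [])
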