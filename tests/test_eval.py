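"""Confusion matrix, threshold metrics and rank AUC against independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from colonyqc.evaluate import (ConfusionMatrix, auc, confusion, dual_report,
                               metrics, report_from_scores)
from colonyqc.exceptions import ValidationError
from colonyqc.image import BAD, GOOD


def table4_vectors():
    """Label vectors reproducing the study's validation confusion matrix:
    of 26 actual-good colonies 24 were called good; of 28 actual-bad, 24 bad."""
    y_true = [GOOD] * 26 + [BAD] * 28
    y_pred = [GOOD] * 24 + [BAD] * 2 + [GOOD] * 4 + [BAD] * 24
    return y_true, y_pred


class TestConfusion:
    def test_reference_counts(self):
        cm = confusion(*table4_vectors(), positive_class=GOOD)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (24, 2, 4, 24)
        assert cm.n == 54

    def test_perfect_agreement(self):
        y = [GOOD, BAD, GOOD]
        cm = confusion(y, y)
        assert cm.fp == cm.fn == 0

    def test_flip_predictions_swaps_offdiagonals(self):
        y_true, y_pred = table4_vectors()
        flipped = [BAD if p == GOOD else GOOD for p in y_pred]
        cm = confusion(y_true, y_pred)
        cmf = confusion(y_true, flipped)
        assert (cmf.tp, cmf.fn) == (cm.fn, cm.tp)
        assert (cmf.fp, cmf.tn) == (cm.tn, cm.fp)

    def test_positive_class_swap(self):
        cm = confusion(*table4_vectors(), positive_class=GOOD)
        sw = cm.swapped()
        assert (sw.tp, sw.fn, sw.fp, sw.tn) == (cm.tn, cm.fp, cm.fn, cm.tp)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="ugly"):
            confusion([GOOD, "ugly"], [GOOD, BAD])


class TestMetrics:
    def test_headline_accuracy_and_f1(self):
        """24/2/4/24 -> accuracy 48/54 = 89% and F1 0.89 (2 d.p.), under
        either positive-class convention for this matrix."""
        cm = confusion(*table4_vectors())
        r = metrics(cm)
        assert r.accuracy == pytest.approx(48 / 54)
        assert round(100 * r.accuracy) == 89
        assert round(r.f1, 2) == 0.89
        rb = metrics(cm.swapped())
        assert rb.accuracy == pytest.approx(r.accuracy)
        assert round(rb.f1, 2) == 0.89

    def test_perfect_classifier_all_ones(self):
        r = metrics(ConfusionMatrix(tp=5, fn=0, fp=0, tn=9))
        assert (r.accuracy, r.precision, r.recall, r.f1) == (1, 1, 1, 1)
        assert not r.degenerate

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 30, 4)
            r = metrics(ConfusionMatrix(int(tp), int(fn), int(fp), int(tn)))
            assert min(r.precision, r.recall) - 1e-12 <= r.f1
            assert r.f1 <= max(r.precision, r.recall) + 1e-12

    def test_zero_denominator_flagged_not_nan(self):
        r = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=10))
        assert r.precision == 0.0 and "precision" in r.degenerate
        assert "recall" in r.degenerate

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_all_correct_metrics_from_labels(self):
        y = [GOOD] * 3 + [BAD] * 4
        r = metrics(confusion(y, y))
        assert (r.accuracy, r.precision, r.recall, r.f1) == (1, 1, 1, 1)


class TestAuc:
    def test_perfectly_ordered_is_one(self):
        y = [GOOD] * 3 + [BAD] * 3
        assert auc(y, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]) == 1.0

    def test_perfectly_inverted_is_zero(self):
        y = [GOOD] * 3 + [BAD] * 3
        assert auc(y, [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = [GOOD] * 500 + [BAD] * 500
        val = auc(y, rng.random(1000))
        assert val == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_and_sklearn_oracles(self):
        """Rank AUC == brute-force pairwise comparison == ROC trapezoid."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_pos, n_neg = rng.integers(2, 15, 2)
            y = np.array([GOOD] * n_pos + [BAD] * n_neg, dtype=object)
            s = np.round(rng.random(n_pos + n_neg), 1)   # force ties
            pos, neg = s[:n_pos], s[n_pos:]
            pairwise = np.mean((pos[:, None] > neg[None, :])
                               + 0.5 * (pos[:, None] == neg[None, :]))
            ours = auc(y, s)
            assert ours == pytest.approx(pairwise, abs=1e-9)
            assert ours == pytest.approx(
                roc_auc_score((y == GOOD).astype(int), s), abs=1e-9)

    def test_ties_count_half(self):
        assert auc([GOOD, BAD], [0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([GOOD, GOOD], [0.1, 0.9])


class TestReports:
    def test_dual_report_conventions(self):
        rng = np.random.default_rng(3)
        y = np.array([GOOD] * 10 + [BAD] * 12, dtype=object)
        s = rng.random(22)
        both = dual_report(y, s)
        assert both[GOOD].accuracy == pytest.approx(both[BAD].accuracy)
        # flipping both the positive class and the score orientation leaves
        # the ranking quality unchanged
        assert both[GOOD].auc == pytest.approx(both[BAD].auc)
        assert both[GOOD].confusion.tp == both[BAD].confusion.tn

    def test_report_from_scores_thresholding(self):
        y = [GOOD, GOOD, BAD, BAD]
        r = report_from_scores(y, [0.9, 0.6, 0.4, 0.1], threshold=0.5)
        assert r.accuracy == 1.0
        assert r.auc == 1.0
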