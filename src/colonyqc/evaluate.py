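"""Confusion matrix, the four threshold metrics, and rank-based AUC.

Accuracy is the fraction of correctly classified samples; precision is
TP / (TP + FP); recall (sensitivity) is TP / (TP + FN); F1 is the harmonic
mean 2·precision·recall / (precision + recall).  AUC is computed rank-based
(Mann–Whitney statistic, ties counted 1/2), which equals the trapezoidal
area under the empirical ROC curve.

Because precision/recall depend on which phenotype is called positive, the
:func:`dual_report` helper reports both conventions side by side; the
package headline convention is good-positive (matching the training target
y = 1 for good).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import ValidationError
from .image import BAD, GOOD

__all__ = ["ConfusionMatrix", "EvalReport", "confusion", "metrics", "auc",
           "dual_report", "report_from_scores"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 actual-vs-predicted counts under a declared positive class."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_class: str = GOOD

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """Same data with the positive-class convention flipped."""
        other = BAD if self.positive_class == GOOD else GOOD
        return ConfusionMatrix(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp,
                               positive_class=other)


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    positive_class: str
    threshold: float
    confusion: ConfusionMatrix
    degenerate: tuple[str, ...] = field(default_factory=tuple)
    """Names of metrics whose denominator was zero (reported as 0)."""

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "positive_class": self.positive_class, "threshold": self.threshold,
            "confusion": {"tp": self.confusion.tp, "fn": self.confusion.fn,
                          "fp": self.confusion.fp, "tn": self.confusion.tn},
            "degenerate": list(self.degenerate),
        }


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    bad_vals = sorted({str(v) for v in labels if v not in (GOOD, BAD)})
    if bad_vals:
        raise ValidationError(f"unknown labels {bad_vals}; expected good/bad")
    return labels


def confusion(y_true, y_pred, positive_class: str = GOOD) -> ConfusionMatrix:
    """Count the 2x2 table from matched label vectors."""
    y_true = _check_labels(y_true)
    y_pred = _check_labels(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if positive_class not in (GOOD, BAD):
        raise ValidationError(f"positive_class must be good/bad, got {positive_class!r}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionMatrix(tp=int(np.sum(pos_t & pos_p)),
                           fn=int(np.sum(pos_t & ~pos_p)),
                           fp=int(np.sum(~pos_t & pos_p)),
                           tn=int(np.sum(~pos_t & ~pos_p)),
                           positive_class=positive_class)


def metrics(cm: ConfusionMatrix, auc_value: float | None = None,
            threshold: float = 0.5) -> EvalReport:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    Zero-denominator ratios are reported as 0 and flagged in ``degenerate``
    rather than returned as NaN.
    """
    if cm.n == 0:
        raise ValidationError("cannot compute metrics on an empty sample")
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.n
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return EvalReport(accuracy=accuracy, precision=precision, recall=recall,
                      f1=f1, auc=auc_value, positive_class=cm.positive_class,
                      threshold=threshold, confusion=cm,
                      degenerate=tuple(degenerate))


def auc(y_true, scores, positive_class: str = GOOD) -> float:
    """Rank-based (Mann–Whitney) AUC; ties counted 1/2.

    1.0 when every positive is scored above every negative, 0.0 when every
    prediction is inverted, 0.5 for uninformative scores.
    """
    y_true = _check_labels(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if len(y_true) != len(scores):
        raise ValidationError(
            f"length mismatch: {len(y_true)} labels vs {len(scores)} scores")
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(scores)                     # average ranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def report_from_scores(y_true, scores, threshold: float = 0.5,
                       positive_class: str = GOOD) -> EvalReport:
    """Full report from good-probability scores: threshold, count, rank."""
    y_true = _check_labels(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pred = np.where(scores >= threshold, GOOD, BAD)
    cm = confusion(y_true, pred, positive_class)
    s = scores if positive_class == GOOD else 1.0 - scores
    try:
        a = auc(y_true, s, positive_class)
    except ValidationError:
        a = None
    return metrics(cm, auc_value=a, threshold=threshold)


def dual_report(y_true, scores, threshold: float = 0.5) -> dict[str, EvalReport]:
    """The same predictions scored under both positive-class conventions."""
    return {GOOD: report_from_scores(y_true, scores, threshold, GOOD),
            BAD: report_from_scores(y_true, scores, threshold, BAD)}
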