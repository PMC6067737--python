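"""Binary-classification metrics, ROC/AUC, and cross-fold aggregation.

Positive labels are +1, negative -1; grey-area calls (0) are excluded
from the confusion counts and surfaced as a separate coverage fraction —
a metric over abstentions would silently mix calibration and accuracy.
Metrics with a zero denominator are reported as ``None`` (undefined),
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import ValidationError


@dataclass(frozen=True)
class MetricSet:
    tp: int
    fp: int
    tn: int
    fn: int
    coverage: float  # fraction of calls that were not grey-area abstentions
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    negative_precision: float | None
    f1_positive: float | None
    f1_negative: float | None
    auc: float | None = None


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den else None


def _f1(p: float | None, r: float | None) -> float | None:
    if p is None or r is None or (p + r) == 0:
        return None
    return 2 * p * r / (p + r)


def confusion_metrics(truth: Sequence[int], pred: Sequence[int]) -> MetricSet:
    """Standard confusion-matrix metrics over +1/-1 labels.

    ``pred`` entries equal to 0 (unknown) are dropped from the counts;
    their share is reported via ``coverage``.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.size == 0 or truth.shape != pred.shape:
        raise ValidationError("truth and pred must be equal-length and non-empty")
    if not set(np.unique(truth).tolist()) <= {-1, 1}:
        raise ValidationError("truth labels must be +1/-1")
    if not set(np.unique(pred).tolist()) <= {-1, 0, 1}:
        raise ValidationError("predictions must be +1/-1/0(unknown)")
    known = pred != 0
    coverage = float(known.mean())
    t, p = truth[known], pred[known]
    tp = int(((t == 1) & (p == 1)).sum())
    fp = int(((t == -1) & (p == 1)).sum())
    tn = int(((t == -1) & (p == -1)).sum())
    fn = int(((t == 1) & (p == -1)).sum())
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    negative_precision = _safe_div(tn, tn + fn)
    return MetricSet(
        tp=tp, fp=fp, tn=tn, fn=fn, coverage=coverage,
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn),
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        negative_precision=negative_precision,
        f1_positive=_f1(precision, sensitivity),
        f1_negative=_f1(negative_precision, specificity),
    )


def roc_auc(truth: Sequence[int], scores: Sequence[float]):
    """ROC curve (threshold sweep) and trapezoid AUC.

    Ties in ``scores`` are handled by the midrank convention (equal scores
    share one threshold point), so all-equal scores give AUC = 0.5.
    Raises on single-class truth.
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape or truth.size == 0:
        raise ValidationError("truth and scores must be equal-length and non-empty")
    if len(set(np.unique(truth).tolist())) < 2:
        raise ValidationError("ROC needs at least one example of each class")
    fpr, tpr, _ = _roc_curve(truth, scores, pos_label=1)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def evaluate_folds(per_fold: Sequence[MetricSet]) -> dict:
    """Per-metric mean and standard deviation across folds.

    Undefined (None) fold metrics are skipped; a single defined fold gives
    sd = None (undefined, reported as such).  The per-fold table is kept.
    """
    if not per_fold:
        raise ValidationError("need at least one fold")
    metric_names = (
        "accuracy", "precision", "sensitivity", "specificity",
        "negative_precision", "f1_positive", "f1_negative", "auc", "coverage",
    )
    summary: dict = {"folds": list(per_fold), "mean": {}, "sd": {}}
    for name in metric_names:
        values = [getattr(m, name) for m in per_fold if getattr(m, name) is not None]
        summary["mean"][name] = float(np.mean(values)) if values else None
        summary["sd"][name] = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return summary
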