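"""Confusion counts, the five binary-classification metrics, and CV utilities.

AF is the positive class throughout the package.  Metrics with a zero
denominator are reported as NaN and flagged by name in the report rather
than silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

POSITIVE_LABEL = "AF"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts with AF as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Precision, recall (sensitivity), specificity, accuracy and F1.

    ``undefined`` names any metric whose denominator was zero; such metrics
    hold NaN.
    """

    precision: float
    recall: float
    specificity: float
    accuracy: float
    f1: float
    counts: ConfusionCounts
    undefined: tuple[str, ...] = field(default=())

    def rounded(self, ndigits: int = 4) -> dict:
        """Display form matching the 4-decimal convention of result tables."""
        out = {}
        for name in ("f1", "precision", "recall", "specificity", "accuracy"):
            v = getattr(self, name)
            out[name] = round(v, ndigits) if math.isfinite(v) else None
        return out


def _as_labels(x: Sequence) -> np.ndarray:
    arr = np.asarray(x)
    return arr


def confusion(labels: Sequence, predictions: Sequence, positive=POSITIVE_LABEL) -> ConfusionCounts:
    """Tally the confusion counts of predictions against reference labels.

    ``labels`` and ``predictions`` may be strings ("AF"/"NSR") or any other
    binary coding; ``positive`` names the positive class (default AF).
    """
    y = _as_labels(labels)
    p = _as_labels(predictions)
    if y.shape != p.shape:
        raise ValueError(f"labels and predictions differ in length: {y.shape} vs {p.shape}")
    pos_y = y == positive
    pos_p = p == positive
    tp = int(np.sum(pos_y & pos_p))
    fp = int(np.sum(~pos_y & pos_p))
    fn = int(np.sum(pos_y & ~pos_p))
    tn = int(np.sum(~pos_y & ~pos_p))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute precision, recall, specificity, accuracy and F1 from counts.

    F1 is the harmonic mean 2*P*R/(P+R).  Any metric whose denominator is
    zero is NaN and listed in ``undefined``.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    accuracy = _ratio(tp + tn, counts.total)
    if math.isfinite(precision) and math.isfinite(recall) and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    elif math.isfinite(precision) and math.isfinite(recall):
        f1 = math.nan  # P + R == 0
    else:
        f1 = math.nan
    undefined = tuple(
        name
        for name, v in (
            ("precision", precision),
            ("recall", recall),
            ("specificity", specificity),
            ("accuracy", accuracy),
            ("f1", f1),
        )
        if not math.isfinite(v)
    )
    return MetricsReport(
        precision=precision,
        recall=recall,
        specificity=specificity,
        accuracy=accuracy,
        f1=f1,
        counts=counts,
        undefined=undefined,
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic-mean F1 from already-computed precision and recall."""
    if precision + recall <= 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


def balanced_accuracy_from_rates(recall: float, specificity: float) -> float:
    """Accuracy under a balanced (50% prevalence) test design.

    With equal class counts, accuracy = prevalence*recall +
    (1-prevalence)*specificity reduces to the plain mean of the two rates.
    """
    return 0.5 * (recall + specificity)


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Record-disjoint stratified fold index pairs, deterministic per seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y = np.asarray(labels)
    return [(tr, te) for tr, te in skf.split(np.zeros_like(y), y)]


def crossval(
    dataset: tuple[np.ndarray, np.ndarray],
    model_factory: Callable[[], object],
    k: int = 5,
    seed: int = 0,
) -> list[MetricsReport]:
    """k-fold stratified cross-validation over a (X, y) dataset.

    Each sample corresponds to one source record, so stratified folds are
    automatically record-disjoint (inter-patient).  ``model_factory`` must
    return a fresh estimator with ``fit(X, y)`` and ``predict(X)``.
    """
    X, y = dataset
    y = np.asarray(y)
    reports = []
    for tr, te in stratified_folds(y, k, seed):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a fold contains a single class; reduce k or add data")
        model = model_factory()
        model.fit(X[tr], y[tr])
        pred = np.asarray(model.predict(X[te]))
        reports.append(metrics(confusion(y[te], pred, positive=1)))
    return reports
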