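"""Confusion-matrix performance metrics and the selection-stability statistic.

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
GMean = sqrt(sensitivity * specificity), F1 = 2*PPV*sens/(PPV+sens),
accuracy, and Matthews correlation. Indeterminate 0/0 forms return 0, the
conservative convention. Multiclass tasks are scored one-vs-rest per class
and macro-averaged.

Stability between two selected subsets of sizes k_i, k_j with c features in
common, out of n, is the chance-corrected overlap

    S = (c - k_i*k_j/n) / (min(k_i, k_j) - max(0, k_i + k_j - n))

with range (-1, 1]; 0 is the expectation for subsets drawn uniformly at
random, positive values mean more consistent selection than chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "StabilityResult",
    "StabilityUndefinedError",
    "confusion_counts",
    "compute_metrics",
    "metric_from_labels",
    "pairwise_stability",
    "mean_stability",
    "METRIC_IDS",
]

METRIC_IDS = ("accuracy", "gmean", "f1", "mcc")


class StabilityUndefinedError(ValueError):
    """The stability denominator vanished (degenerate subset sizes)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    ppv: float
    gmean: float
    f1: float
    accuracy: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __getitem__(self, metric_id: str) -> float:
        return self.as_dict()[metric_id]


@dataclass
class StabilityResult:
    """Pairwise stability values per unordered fold pair, and their mean."""

    pairwise: dict[tuple[int, int], float]
    mean_stability: float


def confusion_counts(y_true, y_pred, positive: str) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=str)
    y_pred = np.asarray(y_pred, dtype=str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    alphabet = set(np.unique(y_true)) | set(np.unique(y_pred))
    if str(positive) not in alphabet:
        raise ValueError(f"positive symbol {positive!r} absent from labels")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero evaluated samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    gmean = math.sqrt(sens * spec)
    f1 = _ratio(2 * ppv * sens, ppv + sens)
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricSet(sens, spec, ppv, gmean, f1, acc, mcc)


def metric_from_labels(y_true, y_pred, metric_id: str,
                       positive: str | None = None) -> float:
    """Score predictions with one metric id; macro-averaged if multiclass.

    For binary tasks the positive class defaults to the lexicographically
    last symbol of the true-label alphabet.
    """
    if metric_id not in MetricSet.__dataclass_fields__:
        raise ValueError(f"unknown metric {metric_id!r}")
    y_true = np.asarray(y_true, dtype=str)
    symbols = sorted(np.unique(y_true).tolist())
    if len(symbols) <= 2:
        pos = str(positive) if positive is not None else symbols[-1]
        return compute_metrics(confusion_counts(y_true, y_pred, pos))[metric_id]
    vals = [compute_metrics(confusion_counts(y_true, y_pred, s))[metric_id]
            for s in symbols]
    return float(np.mean(vals))


def pairwise_stability(subset_a, subset_b, n: int) -> float:
    a, b = set(map(int, subset_a)), set(map(int, subset_b))
    for s in (a, b):
        if not s:
            raise ValueError("stability requires non-empty subsets")
        if not all(0 <= i < n for i in s):
            raise ValueError(f"subset indices must lie in [0, {n})")
    ki, kj, c = len(a), len(b), len(a & b)
    denom = min(ki, kj) - max(0, ki + kj - n)
    if denom == 0:
        raise StabilityUndefinedError(
            f"stability undefined for subset sizes {ki} and {kj} with n={n}"
        )
    return (c - ki * kj / n) / denom


def mean_stability(subsets, n: int) -> StabilityResult:
    subsets = list(subsets)
    if len(subsets) < 2:
        raise ValueError("need at least 2 subsets")
    pairwise: dict[tuple[int, int], float] = {}
    for i in range(len(subsets)):
        for j in range(i + 1, len(subsets)):
            try:
                pairwise[(i, j)] = pairwise_stability(subsets[i], subsets[j], n)
            except StabilityUndefinedError as exc:
                raise StabilityUndefinedError(
                    f"stability undefined for pair ({i}, {j}): {exc}"
                ) from None
    return StabilityResult(pairwise, float(np.mean(list(pairwise.values()))))
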