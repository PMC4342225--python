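"""Assessment harness: nested cross-validation, hybrid filter->wrapper
selection, reduction percentages, performance-per-feature ratios, and the
ranking-points comparison scheme.

Nested CV evaluates the *whole* selection procedure: in each outer fold
the feature-selection method sees only the outer-training rows (the
wrapper's internal Performance signal comes from an inner k-fold split of
those rows), the classifier is refit on the outer-training rows with the
selected mask, and metrics are computed on the untouched outer-test rows.
Selection stability is then measured across the outer folds' selected
sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata

from .classifiers import PerformanceRequest, evaluate_performance
from .data import Dataset, stratified_kfold
from .filters import rank_features, select_top_fraction
from .ga import GAConfig, run_ga
from .metrics import (MetricSet, StabilityResult, StabilityUndefinedError,
                      mean_stability)

__all__ = [
    "FoldOutcome",
    "CVResult",
    "RankingTable",
    "nested_cv",
    "hybrid_select",
    "reduction_percentage",
    "performance_per_feature",
    "rank_methods",
    "all_features_method",
    "filter_method",
    "ga_method",
    "hybrid_method",
]

# a feature-selection procedure: (training data, request, seed) -> indices
FSMethod = Callable[[Dataset, PerformanceRequest, int], list[int]]


@dataclass
class FoldOutcome:
    fold: int
    selected: list[int]
    metrics: MetricSet


@dataclass
class CVResult:
    """Per-outer-fold selections and test metrics, with aggregates."""

    folds: list[FoldOutcome]
    mean_metrics: dict[str, float]
    sd_metrics: dict[str, float]
    stability: StabilityResult
    mean_reduction_pct: float
    n_features: int

    def summary(self) -> str:
        lines = [f"{'metric':<12}{'mean':>8}{'sd':>8}"]
        for name, mean in self.mean_metrics.items():
            lines.append(f"{name:<12}{mean:>8.3f}{self.sd_metrics[name]:>8.3f}")
        lines.append(f"{'stability':<12}{self.stability.mean_stability:>8.3f}")
        lines.append(f"{'reduction%':<12}{self.mean_reduction_pct:>8.2f}")
        sizes = [len(f.selected) for f in self.folds]
        lines.append(f"{'n_selected':<12}{np.mean(sizes):>8.1f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "folds": [{"fold": f.fold, "selected": f.selected,
                       "metrics": f.metrics.as_dict()} for f in self.folds],
            "mean_metrics": self.mean_metrics,
            "sd_metrics": self.sd_metrics,
            "mean_stability": self.stability.mean_stability,
            "mean_reduction_pct": self.mean_reduction_pct,
            "n_features": self.n_features,
        }


@dataclass
class RankingTable:
    """Rank points per method per comparison cell, plus summed final ranks."""

    points: dict[str, dict[tuple, float]]
    totals: dict[str, float] = field(default_factory=dict)
    final_rank: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{'method':<20}{'points':>8}{'rank':>6}"]
        for method in sorted(self.totals, key=lambda m: self.final_rank[m]):
            lines.append(f"{method:<20}{self.totals[method]:>8.1f}"
                         f"{self.final_rank[method]:>6}")
        return "\n".join(lines)


def nested_cv(
    dataset: Dataset,
    method: FSMethod,
    k_outer: int = 5,
    k_inner: int = 5,
    request: PerformanceRequest | None = None,
    seed: int = 0,
    audit: list | None = None,
) -> CVResult:
    """Nested k-fold cross-validation of a feature-selection procedure.

    ``audit``, if given, collects per-fold dicts with the sample indices
    the FS method was shown and the outer-test indices, for leakage
    checks.
    """
    request = request or PerformanceRequest()
    folds = stratified_kfold(dataset, k_outer, seed)
    outcomes: list[FoldOutcome] = []
    selected_sets: list[list[int]] = []
    for f in range(k_outer):
        train_idx = folds.train_indices(f)
        test_idx = folds.test_indices(f)
        train = dataset.take(train_idx)
        test = dataset.take(test_idx)
        fold_seed = (seed * 31 + 1000 * (f + 1)) % (2 ** 31)
        selected = sorted(int(i) for i in method(train, request, fold_seed))
        if audit is not None:
            audit.append({"fold": f,
                          "fs_visible": set(map(int, train_idx)),
                          "outer_test": set(map(int, test_idx))})
        metrics = _fold_metrics(train, test, selected, request)
        outcomes.append(FoldOutcome(f, selected, metrics))
        selected_sets.append(selected)
    metric_names = list(outcomes[0].metrics.as_dict())
    mean_metrics = {m: float(np.mean([o.metrics[m] for o in outcomes]))
                    for m in metric_names}
    sd_metrics = {m: float(np.std([o.metrics[m] for o in outcomes], ddof=1))
                  for m in metric_names}
    try:
        stability = mean_stability(selected_sets, dataset.n_features)
    except StabilityUndefinedError:
        # e.g. every fold selected the full feature set: overlap carries
        # no information, reported as NaN rather than a hard failure
        stability = StabilityResult({}, float("nan"))
    reduction = float(np.mean([
        reduction_percentage(s, dataset.n_features) for s in selected_sets]))
    return CVResult(outcomes, mean_metrics, sd_metrics, stability,
                    reduction, dataset.n_features)


def _fold_metrics(train: Dataset, test: Dataset, selected: list[int],
                  request: PerformanceRequest) -> MetricSet:
    """Refit on the full outer-training rows and score the outer test."""
    from .classifiers import knn_predict, nbc_fit, nbc_predict
    from .metrics import compute_metrics, confusion_counts

    idx = np.asarray(selected, dtype=int)
    preds = {}
    if request.classifier_id in ("nbc", "both"):
        model = nbc_fit(train, idx)
        preds["nbc"] = nbc_predict(model, test, idx)
    if request.classifier_id in ("knn", "both"):
        preds["knn"] = knn_predict(train, test, idx, request.knn)
    sets = []
    for pred in preds.values():
        symbols = sorted(np.unique(test.labels).tolist())
        if len(symbols) <= 2:
            pos = request.positive or sorted(np.unique(train.labels))[-1]
            sets.append(compute_metrics(confusion_counts(test.labels, pred, pos)))
        else:
            per_class = [compute_metrics(confusion_counts(test.labels, pred, s))
                         for s in symbols]
            sets.append(MetricSet(*[
                float(np.mean([m[name] for m in per_class]))
                for name in MetricSet.__dataclass_fields__]))
    if len(sets) == 1:
        return sets[0]
    return MetricSet(*[0.5 * (sets[0][name] + sets[1][name])
                       for name in MetricSet.__dataclass_fields__])


def hybrid_select(dataset: Dataset, criterion: str, fraction: float,
                  ga_config: GAConfig, request: PerformanceRequest,
                  n_bins: int = 10, k_inner: int = 5) -> list[int]:
    """Two-phase selection: filter ranking, keep the top fraction, then GA.

    Returned indices refer to the original feature space.
    """
    n_keep = max(1, math.ceil(fraction * dataset.n_features))
    ranking = rank_features(dataset, criterion, n_select=n_keep, n_bins=n_bins)
    candidates = select_top_fraction(ranking, fraction, dataset.n_features)
    _, history = run_ga(dataset, ga_config, request,
                        candidate_features=candidates, inner_k=k_inner)
    return history.selected_indices


def reduction_percentage(selected, n: int) -> float:
    """Selected features as a percentage of all features."""
    sel = set(map(int, selected))
    if not all(0 <= i < n for i in sel):
        raise ValueError(f"selected indices must lie in [0, {n})")
    return 100.0 * len(sel) / n


def performance_per_feature(metric_value: float, selected_count: int) -> float:
    """Classification performance divided by the number of selected features."""
    if selected_count < 1:
        raise ValueError("selected_count must be >= 1")
    return metric_value / selected_count


def rank_methods(results: dict) -> RankingTable:
    """Ranking-points comparison of methods over a grid of comparison cells.

    ``results[method][cell] = metric value`` where ``cell`` identifies one
    (dataset, metric, ...) combination; every method must cover every
    cell. Within a cell the best value earns 1 point, the second best 2,
    and so on; ties share the mean of their ranks. Methods are finally
    ranked by ascending point totals.
    """
    methods = sorted(results)
    if not methods:
        raise ValueError("no methods to rank")
    cells = sorted({c for m in methods for c in results[m]})
    for m in methods:
        for c in cells:
            if c not in results[m]:
                raise ValueError(f"missing cell {c!r} for method {m!r}")
    points: dict[str, dict[tuple, float]] = {m: {} for m in methods}
    for c in cells:
        values = np.array([results[m][c] for m in methods], dtype=float)
        ranks = rankdata(-values, method="average")  # best value -> rank 1
        for m, r in zip(methods, ranks):
            points[m][c] = float(r)
    totals = {m: float(sum(points[m].values())) for m in methods}
    order = sorted(methods, key=lambda m: (totals[m], m))
    final_rank = {m: i + 1 for i, m in enumerate(order)}
    return RankingTable(points, totals, final_rank)


# ---------------------------------------------------------------- methods

def all_features_method() -> FSMethod:
    def method(train: Dataset, request: PerformanceRequest, seed: int):
        return list(range(train.n_features))
    return method


def filter_method(criterion: str, fraction: float = 0.10,
                  n_bins: int = 10) -> FSMethod:
    def method(train: Dataset, request: PerformanceRequest, seed: int):
        n_keep = max(1, math.ceil(fraction * train.n_features))
        ranking = rank_features(train, criterion, n_select=n_keep, n_bins=n_bins)
        return select_top_fraction(ranking, fraction, train.n_features)
    return method


def ga_method(config: GAConfig, k_inner: int = 5) -> FSMethod:
    def method(train: Dataset, request: PerformanceRequest, seed: int):
        cfg = GAConfig(**{**config.__dict__, "seed": seed})
        _, history = run_ga(train, cfg, request, inner_k=k_inner)
        return history.selected_indices
    return method


def hybrid_method(criterion: str, fraction: float, config: GAConfig,
                  n_bins: int = 10, k_inner: int = 5) -> FSMethod:
    def method(train: Dataset, request: PerformanceRequest, seed: int):
        cfg = GAConfig(**{**config.__dict__, "seed": seed})
        return hybrid_select(train, criterion, fraction, cfg, request,
                             n_bins=n_bins, k_inner=k_inner)
    return method
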