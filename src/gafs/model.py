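"""Model/Results facade over the selection machinery.

:class:`FeatureSelection` is constructed from data plus the search
configuration; :meth:`FeatureSelection.fit` runs the (optionally
filter-preceded) GA wrapper and returns a
:class:`FeatureSelectionResults` carrying the selected features, the
generation history, and a ``summary()`` table. ``cross_validate`` wraps
the nested-CV assessment of the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .classifiers import KNNConfig, PerformanceRequest
from .data import Dataset
from .evaluation import (CVResult, ga_method, hybrid_method, nested_cv,
                         reduction_percentage)
from .ga import GAConfig, GAHistory, run_ga

__all__ = ["FeatureSelection", "FeatureSelectionResults"]


class FeatureSelection:
    """GA-wrapper feature selection over a labelled dataset.

    Parameters
    ----------
    dataset : Dataset
        Samples x features matrix with class labels.
    classifier : {"nbc", "knn", "both"}
        Wrapped classifier whose cross-validated metric drives the search.
    metric : {"accuracy", "gmean", "f1", "mcc"}
        Performance metric inside the fitness function.
    filter_criterion : {"mrmr", "jmi", "cmim", "icap", "correlation"}, optional
        When given, a filter pre-selection keeps ``filter_fraction`` of the
        features before the GA phase (hybrid mode).
    config : GAConfig, optional
        Search-strategy parameters (population 100, crossover 0.8,
        mutation 0.01, alpha 0.15, 100 generations, patience 50).

    Examples
    --------
    >>> from gafs.synthetic import make_informative_dataset
    >>> data, truth = make_informative_dataset(200, 3, n_noise=7, seed=1)
    >>> res = FeatureSelection(data, config=GAConfig(max_generations=20,
    ...                                              stagnation_patience=20)).fit()
    >>> sorted(res.selected_indices) == res.selected_indices
    True
    """

    def __init__(self, dataset: Dataset, classifier: str = "nbc",
                 metric: str = "gmean", filter_criterion: str | None = None,
                 filter_fraction: float = 0.10, n_bins: int = 10,
                 knn: KNNConfig | None = None, positive: str | None = None,
                 config: GAConfig | None = None, k_inner: int = 5):
        self.dataset = dataset
        self.request = PerformanceRequest(classifier, metric,
                                          knn=knn or KNNConfig(),
                                          positive=positive)
        self.filter_criterion = filter_criterion
        self.filter_fraction = filter_fraction
        self.n_bins = n_bins
        self.config = config or GAConfig()
        self.k_inner = k_inner

    @classmethod
    def from_dataframe(cls, frame, label_column: str | None = None, **kwargs
                       ) -> "FeatureSelection":
        """Build from a pandas DataFrame; the label column defaults to the last."""
        import pandas as pd  # deferred: only needed on this path

        if not isinstance(frame, pd.DataFrame):
            raise TypeError("from_dataframe expects a pandas DataFrame")
        label_column = label_column or frame.columns[-1]
        features = frame.drop(columns=[label_column])
        dataset = Dataset(features.to_numpy(dtype=float),
                          frame[label_column].astype(str).to_numpy(),
                          [str(c) for c in features.columns])
        return cls(dataset, **kwargs)

    def fit(self, seed: int | None = None) -> "FeatureSelectionResults":
        """Run the search; ``seed`` overrides the config seed."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        candidates = None
        if self.filter_criterion is not None:
            import math

            from .filters import rank_features, select_top_fraction
            n_keep = max(1, math.ceil(self.filter_fraction
                                      * self.dataset.n_features))
            ranking = rank_features(self.dataset, self.filter_criterion,
                                    n_select=n_keep, n_bins=self.n_bins)
            candidates = select_top_fraction(ranking, self.filter_fraction,
                                             self.dataset.n_features)
        _, history = run_ga(self.dataset, config, self.request,
                            candidate_features=candidates, inner_k=self.k_inner)
        return FeatureSelectionResults(self, history.selected_indices,
                                       history, config)

    def cross_validate(self, k_outer: int = 5, seed: int = 0) -> CVResult:
        """Nested-CV assessment of this configuration."""
        if self.filter_criterion is None:
            method = ga_method(self.config, k_inner=self.k_inner)
        else:
            method = hybrid_method(self.filter_criterion, self.filter_fraction,
                                   self.config, n_bins=self.n_bins,
                                   k_inner=self.k_inner)
        return nested_cv(self.dataset, method, k_outer=k_outer,
                         k_inner=self.k_inner, request=self.request, seed=seed)


@dataclass
class FeatureSelectionResults:
    """Outcome of one fitted search."""

    model: FeatureSelection
    selected_indices: list[int]
    history: GAHistory | None
    config: GAConfig

    @property
    def selected_names(self) -> list[str]:
        names = self.model.dataset.feature_names
        return [names[i] for i in self.selected_indices]

    @property
    def reduction_pct(self) -> float:
        return reduction_percentage(self.selected_indices,
                                    self.model.dataset.n_features)

    @property
    def best_fitness(self) -> float | None:
        if self.history is None or not self.history.generations:
            return None
        return self.history.generations[-1]["best_fitness"]

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Feature selection results",
            "=" * 41,
            f"samples / features     {ds.n_samples} / {ds.n_features}",
            f"classifier / metric    {self.model.request.classifier_id} / "
            f"{self.model.request.metric_id}",
            f"filter                 "
            f"{self.model.filter_criterion or 'none'}",
            f"selected features      {len(self.selected_indices)}"
            f"  ({self.reduction_pct:.2f}% of all)",
        ]
        if self.best_fitness is not None:
            lines.append(f"best fitness           {self.best_fitness:.4f}")
            lines.append(f"generations / stop     "
                         f"{self.history.n_generations} / "
                         f"{self.history.stop_reason}")
        lines.append("-" * 41)
        for i in self.selected_indices:
            lines.append(f"  [{i:>4}] {ds.feature_names[i]}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "selected_indices": list(map(int, self.selected_indices)),
            "selected_names": self.selected_names,
            "reduction_pct": self.reduction_pct,
            "classifier": self.model.request.classifier_id,
            "metric": self.model.request.metric_id,
            "filter": self.model.filter_criterion,
            "seed": self.config.seed,
            "best_fitness": self.best_fitness,
        }
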