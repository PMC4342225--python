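"""Wrapped classifiers: in-house Gaussian naive Bayes and k-nearest-neighbors.

Both classifiers expose one evaluation contract,
:func:`evaluate_performance`, which the GA fitness calls: fit on a training
set restricted to the masked features, predict an evaluation set, score
with the requested metric. ``classifier_id="both"`` averages the NBC and
KNN metric values.

:class:`InnerCVEvaluator` computes the wrapper's internal Performance
signal by stratified k-fold cross-validation of the training portion. For
the NBC it precomputes per-fold, per-feature log-density tables so that a
mask evaluation reduces to a masked sum — a semantics-preserving shortcut
whose agreement with the plain path is enforced by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, stratified_kfold
from .metrics import METRIC_IDS, metric_from_labels

__all__ = [
    "NBCModel",
    "KNNConfig",
    "PerformanceRequest",
    "nbc_fit",
    "nbc_predict",
    "nbc_posterior",
    "knn_predict",
    "evaluate_performance",
    "mask_to_indices",
    "InnerCVEvaluator",
    "CLASSIFIER_IDS",
]

CLASSIFIER_IDS = ("nbc", "knn", "both")

_LOG_2PI = math.log(2.0 * math.pi)


def mask_to_indices(mask, n: int) -> np.ndarray:
    """Normalise a feature mask (bit vector of length n, or index list)."""
    arr = np.asarray(mask)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("feature mask must be a non-empty 1-d array")
    # bool/uint8 vectors are always bit masks; other 0/1 vectors of length
    # n are bit masks only when n > 2 (index lists over features {0, 1}
    # can otherwise collide with them)
    is_bitmask = arr.dtype == bool or arr.dtype == np.uint8 or (
        arr.size == n and n > 2 and np.isin(arr, (0, 1)).all())
    if is_bitmask:
        if arr.size != n:
            raise ValueError(f"bit mask length {arr.size} != n_features {n}")
        idx = np.flatnonzero(arr.astype(bool))
    else:
        idx = np.unique(arr.astype(int))
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError(f"feature indices must lie in [0, {n})")
    if idx.size == 0:
        raise ValueError("feature mask selects no features")
    return idx


@dataclass
class NBCModel:
    """Gaussian naive Bayes: per-class priors and per-feature moments."""

    classes: list[str]
    log_priors: np.ndarray           # (n_classes,)
    means: np.ndarray                # (n_classes, n_selected)
    variances: np.ndarray            # (n_classes, n_selected), floored
    feature_indices: np.ndarray      # selected original-space indices

    def __post_init__(self) -> None:
        if not np.all(self.variances > 0):
            raise ValueError("variances must be strictly positive")
        if abs(float(np.exp(self.log_priors).sum()) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")


@dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    distance: str = "euclidean"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.distance != "euclidean":
            raise ValueError(f"unsupported distance {self.distance!r}")


@dataclass
class PerformanceRequest:
    """What the fitness function should measure: classifier, metric, mask."""

    classifier_id: str = "nbc"
    metric_id: str = "gmean"
    feature_mask: np.ndarray | None = None
    knn: KNNConfig = field(default_factory=KNNConfig)
    positive: str | None = None

    def __post_init__(self) -> None:
        if self.classifier_id not in CLASSIFIER_IDS:
            raise ValueError(
                f"unknown classifier {self.classifier_id!r}; "
                f"choose from {CLASSIFIER_IDS}")
        if self.metric_id not in METRIC_IDS:
            raise ValueError(
                f"unknown metric {self.metric_id!r}; choose from {METRIC_IDS}")


def _variance_floor(train_values: np.ndarray) -> np.ndarray:
    # per-feature floor tied to the global scale so constant features
    # degrade to flat densities instead of infinities
    global_var = train_values.var(axis=0)
    return 1e-9 * (global_var + 1.0)


def nbc_fit(train: Dataset, mask) -> NBCModel:
    idx = mask_to_indices(mask, train.n_features)
    classes = train.class_symbols
    X = train.values[:, idx]
    floor = _variance_floor(train.values)[idx]
    means = np.empty((len(classes), idx.size))
    variances = np.empty_like(means)
    priors = np.empty(len(classes))
    for c, symbol in enumerate(classes):
        rows = train.labels == symbol
        if not rows.any():
            raise ValueError(f"class {symbol!r} absent from training data")
        Xc = X[rows]
        means[c] = Xc.mean(axis=0)
        variances[c] = np.maximum(Xc.var(axis=0), floor)
        priors[c] = rows.mean()
    return NBCModel(classes, np.log(priors), means, variances, idx)


def _nbc_log_joint(model: NBCModel, test: Dataset, mask) -> np.ndarray:
    idx = mask_to_indices(mask, test.n_features)
    if not np.array_equal(idx, model.feature_indices):
        raise ValueError("prediction mask differs from the mask used at fit")
    X = test.values[:, idx]                      # (n, m)
    diff = X[:, None, :] - model.means[None, :, :]
    log_dens = -0.5 * (_LOG_2PI + np.log(model.variances)[None, :, :]
                       + diff ** 2 / model.variances[None, :, :])
    return model.log_priors[None, :] + log_dens.sum(axis=2)   # (n, n_classes)


def nbc_predict(model: NBCModel, test: Dataset, mask) -> np.ndarray:
    """Argmax class per test row; ties go to the lexicographically first class."""
    log_joint = _nbc_log_joint(model, test, mask)
    pick = log_joint.argmax(axis=1)   # classes sorted => first max wins ties
    return np.asarray(model.classes, dtype=str)[pick]


def nbc_posterior(model: NBCModel, test: Dataset, mask) -> np.ndarray:
    """Class posterior probabilities per test row (rows sum to 1)."""
    log_joint = _nbc_log_joint(model, test, mask)
    log_joint -= log_joint.max(axis=1, keepdims=True)
    p = np.exp(log_joint)
    return p / p.sum(axis=1, keepdims=True)


def knn_predict(train: Dataset, test: Dataset, mask,
                config: KNNConfig | None = None) -> np.ndarray:
    """Majority vote among the k nearest training points (Euclidean).

    Distance ties break toward the lower training index; vote ties toward
    the lexicographically first class symbol. Features are standardized
    with training-set mean and standard deviation unless disabled.
    """
    config = config or KNNConfig()
    if config.k > train.n_samples:
        raise ValueError(f"k={config.k} exceeds training size {train.n_samples}")
    idx = mask_to_indices(mask, train.n_features)
    Xtr = train.values[:, idx].copy()
    Xte = test.values[:, idx].copy()
    if config.standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0.0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    classes = train.class_symbols
    label_codes = np.searchsorted(classes, train.labels)
    d2 = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=2)
    # stable sort: equal distances keep training-index order
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :config.k]
    votes = label_codes[nearest]                        # (n_test, k)
    counts = np.zeros((votes.shape[0], len(classes)), dtype=int)
    for c in range(len(classes)):
        counts[:, c] = (votes == c).sum(axis=1)
    pick = counts.argmax(axis=1)   # first max => lexicographically first class
    return np.asarray(classes, dtype=str)[pick]


def _single_classifier_score(classifier_id: str, train: Dataset, eval_ds: Dataset,
                             idx: np.ndarray, request: PerformanceRequest) -> float:
    if classifier_id == "nbc":
        model = nbc_fit(train, idx)
        pred = nbc_predict(model, eval_ds, idx)
    else:
        pred = knn_predict(train, eval_ds, idx, request.knn)
    return metric_from_labels(eval_ds.labels, pred, request.metric_id,
                              positive=request.positive)


def evaluate_performance(train: Dataset, eval_ds: Dataset,
                         request: PerformanceRequest, mask=None) -> float:
    """Fit the requested classifier(s) on masked features and score ``eval_ds``.

    The mask may be passed explicitly or carried in the request.
    """
    if mask is None:
        mask = request.feature_mask
    if mask is None:
        raise ValueError("no feature mask supplied")
    idx = mask_to_indices(mask, train.n_features)
    for symbol in np.unique(eval_ds.labels):
        if symbol not in train.class_symbols:
            raise ValueError(f"class {symbol!r} absent from training data")
    if request.classifier_id == "both":
        a = _single_classifier_score("nbc", train, eval_ds, idx, request)
        b = _single_classifier_score("knn", train, eval_ds, idx, request)
        return 0.5 * (a + b)
    return _single_classifier_score(request.classifier_id, train, eval_ds,
                                    idx, request)


class InnerCVEvaluator:
    """Mean k-fold cross-validated metric as a function of a feature mask.

    The fold assignment is fixed at construction (derived from the seed,
    never from scheduling), so the evaluator is a pure function of the
    mask — the property the parallel GA's determinism rests on.
    """

    def __init__(self, train: Dataset, request: PerformanceRequest,
                 k: int = 5, seed: int = 0):
        self.train = train
        self.request = request
        self.k = k
        self.folds = stratified_kfold(train, k, seed)
        self._fast_nbc = request.classifier_id == "nbc"
        if self._fast_nbc:
            self._precompute_nbc()

    def _precompute_nbc(self) -> None:
        classes = self.train.class_symbols
        self._fold_tables = []
        for f in range(self.k):
            tr = self.train.take(self.folds.train_indices(f))
            te = self.train.take(self.folds.test_indices(f))
            floor = _variance_floor(tr.values)
            n_feat = tr.n_features
            log_dens = np.empty((te.n_samples, len(classes), n_feat))
            log_priors = np.empty(len(classes))
            for c, symbol in enumerate(classes):
                rows = tr.labels == symbol
                mu = tr.values[rows].mean(axis=0)
                var = np.maximum(tr.values[rows].var(axis=0), floor)
                log_priors[c] = math.log(rows.mean())
                diff = te.values - mu[None, :]
                log_dens[:, c, :] = -0.5 * (_LOG_2PI + np.log(var)[None, :]
                                            + diff ** 2 / var[None, :])
            self._fold_tables.append(
                (log_dens, log_priors, np.asarray(classes, dtype=str), te.labels))

    def __call__(self, mask) -> float:
        idx = mask_to_indices(mask, self.train.n_features)
        scores = []
        if self._fast_nbc:
            for log_dens, log_priors, classes, y_true in self._fold_tables:
                log_joint = log_dens[:, :, idx].sum(axis=2) + log_priors[None, :]
                pred = classes[log_joint.argmax(axis=1)]
                scores.append(metric_from_labels(
                    y_true, pred, self.request.metric_id,
                    positive=self.request.positive))
        else:
            for f in range(self.k):
                tr = self.train.take(self.folds.train_indices(f))
                te = self.train.take(self.folds.test_indices(f))
                scores.append(evaluate_performance(tr, te, self.request, idx))
        return float(np.mean(scores))
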