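"""Information-theoretic filter pre-selection.

Mutual information is estimated with the plug-in (maximum-likelihood)
estimator on discrete codes, log base 2; continuous features are first
discretized into equal-frequency bins (default 10). Greedy forward
selection then ranks features under one of the classical criteria —
mRMR, JMI, CMIM, ICAP — or a simple class-correlation baseline. With S
the already-selected set and X_k a candidate, the scores are

    mRMR:  I(X_k;Y) - (1/|S|) * sum_{j in S} I(X_k;X_j)
    JMI:   sum_{j in S} I(X_k,X_j;Y)
    CMIM:  min_{j in S} I(X_k;Y | X_j)
    ICAP:  I(X_k;Y) - sum_{j in S} max(0, I(X_k;X_j) - I(X_k;X_j|Y))

The first pick always maximizes I(X_k;Y); ties break toward the lowest
feature index, so rankings are deterministic and independent of sample
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import Dataset

__all__ = [
    "DiscretizedFeature",
    "FilterRanking",
    "discretize_equal_frequency",
    "encode_labels",
    "mutual_information",
    "conditional_mutual_information",
    "joint_codes",
    "rank_features",
    "correlation_ranking",
    "select_top_fraction",
    "CRITERIA",
]

CRITERIA = ("mrmr", "jmi", "cmim", "icap", "correlation")


@dataclass
class DiscretizedFeature:
    """Integer-coded feature: one symbol in [0, n_bins) per sample."""

    codes: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.n_bins):
            raise ValueError("codes must lie in [0, n_bins)")


@dataclass
class FilterRanking:
    """Greedy ranking: feature indices best-first with selection-time scores."""

    criterion: str
    order: list[int]
    scores: list[float]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranking order contains duplicate feature indices")
        if len(self.order) != len(self.scores):
            raise ValueError("order and scores must have equal length")

    def to_records(self) -> list[dict]:
        recs = []
        for rank, (idx, score) in enumerate(zip(self.order, self.scores), start=1):
            rec = {"rank": rank, "index": int(idx), "score": float(score)}
            if self.feature_names is not None:
                rec["name"] = self.feature_names[idx]
            recs.append(rec)
        return recs


def discretize_equal_frequency(values, n_bins: int) -> DiscretizedFeature:
    """Equal-frequency (quantile) binning of a real vector.

    Bin occupancies differ by at most one except under ties, which always
    land in a single bin. Integer-coded inputs with at most ``n_bins``
    distinct values pass through unchanged (recoded to 0..k-1 by value
    order), so already-discrete data is never re-binned.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    uniq = np.unique(values)
    if uniq.size <= n_bins and np.all(uniq == np.round(uniq)):
        codes = np.searchsorted(uniq, values)
        return DiscretizedFeature(codes, max(1, uniq.size))
    if n_bins == 1 or uniq.size == 1:
        return DiscretizedFeature(np.zeros(values.size, dtype=np.int64), 1)
    n = values.size
    order = np.argsort(values, kind="stable")
    provisional = (np.arange(n) * n_bins) // n  # bin by rank position
    sorted_vals = values[order]
    # ties must share one bin: give every member of a tie group the bin of
    # the group's first (lowest-rank) element
    group_start = np.zeros(n, dtype=np.int64)
    new_group = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    group_start[new_group] = new_group
    np.maximum.accumulate(group_start, out=group_start)
    binned = provisional[group_start]
    codes = np.empty(n, dtype=np.int64)
    codes[order] = binned
    # compact unused bin ids (possible when large tie groups swallow bins)
    used = np.unique(codes)
    codes = np.searchsorted(used, codes)
    return DiscretizedFeature(codes, used.size)


def encode_labels(labels) -> DiscretizedFeature:
    """Map class symbols to integer codes by sorted symbol order."""
    labels = np.asarray(labels, dtype=str)
    symbols, codes = np.unique(labels, return_inverse=True)
    return DiscretizedFeature(codes.astype(np.int64), symbols.size)


def _codes(x) -> tuple[np.ndarray, int]:
    if isinstance(x, DiscretizedFeature):
        return x.codes, x.n_bins
    arr = np.asarray(x)
    if arr.dtype.kind in "US":
        d = encode_labels(arr)
        return d.codes, d.n_bins
    arr = arr.astype(np.int64)
    return arr, int(arr.max()) + 1 if arr.size else 1


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) in bits from the joint table."""
    xc, xb = _codes(x)
    yc, yb = _codes(y)
    if xc.size != yc.size:
        raise ValueError(f"length mismatch: {xc.size} vs {yc.size}")
    joint = np.bincount(xc * yb + yc, minlength=xb * yb).astype(float)
    hx = _entropy_from_counts(np.bincount(xc, minlength=xb).astype(float))
    hy = _entropy_from_counts(np.bincount(yc, minlength=yb).astype(float))
    hxy = _entropy_from_counts(joint)
    return max(0.0, hx + hy - hxy)


def joint_codes(x, z) -> DiscretizedFeature:
    """Code pair (X,Z) as a single discrete variable."""
    xc, xb = _codes(x)
    zc, zb = _codes(z)
    if xc.size != zc.size:
        raise ValueError(f"length mismatch: {xc.size} vs {zc.size}")
    return DiscretizedFeature(xc * zb + zc, xb * zb)


def conditional_mutual_information(x, y, z) -> float:
    """Plug-in conditional MI I(X;Y|Z) = sum_z p(z) I(X;Y | Z=z), in bits."""
    xc, _ = _codes(x)
    yc, _ = _codes(y)
    zc, zb = _codes(z)
    if not (xc.size == yc.size == zc.size):
        raise ValueError("length mismatch between x, y, z")
    n = xc.size
    total = 0.0
    for zv in range(zb):
        sel = zc == zv
        nz = int(sel.sum())
        if nz == 0:
            continue
        total += (nz / n) * mutual_information(xc[sel], yc[sel])
    return max(0.0, total)


def _discretize_dataset(dataset: Dataset, n_bins: int) -> list[DiscretizedFeature]:
    return [discretize_equal_frequency(dataset.values[:, j], n_bins)
            for j in range(dataset.n_features)]


def rank_features(dataset: Dataset, criterion: str, n_select: int | None = None,
                  n_bins: int = 10) -> FilterRanking:
    """Greedy forward feature ranking under an information-theoretic criterion.

    Parameters
    ----------
    criterion : {"mrmr", "jmi", "cmim", "icap", "correlation"}
        "correlation" dispatches to :func:`correlation_ranking`.
    n_select : int, optional
        Number of features to rank; defaults to all.
    n_bins : int
        Equal-frequency bins for continuous features.
    """
    n = dataset.n_features
    if n_select is None:
        n_select = n
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must lie in [1, {n}], got {n_select}")
    if criterion == "correlation":
        return correlation_ranking(dataset, n_select)
    if criterion not in ("mrmr", "jmi", "cmim", "icap"):
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")

    feats = _discretize_dataset(dataset, n_bins)
    y = encode_labels(dataset.labels)
    relevance = np.array([mutual_information(f, y) for f in feats])

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(n))
    # accumulators over the already-selected set, updated incrementally
    red_sum = np.zeros(n)       # sum_j I(Xk;Xj)            (mrmr)
    jmi_sum = np.zeros(n)       # sum_j I(Xk,Xj;Y)          (jmi)
    cmim_min = np.full(n, np.inf)  # min_j I(Xk;Y|Xj)       (cmim)
    icap_sum = np.zeros(n)      # sum_j max(0, I;I|Y gap)   (icap)

    while len(selected) < n_select:
        if not selected:
            crit = relevance.copy()
        elif criterion == "mrmr":
            crit = relevance - red_sum / len(selected)
        elif criterion == "jmi":
            crit = jmi_sum.copy()
        elif criterion == "cmim":
            crit = cmim_min.copy()
        else:  # icap
            crit = relevance - icap_sum
        best = min(remaining, key=lambda k: (-crit[k], k))
        selected.append(best)
        scores.append(float(crit[best]))
        remaining.remove(best)
        if len(selected) == n_select:
            break
        fj = feats[best]
        for k in remaining:
            fk = feats[k]
            if criterion == "mrmr":
                red_sum[k] += mutual_information(fk, fj)
            elif criterion == "jmi":
                jmi_sum[k] += mutual_information(joint_codes(fk, fj), y)
            elif criterion == "cmim":
                cmim_min[k] = min(cmim_min[k],
                                  conditional_mutual_information(fk, y, fj))
            else:
                gap = (mutual_information(fk, fj)
                       - conditional_mutual_information(fk, fj, y))
                icap_sum[k] += max(0.0, gap)
    return FilterRanking(criterion, selected, scores, list(dataset.feature_names))


def correlation_ranking(dataset: Dataset, n_select: int | None = None
                        ) -> FilterRanking:
    """Rank by absolute Pearson correlation with the class encoding.

    Binary tasks use the point-biserial correlation (0/1 class encoding);
    multiclass tasks take the maximum over one-vs-rest encodings.
    Zero-variance features score 0.
    """
    n = dataset.n_features
    if n_select is None:
        n_select = n
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must lie in [1, {n}], got {n_select}")
    symbols = dataset.class_symbols
    encodings = [symbols[-1:]] if len(symbols) == 2 else [[s] for s in symbols]
    X = dataset.values
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    best = np.zeros(n)
    for pos in encodings:
        yv = np.isin(dataset.labels, pos).astype(float)
        yc = yv - yv.mean()
        sy = math.sqrt(float((yc ** 2).sum()))
        if sy == 0.0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(Xc.T @ yc) / (sx * sy)
        r[sx == 0.0] = 0.0
        best = np.maximum(best, r)
    order = sorted(range(n), key=lambda k: (-best[k], k))[:n_select]
    return FilterRanking("correlation", order, [float(best[k]) for k in order],
                         list(dataset.feature_names))


def select_top_fraction(ranking: FilterRanking, fraction: float, n_total: int
                        ) -> list[int]:
    """Keep the top ceil(fraction * n_total) ranked features (at least 1)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    m = max(1, math.ceil(fraction * n_total))
    return list(ranking.order[:m])
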