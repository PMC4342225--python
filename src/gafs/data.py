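"""Tab-delimited dataset I/O and stratified splitting.

The table dialect is the one the selection tool consumes: rows are samples,
columns are features, and the last column holds the class label. A header
row is optional; it is recognised when any non-label field of the first
line fails numeric parsing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dataset",
    "FoldAssignment",
    "FormatError",
    "ValidationError",
    "StratificationError",
    "read_table",
    "write_table",
    "stratified_kfold",
    "split_train_test",
]


class FormatError(ValueError):
    """A structural problem in an input table (ragged rows, bad cells)."""


class ValidationError(ValueError):
    """Data that parses but violates a dataset invariant."""


class StratificationError(ValueError):
    """A requested split cannot preserve per-class representation."""


@dataclass
class Dataset:
    """A rectangular samples x features matrix with one class label per row.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix.
    labels : ndarray of str, shape (n_samples,)
        Class symbol per sample. Labels are opaque strings; at least two
        distinct symbols are required.
    feature_names : list of str, optional
        One name per feature; defaults to ``f1..fn``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-d samples x features matrix")
        self.labels = np.asarray(self.labels, dtype=str)
        if self.labels.shape != (self.values.shape[0],):
            raise ValidationError(
                f"labels length {self.labels.shape} does not match "
                f"{self.values.shape[0]} samples"
            )
        if self.values.shape[1] < 1:
            raise ValidationError("dataset needs at least one feature")
        if self.feature_names is None:
            self.feature_names = [f"f{i + 1}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValidationError("feature_names length does not match n_features")
        symbols = np.unique(self.labels)
        if symbols.size < 2:
            raise ValidationError(
                f"dataset must contain at least 2 classes, found {symbols.size}"
            )
        if self.values.shape[0] < symbols.size:
            raise ValidationError("fewer samples than classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_symbols(self) -> list[str]:
        return sorted(np.unique(self.labels).tolist())

    def take(self, row_indices) -> "Dataset":
        """Row subset as a new Dataset (feature space unchanged)."""
        idx = np.asarray(row_indices, dtype=int)
        return Dataset(self.values[idx], self.labels[idx], list(self.feature_names))


@dataclass
class FoldAssignment:
    """Stratified fold index per sample for k-fold cross-validation."""

    fold_index: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.fold_index = np.asarray(self.fold_index, dtype=int)
        if not ((self.fold_index >= 0) & (self.fold_index < self.k)).all():
            raise ValidationError("fold indices must lie in [0, k)")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def _parse_cell(cell: str, line_no: int, col_no: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise FormatError(
            f"non-numeric feature value {cell!r} at line {line_no}, column {col_no}"
        ) from None


def _is_numeric(cell: str) -> bool:
    try:
        v = float(cell)
    except ValueError:
        return False
    return math.isfinite(v)


def read_table(path, delimiter: str = "\t") -> Dataset:
    """Read a delimited table where the last column is the class label.

    A first row whose non-label fields are not all numeric is treated as a
    header supplying feature names. Missing values are not supported.
    """
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        raw = [(i + 1, line.rstrip("\r\n")) for i, line in enumerate(fh)]
    rows = [(no, line.split(delimiter)) for no, line in raw if line.strip() != ""]
    if not rows:
        raise FormatError(f"{path}: empty table")
    width = len(rows[0][1])
    if width < 2:
        raise FormatError(
            f"{path}: line {rows[0][0]} has {width} field(s); need >= 2 "
            "(features plus a label column)"
        )
    for no, fields in rows:
        if len(fields) != width:
            raise FormatError(
                f"{path}: ragged row at line {no}: expected {width} fields, "
                f"found {len(fields)}"
            )

    first_no, first = rows[0]
    header = not all(_is_numeric(c) for c in first[:-1])
    if header:
        feature_names = [c.strip() for c in first[:-1]]
        body = rows[1:]
        if not body:
            raise FormatError(f"{path}: header but no data rows")
    else:
        feature_names = [f"f{i + 1}" for i in range(width - 1)]
        body = rows

    values = np.empty((len(body), width - 1), dtype=float)
    labels = []
    for r, (no, fields) in enumerate(body):
        for c, cell in enumerate(fields[:-1]):
            values[r, c] = _parse_cell(cell, no, c + 1)
        labels.append(fields[-1].strip())
    return Dataset(values, np.asarray(labels, dtype=str), feature_names)


def _format_value(v: float) -> str:
    # repr round-trips doubles exactly; integers print without exponent noise
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_table(dataset: Dataset, path, delimiter: str = "\t",
                header: bool = True) -> None:
    """Write a Dataset in the tab-delimited last-column-label dialect."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write(delimiter.join([*dataset.feature_names, "class"]) + "\n")
        for row, label in zip(dataset.values, dataset.labels):
            fh.write(delimiter.join(_format_value(v) for v in row))
            fh.write(delimiter + str(label) + "\n")


def stratified_kfold(dataset: Dataset, k: int, seed: int) -> FoldAssignment:
    """Assign samples to k folds, balancing every class across folds.

    Per-class fold occupancies differ by at most one; assignment is a
    deterministic function of the seed.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    fold_index = np.empty(dataset.n_samples, dtype=int)
    offset = 0
    for symbol in dataset.class_symbols:
        idx = np.flatnonzero(dataset.labels == symbol)
        if idx.size < k:
            raise StratificationError(
                f"class {symbol!r} has {idx.size} samples, fewer than k={k}"
            )
        perm = rng.permutation(idx)
        # rotate the starting fold between classes so remainder samples do
        # not all pile into fold 0
        fold_index[perm] = (np.arange(perm.size) + offset) % k
        offset += perm.size % k
    return FoldAssignment(fold_index, k)


def split_train_test(dataset: Dataset, test_fraction: float, seed: int
                     ) -> tuple[Dataset, Dataset]:
    """Stratified one-shot split into train and test parts."""
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    test_rows: list[np.ndarray] = []
    train_rows: list[np.ndarray] = []
    for symbol in dataset.class_symbols:
        idx = np.flatnonzero(dataset.labels == symbol)
        n_test = int(round(test_fraction * idx.size))
        if n_test < 1 or n_test >= idx.size:
            raise ValidationError(
                f"test_fraction {test_fraction} leaves class {symbol!r} empty "
                "on one side of the split"
            )
        perm = rng.permutation(idx)
        test_rows.append(perm[:n_test])
        train_rows.append(perm[n_test:])
    train_idx = np.sort(np.concatenate(train_rows))
    test_idx = np.sort(np.concatenate(test_rows))
    return dataset.take(train_idx), dataset.take(test_idx)
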