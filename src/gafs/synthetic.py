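"""Synthetic labelled datasets with known ground-truth feature relevance.

Every generator returns a :class:`~gafs.data.Dataset` together with a
:class:`GroundTruth` that records which features are informative, which are
redundant copies of informative ones, and which are pure noise — so
filters, classifiers, and the GA wrapper can be validated without external
benchmark downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, ValidationError

__all__ = [
    "GroundTruth",
    "make_informative_dataset",
    "make_binary_dataset",
    "make_xor_dataset",
]

_NEG, _POS = "neg", "pos"


@dataclass
class GroundTruth:
    """Which features carry class signal in a generated dataset."""

    informative_indices: set[int]
    redundant_map: dict[int, int] = field(default_factory=dict)
    noise_indices: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.informative_indices = set(int(i) for i in self.informative_indices)
        self.redundant_map = {int(k): int(v) for k, v in self.redundant_map.items()}
        self.noise_indices = set(int(i) for i in self.noise_indices)
        if not self.informative_indices:
            raise ValidationError("informative feature set must be non-empty")
        groups = [self.informative_indices, set(self.redundant_map), self.noise_indices]
        total = set().union(*groups)
        if sum(len(g) for g in groups) != len(total):
            raise ValidationError("feature groups must be disjoint")

    @property
    def n_features(self) -> int:
        return (len(self.informative_indices) + len(self.redundant_map)
                + len(self.noise_indices))

    def to_json(self) -> str:
        return json.dumps({
            "informative_indices": sorted(self.informative_indices),
            "redundant_map": {str(k): v for k, v in sorted(self.redundant_map.items())},
            "noise_indices": sorted(self.noise_indices),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            set(obj["informative_indices"]),
            {int(k): v for k, v in obj["redundant_map"].items()},
            set(obj["noise_indices"]),
        )


def _balanced_labels(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.array([_NEG, _POS])[np.arange(n_samples) % 2]
    rng.shuffle(labels)
    return labels


def _scatter_columns(blocks: list[np.ndarray], roles: list[str],
                     rng: np.random.Generator,
                     sources: list[int | None]) -> tuple[np.ndarray, GroundTruth]:
    """Stack feature blocks, shuffle column order, build the GroundTruth."""
    matrix = np.column_stack(blocks)
    n = matrix.shape[1]
    perm = rng.permutation(n)
    matrix = matrix[:, perm]
    position = np.empty(n, dtype=int)   # original block column -> final column
    position[perm] = np.arange(n)
    informative, noise, redundant = set(), set(), {}
    for orig, (role, src) in enumerate(zip(roles, sources)):
        where = int(position[orig])
        if role == "informative":
            informative.add(where)
        elif role == "noise":
            noise.add(where)
        else:
            redundant[where] = int(position[src])
    return matrix, GroundTruth(informative, redundant, noise)


def make_informative_dataset(
    n_samples: int,
    n_informative: int,
    n_redundant: int = 0,
    n_noise: int = 0,
    class_sep: float = 1.0,
    flip_prob: float = 0.0,
    seed: int = 0,
) -> tuple[Dataset, GroundTruth]:
    """Gaussian two-class dataset with informative / redundant / noise features.

    Each informative feature j carries a class-mean shift of magnitude
    ``class_sep`` with a random sign (class centres at ±class_sep/2 along a
    random ±1 direction), plus unit-variance Gaussian noise. Redundant
    features are scaled noisy copies of a randomly chosen informative
    source. Noise features are label-independent standard normals. Labels
    are flipped independently with probability ``flip_prob`` after the
    features are drawn.
    """
    if n_samples < 1 or n_informative < 1:
        raise ValidationError("need at least one sample and one informative feature")
    if min(n_redundant, n_noise) < 0 or not 0.0 <= flip_prob <= 1.0:
        raise ValidationError("counts must be >= 0 and flip_prob in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = _balanced_labels(n_samples, rng)
    y = (labels == _POS).astype(float)  # 0/1

    signs = rng.choice([-1.0, 1.0], size=n_informative)
    shift = (y[:, None] - 0.5) * class_sep * signs[None, :]
    informative = shift + rng.standard_normal((n_samples, n_informative))

    blocks = [informative]
    roles = ["informative"] * n_informative
    sources: list[int | None] = [None] * n_informative
    if n_redundant:
        src = rng.integers(0, n_informative, size=n_redundant)
        scale = rng.uniform(0.5, 2.0, size=n_redundant) * rng.choice(
            [-1.0, 1.0], size=n_redundant)
        red = informative[:, src] * scale + 0.1 * rng.standard_normal(
            (n_samples, n_redundant))
        blocks.append(red)
        roles += ["redundant"] * n_redundant
        sources += [int(s) for s in src]
    if n_noise:
        blocks.append(rng.standard_normal((n_samples, n_noise)))
        roles += ["noise"] * n_noise
        sources += [None] * n_noise

    matrix, truth = _scatter_columns(blocks, roles, rng, sources)
    flips = rng.random(n_samples) < flip_prob
    flipped = labels.copy()
    flipped[flips] = np.where(labels[flips] == _POS, _NEG, _POS)
    if np.unique(flipped).size < 2:  # pathological flip outcome at tiny n
        flipped[0] = _NEG if flipped[0] == _POS else _POS
    return Dataset(matrix, flipped), truth


def make_binary_dataset(
    n_samples: int,
    n_informative: int,
    n_noise: int = 0,
    feature_flip: float = 0.1,
    seed: int = 0,
) -> tuple[Dataset, GroundTruth]:
    """0/1-valued dataset for exact-MI oracle checks.

    Informative bits equal the class bit corrupted independently with
    probability ``feature_flip`` (a binary symmetric channel); noise bits
    are fair coins. Exact mutual information of each feature with the label
    follows in closed form, which makes this fixture the reference for the
    discretization-free estimation path.
    """
    if n_samples < 2 or n_informative < 1 or n_noise < 0:
        raise ValidationError("need n_samples >= 2, n_informative >= 1, n_noise >= 0")
    rng = np.random.default_rng(seed)
    labels = _balanced_labels(n_samples, rng)
    y = (labels == _POS).astype(int)
    informative = np.where(
        rng.random((n_samples, n_informative)) < feature_flip,
        1 - y[:, None], y[:, None]).astype(float)
    blocks = [informative]
    roles = ["informative"] * n_informative
    sources: list[int | None] = [None] * n_informative
    if n_noise:
        blocks.append(rng.integers(0, 2, size=(n_samples, n_noise)).astype(float))
        roles += ["noise"] * n_noise
        sources += [None] * n_noise
    matrix, truth = _scatter_columns(blocks, roles, rng, sources)
    return Dataset(matrix, labels), truth


def make_xor_dataset(n_samples: int, n_noise: int = 0, seed: int = 0
                     ) -> tuple[Dataset, GroundTruth]:
    """Two continuous features whose sign product (XOR) sets the label.

    Each informative feature is marginally independent of the label, so any
    univariate ranking scores it like noise, but the pair determines the
    class — the canonical fixture where a subset-evaluating wrapper beats
    single-feature filters.
    """
    if n_samples < 8:
        raise ValidationError("need n_samples >= 8")
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n_samples)
    x2 = rng.standard_normal(n_samples)
    x1[x1 == 0.0] = 1e-12
    x2[x2 == 0.0] = 1e-12
    labels = np.where(x1 * x2 > 0, _POS, _NEG).astype(str)
    blocks = [np.column_stack([x1, x2])]
    roles = ["informative", "informative"]
    sources: list[int | None] = [None, None]
    if n_noise:
        blocks.append(rng.standard_normal((n_samples, n_noise)))
        roles += ["noise"] * n_noise
        sources += [None] * n_noise
    matrix, truth = _scatter_columns(blocks, roles, rng, sources)
    return Dataset(matrix, labels), truth
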