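import numpy as np
import pytest

from gafs.data import Dataset
from gafs.synthetic import make_informative_dataset, make_xor_dataset


@pytest.fixture
def separable_dataset():
    """Widely separated two-class Gaussian clusters: any sane classifier is perfect."""
    ds, truth = make_informative_dataset(120, 3, n_noise=2, class_sep=8.0,
                                         flip_prob=0.0, seed=7)
    return ds, truth


@pytest.fixture
def xor_dataset():
    ds, truth = make_xor_dataset(240, n_noise=6, seed=11)
    return ds, truth


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(5)
    values = rng.standard_normal((40, 6))
    labels = np.array(["a", "b"] * 20)
    values[:, 0] += np.where(labels == "b", 3.0, -3.0)
    return Dataset(values, labels)


def write_tsv(path, rows, header=None):
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
    return path
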