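import numpy as np
import pandas as pd
import pytest

from gbmselect.gdsc_io import ResponseMatrix, pivot_mean
from gbmselect.synthetic_data import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted dataset shared by read/pivot/selection tests."""
    spec = SyntheticSpec(
        n_cell_lines=150,
        n_drugs=30,
        n_informative=3,
        positive_fraction=0.12,
        effect_size=2.0,
        block_size=5,
        block_rho=0.5,
        missing_rate_range=(0.05, 0.25),
        replicate_rate=0.05,
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return pivot_mean(small_dataset.records, "AUC")


@pytest.fixture(scope="session")
def small_imputed(small_matrix):
    from gbmselect.imputation import iterative_impute

    return iterative_impute(small_matrix)


def make_matrix(values, labels, metric="AUC", drugs=None, cells=None) -> ResponseMatrix:
    """Build a ResponseMatrix from a plain array, for hand-rolled cases."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ResponseMatrix(
        metric=metric,
        cell_lines=cells or [f"CL_{i:03d}" for i in range(n)],
        drugs=drugs or [f"DRUG_{j:03d}" for j in range(p)],
        values=values,
        labels=np.asarray(labels, dtype=int),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def frame(values, names=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    names = names or [f"D{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, columns=names)
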