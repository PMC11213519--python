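import numpy as np
import pandas as pd
import pytest

from cesfw import ActivityMatrix, CountsMatrix


def binary_activity(V: np.ndarray) -> ActivityMatrix:
    """Wrap a 0/1 cells x genes array as an already-normalised activity
    matrix (binary minority data is a fixed point of the normalisation)."""
    genes = [f"g{i:03d}" for i in range(V.shape[1])]
    cells = [f"c{i:03d}" for i in range(V.shape[0])]
    return ActivityMatrix(
        values=pd.DataFrame(V.astype(float), index=cells, columns=genes),
        flip_flags=pd.Series(False, index=genes),
        scale_factors=pd.Series(1.0, index=genes),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def binary_fixture_50(rng):
    """50-gene sparse binary matrix, every gene expressed somewhere,
    minority-oriented by construction."""
    V = (rng.random((60, 50)) < 0.3).astype(float)
    V[:, V.sum(axis=0) == 0] = 0
    V = V[:, V.sum(axis=0) > 0]
    return binary_activity(V)


@pytest.fixture
def small_counts(rng):
    """Integer counts with two planted co-expression modules plus noise
    genes, two datasets, embryo/state metadata."""
    n = 120
    states = np.repeat(["A", "B", "C"], n // 3)
    cols = {}
    for mod, state in (("m1", "A"), ("m2", "B")):
        active = states == state
        for g in range(6):
            mu = np.where(active, 8.0, 0.1)
            cols[f"{mod}_g{g}"] = rng.poisson(mu)
    for g in range(12):
        cols[f"noise_{g}"] = rng.poisson(1.0, size=n)
    values = pd.DataFrame(cols, index=[f"cell{i:03d}" for i in range(n)]).astype(float)
    meta = pd.DataFrame(
        {
            "dataset_label": np.where(np.arange(n) % 2 == 0, "dsA", "dsB"),
            "embryo_id": [f"e{i % 8}" for i in range(n)],
            "state_label": states,
        },
        index=values.index,
    )
    return CountsMatrix(values, meta)
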