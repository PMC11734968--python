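"""Shared fixtures: small planted models and datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from mgmnet import (
    MixedDataset,
    VariableSpec,
    make_planted_model,
    sample_mgm,
)


@pytest.fixture(scope="session")
def two_block_model():
    """Two 3-node continuous blocks (partial 0.45) — loading 1, no attenuation."""
    return make_planted_model(
        n_continuous=6,
        categorical_specs=[],
        community_sizes=[3, 3],
        within_weight=0.45,
        between_weight=0.0,
        n_isolated=0,
        seed=7,
    )


@pytest.fixture(scope="session")
def two_block_data(two_block_model):
    return sample_mgm(two_block_model, n=2000, seed=11)


@pytest.fixture
def tiny_mixed():
    """3 rows, one continuous + one binary categorical column."""
    specs = (
        VariableSpec("x", "continuous"),
        VariableSpec("g", "categorical", levels=("a", "b")),
    )
    table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "g": ["a", "b", "a"]})
    return MixedDataset(values=table, specs=specs)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
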