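import warnings

import numpy as np
import pandas as pd
import pytest

import coexkit as ck


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by read-only tests."""
    cfg = ck.SimulationConfig(seed=7, n_genes=1200, n_tissue_specific=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, annotation, traits, truth = ck.simulate_expression(cfg)
    return cfg, counts, annotation, traits, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_counts(rng, n_genes=20, n_samples=5):
    values = pd.DataFrame(
        rng.integers(0, 500, size=(n_genes, n_samples)),
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ck.ExpressionMatrix(values, "raw_counts")
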