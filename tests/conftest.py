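import numpy as np
import pandas as pd
import pytest

import nohelp as nh


@pytest.fixture(scope="session")
def small_reference():
    """500-gene, 3 vs 3 reference with 10% DE — fast variant for unit tests."""
    config = nh.SimulationConfig(n_genes=500, seed=17)
    matrix, meta, truth = nh.simulate_reference(config)
    return matrix, meta, truth


@pytest.fixture(scope="session")
def default_reference():
    """The standard 2000-gene, 3 vs 3, 10% DE, phi=0.1 reference."""
    matrix, meta, truth = nh.simulate_reference(nh.SimulationConfig())
    return matrix, meta, truth


@pytest.fixture(scope="session")
def default_signature(default_reference):
    matrix, meta, _ = default_reference
    return nh.derive_signature(matrix, meta)


@pytest.fixture(scope="session")
def default_centroids(default_reference, default_signature):
    matrix, meta, _ = default_reference
    expr = nh.cpm(nh.remove_zero_genes(matrix))
    return nh.compute_centroids(expr, meta, default_signature)


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        {
            "s1": [10, 0, 5, 100],
            "s2": [20, 0, 4, 90],
            "s3": [15, 0, 6, 110],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return nh.CountMatrix(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
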