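import numpy as np
import pytest

import spanmf


def random_dataset(rng, n=30, p=12, coord_range=10.0):
    """Small random non-negative dataset with scattered coordinates."""
    coords = rng.uniform(0, coord_range, size=(n, 2))
    X = rng.gamma(2.0, 1.0, size=(n, p))
    return spanmf.SpatialDataset(X=X, coords=coords)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def grid_ds():
    """Deterministic 8x8 grid dataset with a smooth planted gene."""
    ds, truth = spanmf.make_layered_dataset(
        n_side=8, r_true=2, p=10, n_background=2, noise_sd=0.1, seed=42
    )
    return ds, truth


@pytest.fixture(scope="session")
def benchmark_runs():
    """Fitted models on the versioned planted benchmark, shared across tests.

    One full pipeline run per benchmark seed: generate, build graph, fit at
    r=10 / alpha=1 with derived defaults, n_cluster=6 for scoring.
    """
    runs = []
    for seed in spanmf.synthetic.BENCHMARK_SEEDS:
        ds, truth = spanmf.make_layered_dataset(seed=seed)
        g = spanmf.build_graph(ds)
        model = spanmf.fit(ds, g, spanmf.FactorParams(r=10, n_cluster=6, seed=seed))
        runs.append((ds, truth, g, model))
    return runs
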