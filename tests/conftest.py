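import numpy as np
import pytest

import menet as m
from menet.pipeline import preprocess_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale labelled cohort with the default planted group contrast."""
    cfg = m.SimulationConfig.desk_scale(n_me=10, n_ne=10, seed=1234)
    return m.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_blocks(small_cohort):
    """GFP-selected 1-s blocks of the small cohort."""
    return preprocess_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)


def random_connectivity(rng, n=16, band=m.DEFAULT_BANDS[0]):
    """A random valid PLV matrix (symmetric, unit diagonal, entries in [0,1])."""
    a = rng.uniform(0.0, 1.0, size=(n, n))
    vals = (a + a.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    ids = tuple(f"ch{k:03d}" for k in range(n))
    return m.ConnectivityMatrix(values=vals, node_ids=ids, band=band)


def random_network(rng, n, p, threshold=0.5):
    """A random Erdos-Renyi binary network."""
    a = (rng.uniform(size=(n, n)) < p).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    ids = tuple(f"n{k}" for k in range(n))
    return m.BinaryNetwork(adjacency=a, node_ids=ids, threshold=threshold)


def floyd_warshall(adj):
    """Brute-force all-pairs hop distances; the independent graph oracle."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d
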