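import numpy as np
import pandas as pd
import pytest

from kroncox import geoclust, kernels, simulate, spatialgraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_units():
    """Four units on a small square with 2-d attributes."""
    return [
        geoclust.SpatialUnit("a", (34.0, -118.0), 100.0, np.array([0.0, 0.0])),
        geoclust.SpatialUnit("b", (34.1, -118.0), 200.0, np.array([0.1, 0.0])),
        geoclust.SpatialUnit("c", (34.0, -117.9), 150.0, np.array([5.0, 5.0])),
        geoclust.SpatialUnit("d", (34.1, -117.9), 250.0, np.array([5.1, 5.0])),
    ]


@pytest.fixture
def chain_operator():
    """Spatial operator from a 4-cluster chain-graph precision."""
    theta = np.eye(4)
    for i, j in [(0, 1), (1, 2), (2, 3)]:
        theta[i, j] = theta[j, i] = -0.35
    est = spatialgraph.PrecisionEstimate(
        theta=theta, penalty=0.1, edge_set=frozenset({(0, 1), (1, 2), (2, 3)})
    )
    return spatialgraph.build_spatial_operator(est, q=0.75)


@pytest.fixture
def small_panel(chain_operator):
    """C=4, T=36 panel simulated from the separable latent model."""
    scen = simulate.SyntheticScenario(n_clusters=4, n_periods=36, seed=7)
    gram = kernels.time_gram(36, scen.kernel_truth)
    panel, truth = simulate.generate_latent_field_counts(scen, chain_operator, gram)
    return panel, truth, scen


def random_connected_graph(rng, n, p_edge=0.4):
    """Adjacency of a random connected graph (spanning tree + extra edges)."""
    A = np.zeros((n, n))
    perm = rng.permutation(n)
    for i in range(1, n):
        j = perm[rng.integers(0, i)]
        A[perm[i], j] = A[j, perm[i]] = 1
    extra = rng.random((n, n)) < p_edge
    extra = np.triu(extra, 1)
    A = np.maximum(A, extra + extra.T)
    np.fill_diagonal(A, 0)
    return A
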