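import numpy as np
import pytest

from neurograph import SimulationConfig, load_atlas, synthetic_atlas


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    return synthetic_atlas(20)


@pytest.fixture()
def small_config():
    """Fast cohort: 3+3 subjects, 20 regions, short runs."""
    return SimulationConfig(n_ad=3, n_nc=3, n_regions=20, T=60, seed=11)


def adjacency_from_edges(n, edges):
    A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        A[i, j] = A[j, i] = True
    return A


@pytest.fixture(scope="session")
def canonical_graphs():
    """Named small graphs with hand-computed metric values."""
    path3 = adjacency_from_edges(3, [(0, 1), (1, 2)])
    k3 = adjacency_from_edges(3, [(0, 1), (1, 2), (0, 2)])
    k4 = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
    k4_minus = k4.copy()
    k4_minus[0, 1] = k4_minus[1, 0] = False
    star5 = adjacency_from_edges(5, [(0, i) for i in range(1, 5)])
    c4 = adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
    wheel5 = adjacency_from_edges(
        5, [(0, i) for i in range(1, 5)] + [(1, 2), (2, 3), (3, 4), (4, 1)]
    )
    return {
        "path3": path3,
        "k3": k3,
        "k4": k4,
        "k4_minus_edge": k4_minus,
        "star5": star5,
        "c4": c4,
        "wheel5": wheel5,
    }
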