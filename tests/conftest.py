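import numpy as np
import pytest

from netclus import subdivide, weight_matrix
from netclus.synth import (make_grid_network, make_random_planar_network,
                           make_ring_network)


@pytest.fixture(scope="session")
def grid3():
    """3×3 lattice of unit squares (16 nodes, 24 edges)."""
    return make_grid_network(3, 3, 1.0)


@pytest.fixture(scope="session")
def grid100():
    """7×7 lattice with 100 m spacing — the analysis-scale fixture
    (112 edges of 100 m)."""
    return make_grid_network(7, 7, 100.0)


@pytest.fixture(scope="session")
def grid100_segments(grid100):
    return subdivide(grid100, 100.0, kind="segment")


@pytest.fixture(scope="session")
def grid100_W(grid100, grid100_segments):
    """Distance-band weight matrix at the 300 m default."""
    return weight_matrix(grid100_segments, grid100, mode="distance",
                         threshold_m=300.0)


@pytest.fixture(scope="session")
def ring2000():
    """Closed cycle of total length 2000 m (no dead ends)."""
    return make_ring_network(2000.0, n_arcs=100)


@pytest.fixture(scope="session")
def planar20():
    """Small random planar (Delaunay) network, ≤ 30 nodes."""
    return make_random_planar_network(20, extent=500.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
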