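import numpy as np
import pytest

from stgat.datatypes import make_spot_table
from stgat.simulate import SimConfig, simulate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim_sample():
    """A 6x6-grid synthetic sample reused across read-only tests."""
    return simulate_sample(SimConfig(grid=(6, 6), seed=7))


@pytest.fixture
def grid_spots():
    """A 3x3 pixel-coordinate spot grid."""
    ids, xs, ys = [], [], []
    for r in range(3):
        for c in range(3):
            ids.append(f"s{r}{c}")
            xs.append(200 + 50 * c)
            ys.append(200 + 50 * r)
    return make_spot_table(ids, xs, ys)


def random_adjacency(rng, g, p_edge=0.4):
    entries = (rng.random((g, g)) < p_edge).astype(np.uint8)
    np.fill_diagonal(entries, 0)
    from stgat.datatypes import AdjacencyMatrix

    return AdjacencyMatrix(entries=entries, threshold=0.5)
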