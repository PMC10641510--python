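import numpy as np
import pytest

from nirsnet.core import default_montage
from nirsnet.simcohort import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def montage20():
    return default_montage(20)


@pytest.fixture
def short_cfg():
    """Small, fast simulation config for unit tests."""
    return SimConfig(n_channels=20, duration_s=240.0, n_blocks=5)


def random_connected_weighted_graph(rng: np.random.Generator, n_nodes: int) -> np.ndarray:
    """Random connected weighted graph for oracle comparisons.

    A random spanning tree guarantees connectedness; extra edges are added
    with probability 0.4. Weights are uniform on (0.2, 1.0).
    """
    w = np.zeros((n_nodes, n_nodes))
    order = rng.permutation(n_nodes)
    for a, b in zip(order[:-1], order[1:]):
        w[a, b] = w[b, a] = rng.uniform(0.2, 1.0)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if w[i, j] == 0 and rng.random() < 0.4:
                w[i, j] = w[j, i] = rng.uniform(0.2, 1.0)
    return w
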