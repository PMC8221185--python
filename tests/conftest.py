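import numpy as np
import pytest

import dynmst


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """Plain-noise epochs: 6 trials, 4 channels, 1000 Hz, -200..800 ms."""
    data = rng.standard_normal((6, 4, 1000))
    return dynmst.EpochSet(
        data=data, sample_rate=1000.0, time_zero_index=200,
        channel_labels=["Fp1", "Fz", "Cz", "Oz"],
        condition=np.array(["a", "a", "a", "b", "b", "b"]),
        subject=np.repeat("S01", 6))


def path_tree(n, weight=0.5):
    """Spanning tree 0-1-2-...-(n-1) with equal edge weights."""
    return dynmst.SpanningTree(
        n_nodes=n, edges=[(i, i + 1, weight) for i in range(n - 1)])


def star_tree(n, center=0, weight=0.5):
    """Spanning tree with every node attached to ``center``."""
    return dynmst.SpanningTree(
        n_nodes=n,
        edges=[(center, j, weight) for j in range(n) if j != center])


@pytest.fixture
def tree_builders():
    return path_tree, star_tree
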