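import itertools

import numpy as np
import pytest

from sbmbench.graph import Graph, Partition
from sbmbench.state import BlockState


@pytest.fixture
def two_edges():
    """Two disjoint edges on four nodes: the standard toy example."""
    return Graph([(0, 1), (2, 3)], n_nodes=4)


@pytest.fixture
def two_edges_state(two_edges):
    return BlockState(two_edges, Partition([0, 0, 1, 1]))


def random_simple_graph(n_nodes: int, n_edges: int, seed: int) -> Graph:
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(n_nodes), 2))
    idx = rng.choice(len(pairs), size=n_edges, replace=False)
    return Graph([pairs[i] for i in idx], n_nodes=n_nodes, simple=True)


def random_state(graph: Graph, K: int, seed: int,
                 allow_empty: bool = False) -> BlockState:
    rng = np.random.default_rng(seed)
    while True:
        labels = rng.integers(0, K, size=graph.N)
        if allow_empty or len(np.unique(labels)) == K:
            return BlockState(graph, Partition(labels, K=K,
                                               allow_empty=allow_empty))
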