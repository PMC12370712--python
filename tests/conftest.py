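import numpy as np
import pytest

from hyperhealth import Hypergraph, clique_expand


def random_hypergraph(rng, n_max=12, e_max=12, density=0.4) -> Hypergraph:
    """Random small hypergraph with no empty edges and no isolated nodes."""
    n = int(rng.integers(3, n_max + 1))
    k = int(rng.integers(2, e_max + 1))
    B = (rng.random((n, k)) < density).astype(float)
    for y in range(k):
        if B[:, y].sum() == 0:
            B[int(rng.integers(n)), y] = 1.0
    for x in range(n):
        if B[x].sum() == 0:
            B[x, int(rng.integers(k))] = 1.0
    return Hypergraph(B, np.ones(k), tuple(f"n{i}" for i in range(n)))


def random_connected_hypergraph(rng, **kw) -> Hypergraph:
    from scipy.sparse.csgraph import connected_components

    while True:
        h = random_hypergraph(rng, **kw)
        nc, _ = connected_components(clique_expand(h).adjacency, directed=False)
        if nc == 1:
            return h


@pytest.fixture
def path_hypergraph() -> Hypergraph:
    """Two hyperedges {a,b}, {b,c} over three nodes."""
    B = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return Hypergraph(B, np.ones(2), ("a", "b", "c"))


@pytest.fixture
def pair_hypergraph() -> Hypergraph:
    """Single hyperedge over two nodes, unit weight."""
    return Hypergraph(np.ones((2, 1)), np.ones(1), ("a", "b"))
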