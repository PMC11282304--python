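import numpy as np
import pytest

from ierw.graph_core import Partition, WeightedGraph
from ierw.synthetic_benchmarks import PPParams, generate_pp


def make_graph(edges, weights=None, semantics="unweighted", nodes=None):
    """Small-graph helper: edges as (u, v) label pairs."""
    if nodes is None:
        nodes = []
        for u, v in edges:
            for x in (u, v):
                if x not in nodes:
                    nodes.append(x)
    idx = {n: i for i, n in enumerate(nodes)}
    e = np.array([[idx[u], idx[v]] for u, v in edges], dtype=np.int64)
    w = np.ones(len(edges)) if weights is None else np.asarray(weights, float)
    return WeightedGraph(tuple(str(n) for n in nodes), e, w, semantics)


@pytest.fixture
def triangle():
    return make_graph([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def two_cliques_bridge():
    """Two 5-cliques joined by a single bridge edge."""
    edges = []
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((base + i, base + j))
    edges.append((0, 5))
    return make_graph(edges)


@pytest.fixture
def small_pp():
    """150-node planted partition, 3 communities of 50, easy mixing."""
    return generate_pp(PPParams(N=150, m=50, mean_degree=20.0, mu=0.1, seed=7))


@pytest.fixture
def clique_ring():
    """Ring of 4 10-cliques, one link between consecutive cliques."""
    edges = []
    for c in range(4):
        base = 10 * c
        for i in range(10):
            for j in range(i + 1, 10):
                edges.append((base + i, base + j))
    for c in range(4):
        edges.append((10 * c, 10 * ((c + 1) % 4) + 5))
    g = make_graph(edges)
    truth = Partition({str(v): str(v // 10) for v in range(40)})
    return g, truth
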