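import itertools

import networkx as nx
import numpy as np
import pytest

from connstack.enhance import WeightedGraph
from connstack.tsio import RoiTimeSeries


# ---------------------------------------------------------------------------
# independent brute-force spanning-tree oracle (networkx for connectivity)

def enumerate_spanning_trees(g: WeightedGraph):
    """All spanning trees of g by exhaustive enumeration of edge subsets."""
    n = g.n_vertices
    trees = []
    for combo in itertools.combinations(g.edges, n - 1):
        h = nx.Graph()
        h.add_nodes_from(range(n))
        h.add_edges_from((i, j) for i, j, _ in combo)
        if nx.is_connected(h) and h.number_of_edges() == n - 1:
            trees.append(combo)
    return trees


def brute_force_tree(g: WeightedGraph, variant: str):
    """(total_weight, edge set) of the extremal spanning tree by enumeration."""
    trees = enumerate_spanning_trees(g)
    assert trees, "graph is disconnected"
    weights = [sum(w for _, _, w in t) for t in trees]
    pick = min if variant == "min" else max
    best = pick(range(len(trees)), key=lambda k: weights[k])
    return weights[best], {(i, j) for i, j, _ in trees[best]}


def random_connected_graph(rng, max_vertices: int = 6) -> WeightedGraph:
    """Random connected graph with distinct continuous weights."""
    n = int(rng.integers(2, max_vertices + 1))
    all_pairs = list(itertools.combinations(range(n), 2))
    # random spanning tree first so the graph is connected
    perm = rng.permutation(n)
    edges = {tuple(sorted((int(perm[k]), int(perm[int(rng.integers(0, k))]))))
             for k in range(1, n)}
    for pair in all_pairs:
        if rng.random() < 0.5:
            edges.add(pair)
    weights = rng.normal(size=len(edges))
    return WeightedGraph(
        n_vertices=n,
        edges=[(i, j, float(w)) for (i, j), w in zip(sorted(edges), weights)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """A well-behaved 40x6 time series."""
    return RoiTimeSeries("s0", "toy", rng.standard_normal((40, 6)))


def random_spd(rng, n: int, cond: float = 10.0) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    vals = np.exp(rng.uniform(0, np.log(cond), size=n))
    return (q * vals) @ q.T
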