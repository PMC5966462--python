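"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (double sums over all vertex or
community pairs) so that the optimised bookkeeping in the package can be
checked against a computation that shares no code with it.
"""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import settings

from votecomm import Partition, UndirectedGraph

# fully reproducible property tests: example generation derandomised
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def modularity_double_sum(graph: UndirectedGraph, partition: Partition) -> float:
    """Q via the per-vertex-pair double sum: (1/2m) Σ_uv [A_uv − k_u k_v / 2m] δ(c_u, c_v)."""
    m = graph.n_edges
    two_m = 2.0 * m
    total = 0.0
    for u in range(graph.n_vertices):
        for v in range(graph.n_vertices):
            if partition.membership[u] != partition.membership[v]:
                continue
            a_uv = 1.0 if graph.has_edge(u, v) else 0.0
            total += a_uv - graph.degree(u) * graph.degree(v) / two_m
    return total / two_m


def sim_brute(graph: UndirectedGraph, u: int, v: int) -> float:
    """Vertex similarity from raw set arithmetic."""
    nu, nv = graph.adjacency[u], graph.adjacency[v]
    denom = len((nu | nv) - {u, v})
    return len(nu & nv) / denom if denom else 0.0


def community_sim_brute(graph: UndirectedGraph, c_i, c_j) -> float:
    return sum(sim_brute(graph, u, v) for u in c_i for v in c_j)


def cc_brute(graph: UndirectedGraph, v: int) -> float:
    """Clustering coefficient by enumerating ordered neighbour pairs."""
    nbrs = graph.adjacency[v]
    d = len(nbrs)
    if d <= 1:
        return 0.0
    links = sum(1 for u, w in itertools.permutations(nbrs, 2) if graph.has_edge(u, w))
    return links / (d * (d - 1))


def random_graph(rng: random.Random, n: int, p: float) -> UndirectedGraph:
    """Erdős–Rényi graph on n labelled vertices (may be disconnected)."""
    edges = [(u, v) for u in range(n) for v in range(u + 1, n) if rng.random() < p]
    return UndirectedGraph.from_index_edges(n, edges)


def random_partition(rng: random.Random, n: int, k: int) -> Partition:
    """Random assignment of n vertices to at most k communities (all non-empty)."""
    membership = [rng.randrange(k) for _ in range(n)]
    return Partition.from_membership(membership)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def triangle() -> UndirectedGraph:
    return UndirectedGraph.from_index_edges(3, [(0, 1), (1, 2), (2, 0)])


@pytest.fixture
def star4() -> UndirectedGraph:
    """Star K1,4: centre 'c' with four leaves."""
    return UndirectedGraph.from_edge_labels(
        [("c", "l1"), ("c", "l2"), ("c", "l3"), ("c", "l4")])


@pytest.fixture
def k4() -> UndirectedGraph:
    return UndirectedGraph.from_index_edges(
        4, [(u, v) for u in range(4) for v in range(u + 1, 4)])


@pytest.fixture
def bridged_cliques() -> tuple[UndirectedGraph, Partition]:
    """Two 5-cliques joined by one bridge edge (vertices 4-5)."""
    from votecomm import ring_of_cliques
    return ring_of_cliques(2, 5)
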