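"""Synthetic benchmark networks with known ground truth.

Three generators, in decreasing order of realism:

* :func:`lfr_graph` — LFR-style benchmark: power-law degree and
  community-size distributions, a mixing parameter ``mu`` giving the
  expected fraction of each vertex's edges that leave its community.
  Construction follows the published LFR recipe: sample degrees from a
  truncated power law calibrated to the target mean, sample community sizes
  from a truncated power law summing to ``n``, assign vertices to
  communities under the capacity constraint (internal degree < community
  size), then wire internal and external stubs by random matching with
  repair sweeps.  Realised ``mu`` tracks the target closely (validated
  empirically in the test suite).
* :func:`planted_partition` — equal-sized blocks with independent
  intra/inter edge probabilities (delegates to networkx).
* :func:`ring_of_cliques` — fully deterministic hand-checkable fixture:
  cliques joined in a ring by single bridge edges.

All generators are seeded and byte-reproducible: identical spec + seed
gives an identical graph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graph import Partition, UndirectedGraph


class InfeasibleSpecError(ValueError):
    """The requested benchmark parameters cannot be realised."""


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of an LFR-style synthetic network.

    ``tau_degree`` and ``tau_size`` are the magnitudes of the power-law
    exponents (a stored value of 2 means density ∝ d^-2).
    """

    n: int = 1000
    avg_degree: float = 30.0
    max_degree: int = 50
    tau_degree: float = 2.0
    tau_size: float = 1.0
    mu: float = 0.5
    min_size: int = 30
    max_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise InfeasibleSpecError("mu must be in [0, 1]")
        if not self.min_size <= self.max_size <= self.n:
            raise InfeasibleSpecError("need min_size <= max_size <= n")
        if not self.avg_degree <= self.max_degree < self.n:
            raise InfeasibleSpecError("need avg_degree <= max_degree < n")

    def with_seed(self, seed: int) -> "BenchmarkSpec":
        return replace(self, seed=seed)


#: The two benchmark parameterisations used throughout: a 1000-vertex
#: network with fairly mixed communities and a sparser, more mixed
#: 5000-vertex one.
LFR_1000 = BenchmarkSpec(n=1000, avg_degree=30, max_degree=50, tau_degree=2,
                         tau_size=1, mu=0.5, min_size=30, max_size=100)
LFR_5000 = BenchmarkSpec(n=5000, avg_degree=20, max_degree=100, tau_degree=2,
                         tau_size=1, mu=0.6, min_size=50, max_size=150)


# ---------------------------------------------------------------------------
# power-law sampling helpers
# ---------------------------------------------------------------------------

def _truncated_powerlaw_mean(tau: float, lo: float, hi: float) -> float:
    """Mean of the continuous density ∝ x^-tau on [lo, hi]."""
    if abs(tau - 1.0) < 1e-12:
        return (hi - lo) / np.log(hi / lo)
    if abs(tau - 2.0) < 1e-12:
        return np.log(hi / lo) / (1.0 / lo - 1.0 / hi)
    z = (hi ** (1 - tau) - lo ** (1 - tau)) / (1 - tau)
    m1 = (hi ** (2 - tau) - lo ** (2 - tau)) / (2 - tau)
    return m1 / z


def _solve_min_degree(tau: float, avg: float, hi: float) -> float:
    """Lower cutoff of the truncated power law whose mean is ``avg``."""
    lo, up = 1.0, float(hi)
    if _truncated_powerlaw_mean(tau, up - 1e-9, up) < avg:
        raise InfeasibleSpecError("average degree too close to the maximum degree")
    for _ in range(200):
        mid = 0.5 * (lo + up)
        if _truncated_powerlaw_mean(tau, mid, hi) < avg:
            lo = mid
        else:
            up = mid
    return 0.5 * (lo + up)


def _sample_powerlaw(rng: np.random.Generator, tau: float, lo: float, hi: float,
                     size: int) -> np.ndarray:
    """Inverse-CDF samples of the continuous density ∝ x^-tau on [lo, hi]."""
    u = rng.random(size)
    if abs(tau - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    e = 1.0 - tau
    return (lo ** e + u * (hi ** e - lo ** e)) ** (1.0 / e)


def _sample_degrees(rng: np.random.Generator, spec: BenchmarkSpec) -> np.ndarray:
    lo = _solve_min_degree(spec.tau_degree, spec.avg_degree, spec.max_degree)
    x = _sample_powerlaw(rng, spec.tau_degree, lo, spec.max_degree, spec.n)
    return np.clip(np.rint(x).astype(np.int64), 1, spec.max_degree)


def _sample_community_sizes(rng: np.random.Generator, spec: BenchmarkSpec) -> list[int]:
    """Power-law community sizes summing exactly to n."""
    support = np.arange(spec.min_size, spec.max_size + 1, dtype=np.float64)
    weights = support ** (-spec.tau_size)
    weights /= weights.sum()
    sizes: list[int] = []
    total = 0
    while total < spec.n:
        s = int(rng.choice(support, p=weights))
        sizes.append(s)
        total += s
    excess = total - spec.n
    if excess:
        if sizes[-1] - excess >= spec.min_size:
            sizes[-1] -= excess
        else:
            deficit = sizes.pop() - excess  # vertices still to place
            order = rng.permutation(len(sizes))
            while deficit > 0:
                grew = False
                for idx in order:
                    if deficit == 0:
                        break
                    if sizes[idx] < spec.max_size:
                        sizes[idx] += 1
                        deficit -= 1
                        grew = True
                if not grew:
                    raise InfeasibleSpecError(
                        "community-size bounds cannot tile the vertex count")
    return sizes


# ---------------------------------------------------------------------------
# stub matching
# ---------------------------------------------------------------------------

def _match_stubs(rng: np.random.Generator, stubs: list[int],
                 valid, existing: set[tuple[int, int]],
                 max_rounds: int = 60) -> list[tuple[int, int]]:
    """Randomly pair stubs, re-queuing conflicting pairs for later rounds.

    ``valid(u, v)`` decides structural eligibility; duplicates against
    ``existing`` (and within this matching) are rejected.  Stubs that cannot
    be placed after ``max_rounds`` are dropped, leaving a small degree
    shortfall rather than biased edges.
    """
    edges: list[tuple[int, int]] = []
    seen = set(existing)
    pool = list(stubs)
    for _ in range(max_rounds):
        if len(pool) < 2:
            break
        pool = list(rng.permutation(np.asarray(pool, dtype=np.int64)))
        leftover: list[int] = []
        if len(pool) % 2:
            leftover.append(int(pool.pop()))
        for idx in range(0, len(pool), 2):
            u, v = int(pool[idx]), int(pool[idx + 1])
            key = (u, v) if u < v else (v, u)
            if u != v and key not in seen and valid(u, v):
                seen.add(key)
                edges.append(key)
            else:
                leftover.extend((u, v))
        if len(leftover) == len(pool) + (len(pool) % 2):
            break
        pool = leftover
    return edges


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def lfr_graph(spec: BenchmarkSpec) -> tuple[UndirectedGraph, Partition]:
    """Generate an LFR-style benchmark graph and its planted partition."""
    rng = np.random.default_rng(spec.seed)
    degrees = _sample_degrees(rng, spec)
    sizes = _sample_community_sizes(rng, spec)
    n_comm = len(sizes)

    int_deg = np.rint((1.0 - spec.mu) * degrees).astype(np.int64)
    int_deg = np.minimum(int_deg, degrees)

    # capacity-constrained assignment, most demanding vertices first
    capacity = list(sizes)
    membership = np.full(spec.n, -1, dtype=np.int64)
    order = sorted(range(spec.n), key=lambda v: (-int_deg[v], v))
    size_arr = np.asarray(sizes)
    for v in order:
        feasible = [c for c in range(n_comm)
                    if capacity[c] > 0 and size_arr[c] - 1 >= int_deg[v]]
        if feasible:
            c = int(rng.choice(np.asarray(feasible)))
        else:
            open_comms = [c for c in range(n_comm) if capacity[c] > 0]
            if not open_comms:
                raise InfeasibleSpecError("ran out of community capacity")
            c = max(open_comms, key=lambda cc: sizes[cc])
            int_deg[v] = sizes[c] - 1  # cap internal degree to fit
        membership[v] = c
        capacity[c] -= 1

    if spec.mu == 0.0:
        ext_deg = np.zeros(spec.n, dtype=np.int64)
    else:
        ext_deg = degrees - int_deg

    # internal edges, one stub pool per community (drop one stub on odd parity)
    edges: set[tuple[int, int]] = set()
    members_of = [np.flatnonzero(membership == c) for c in range(n_comm)]
    for c in range(n_comm):
        stubs: list[int] = []
        local_int = {int(v): int(int_deg[v]) for v in members_of[c]}
        if sum(local_int.values()) % 2:
            vmax = max(local_int, key=lambda v: (local_int[v], v))
            local_int[vmax] -= 1
        for v, d in local_int.items():
            stubs.extend([v] * d)
        intra = _match_stubs(rng, stubs, valid=lambda u, v: True, existing=edges)
        edges.update(intra)

    # external edges: global pool, forbidden inside a community
    stubs = []
    ext = {int(v): int(ext_deg[v]) for v in range(spec.n)}
    if sum(ext.values()) % 2:
        vmax = max(ext, key=lambda v: (ext[v], v))
        ext[vmax] -= 1
    for v, d in ext.items():
        stubs.extend([v] * d)
    inter = _match_stubs(rng, stubs,
                         valid=lambda u, v: membership[u] != membership[v],
                         existing=edges)
    edges.update(inter)

    graph = UndirectedGraph.from_index_edges(spec.n, sorted(edges))
    graph.validate()
    truth = Partition.from_membership(membership.tolist())
    truth.validate(spec.n)
    return graph, truth


def realized_mixing(graph: UndirectedGraph, truth: Partition) -> float:
    """Mean over vertices of the fraction of incident edges leaving the community."""
    fracs = []
    for v in range(graph.n_vertices):
        d = graph.degree(v)
        if d == 0:
            continue
        ext = sum(1 for u in graph.adjacency[v]
                  if truth.membership[u] != truth.membership[v])
        fracs.append(ext / d)
    return float(np.mean(fracs)) if fracs else 0.0


def planted_partition(k: int, size: int, p_in: float, p_out: float,
                      seed: int) -> tuple[UndirectedGraph, Partition]:
    """k equal blocks of `size` vertices; independent edge coin flips.

    Edge probability ``p_in`` within a block, ``p_out`` between blocks;
    the blocks are the ground truth.
    """
    import networkx as nx

    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    g = nx.planted_partition_graph(k, size, p_in, p_out, seed=seed)
    graph = UndirectedGraph.from_index_edges(
        k * size, ((int(u), int(v)) for u, v in g.edges()))
    truth = Partition.from_membership([v // size for v in range(k * size)])
    return graph, truth


def ring_of_cliques(n_cliques: int, clique_size: int) -> tuple[UndirectedGraph, Partition]:
    """Cliques joined in a ring by single bridge edges; the cliques are the truth.

    With two cliques the "ring" degenerates to a single bridge, the classic
    twin-clique fixture.
    """
    if n_cliques < 2 or clique_size < 3:
        raise ValueError("need at least 2 cliques of size >= 3")
    n = n_cliques * clique_size
    edges: list[tuple[int, int]] = []
    for c in range(n_cliques):
        base = c * clique_size
        edges.extend((base + i, base + j)
                     for i in range(clique_size) for j in range(i + 1, clique_size))
    n_bridges = 1 if n_cliques == 2 else n_cliques
    for c in range(n_bridges):
        # last vertex of clique c bridges to first vertex of the next clique
        edges.append((c * clique_size + clique_size - 1,
                      ((c + 1) % n_cliques) * clique_size))
    graph = UndirectedGraph.from_index_edges(n, edges)
    truth = Partition.from_membership([v // clique_size for v in range(n)])
    return graph, truth
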