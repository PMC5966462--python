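"""Merge phase: similarity-gated greedy modularity agglomeration.

Seed clusters from the voting phase become the initial communities.  At each
step the pair of communities with positive similarity whose merge yields the
largest modularity increment is joined; the procedure stops as soon as no
pair of communities shares any neighbourhood overlap.  The result returned
is the partition along the merge trace with maximal modularity (the seed
partition counts as level zero of the dendrogram).

Bookkeeping follows the classic fast greedy scheme: with ``m`` edges,
``e_ii = L_i/m`` (intra-edge fraction), ``e_ij = A_ij/(2m)`` for ``i ≠ j``
(half the inter-edge fraction, so each cross edge contributes to both
ordered pairs), and ``a_i`` the fraction of edge endpoints in ``C_i``.
Under this convention ``Q = Σ_i (e_ii − a_i²)`` and the merge increment
``ΔQ_ij = 2(e_ij − a_i a_j)`` is the exact change in ``Q``.

Community similarity is ``SIM(C_i, C_j) = Σ_{u∈C_i} Σ_{v∈C_j} sim(u, v)``,
which is additive under merges, so the pairwise vertex similarities are
computed once at initialisation (only vertex pairs with a common neighbour
can contribute, i.e. pairs at graph distance ≤ 2).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import Partition, UndirectedGraph
from .voting import VoteState, run_voting, vertex_similarity

Pair = tuple[int, int]


class MergeContractError(RuntimeError):
    """A merge operation was applied to dead or ineligible communities."""


def modularity(graph: UndirectedGraph, partition: Partition) -> float:
    """Newman-Girvan modularity ``Q = Σ_i (L_i/m − (D_i/2m)²)``.

    ``L_i`` is the number of intra-community edges and ``D_i`` the degree
    sum of community ``i``.  Raises on an edgeless graph.
    """
    m = graph.n_edges
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    partition.validate(graph.n_vertices)
    intra = [0] * partition.n_communities
    for u, v in graph.edges():
        if partition.membership[u] == partition.membership[v]:
            intra[partition.membership[u]] += 1
    q = 0.0
    for ci, members in enumerate(partition.communities):
        deg_sum = sum(graph.degree(v) for v in members)
        q += intra[ci] / m - (deg_sum / (2 * m)) ** 2
    return q


def community_similarity(graph: UndirectedGraph, c_i, c_j) -> float:
    """``SIM(C_i, C_j)``: sum of vertex similarity over all cross pairs."""
    c_i, c_j = set(c_i), set(c_j)
    if c_i & c_j:
        raise ValueError("communities overlap")
    if not c_i or not c_j:
        raise ValueError("communities must be non-empty")
    return sum(vertex_similarity(graph, u, v) for u in c_i for v in c_j)


@dataclass
class MergeState:
    """Sparse modularity and similarity bookkeeping over live communities.

    Merged communities receive fresh ids, so ``e_ij``, ``a_i`` and hence
    ``ΔQ_ij`` are immutable for any pair of live ids; the internal priority
    heap therefore never holds stale *values*, only entries whose ids have
    died, which are discarded lazily.  Its answers coincide exactly with a
    brute-force argmax over the SIM table (property-tested).
    """

    e_intra: dict[int, float]
    e_inter: dict[Pair, float]           # key (i, j) with i < j, value e_ij
    a: dict[int, float]
    sim: dict[Pair, float]               # only pairs with SIM > 0
    live: set[int]
    q_current: float
    trace: list[tuple[int, int, float, float]] = field(default_factory=list)
    merges: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, new_id)
    next_id: int = 0
    # accelerators: per-id partner sets and the lazy max-heap of candidates
    _sim_partners: dict[int, set[int]] = field(default_factory=dict, repr=False)
    _e_partners: dict[int, set[int]] = field(default_factory=dict, repr=False)
    _heap: list[tuple[float, float, int, int]] = field(default_factory=list, repr=False)

    def get_e(self, i: int, j: int) -> float:
        return self.e_inter.get((i, j) if i < j else (j, i), 0.0)

    def _push_candidate(self, i: int, j: int) -> None:
        dq = 2.0 * (self.get_e(i, j) - self.a[i] * self.a[j])
        s = self.sim[(i, j) if i < j else (j, i)]
        heapq.heappush(self._heap, (-dq, -s, min(i, j), max(i, j)))


def _pairwise_similarity_matrix(graph: UndirectedGraph):
    """Return (rows, cols, sims) for all vertex pairs u<v with sim(u,v) > 0.

    Vectorised: the common-neighbour count matrix is A·A; the union size for
    the denominator is d(u)+d(v)−common−2·[u~v] (vertices exclude themselves
    from their own neighbourhoods).
    """
    n = graph.n_vertices
    indptr = np.zeros(n + 1, dtype=np.int64)
    for v in range(n):
        indptr[v + 1] = indptr[v] + graph.degree(v)
    indices = np.empty(indptr[-1], dtype=np.int64)
    pos = 0
    for v in range(n):
        nbrs = sorted(graph.adjacency[v])
        indices[pos:pos + len(nbrs)] = nbrs
        pos += len(nbrs)
    A = sp.csr_matrix((np.ones(len(indices), dtype=np.int64), indices, indptr),
                      shape=(n, n))
    # pack common count and adjacency flag into one integer entry
    packed = sp.triu((A @ A) + (n + 1) * A, k=1).tocoo()
    common = packed.data % (n + 1)
    adj = packed.data // (n + 1)
    keep = common > 0
    rows, cols = packed.row[keep], packed.col[keep]
    common, adj = common[keep], adj[keep]
    deg = np.asarray([graph.degree(v) for v in range(n)], dtype=np.int64)
    denom = deg[rows] + deg[cols] - common - 2 * adj
    sims = np.where(denom > 0, common / np.maximum(denom, 1), 0.0)
    keep = sims > 0
    return rows[keep], cols[keep], sims[keep]


def init_merge_state(graph: UndirectedGraph, partition: Partition) -> MergeState:
    """Set up e/a bookkeeping and the sparse SIM table for a seed partition."""
    m = graph.n_edges
    if m == 0:
        raise ValueError("merge phase requires at least one edge")
    partition.validate(graph.n_vertices)
    k = partition.n_communities
    member = partition.membership

    e_intra = {i: 0.0 for i in range(k)}
    e_inter: dict[Pair, float] = {}
    for u, v in graph.edges():
        ci, cj = member[u], member[v]
        if ci == cj:
            e_intra[ci] += 1.0 / m
        else:
            key = (ci, cj) if ci < cj else (cj, ci)
            e_inter[key] = e_inter.get(key, 0.0) + 1.0 / (2 * m)
    a = {}
    for i, members in enumerate(partition.communities):
        a[i] = sum(graph.degree(v) for v in members) / (2 * m)

    # SIM over cross-community vertex pairs (only distance-<=2 pairs contribute)
    rows, cols, sims = _pairwise_similarity_matrix(graph)
    memb = np.asarray(member, dtype=np.int64)
    ci, cj = memb[rows], memb[cols]
    cross = ci != cj
    lo = np.minimum(ci[cross], cj[cross])
    hi = np.maximum(ci[cross], cj[cross])
    keys = lo * k + hi
    uniq, inv = np.unique(keys, return_inverse=True)
    totals = np.bincount(inv, weights=sims[cross])
    sim_table = {(int(key // k), int(key % k)): float(total)
                 for key, total in zip(uniq, totals) if total > 0}

    q = sum(e_intra[i] - a[i] ** 2 for i in range(k))
    state = MergeState(e_intra=e_intra, e_inter=e_inter, a=a, sim=sim_table,
                       live=set(range(k)), q_current=q, next_id=k)
    for (i, j) in e_inter:
        state._e_partners.setdefault(i, set()).add(j)
        state._e_partners.setdefault(j, set()).add(i)
    for (i, j) in sim_table:
        state._sim_partners.setdefault(i, set()).add(j)
        state._sim_partners.setdefault(j, set()).add(i)
        state._push_candidate(i, j)
    return state


def delta_q(state: MergeState, i: int, j: int) -> float:
    """Exact modularity change from merging communities i and j: 2(e_ij − a_i a_j)."""
    if i == j:
        raise ValueError("cannot merge a community with itself")
    if i not in state.live or j not in state.live:
        raise MergeContractError(f"community {i if i not in state.live else j} is not live")
    return 2.0 * (state.get_e(i, j) - state.a[i] * state.a[j])


def best_merge_pair(state: MergeState) -> Pair | None:
    """Eligible pair (SIM > 0) with the largest ΔQ.

    Ties break toward larger SIM, then the lexicographically smallest
    ``(i, j)``; returns ``None`` when no pair has positive similarity.
    """
    heap = state._heap
    while heap:
        _, _, i, j = heap[0]
        if i in state.live and j in state.live:
            return (i, j)
        heapq.heappop(heap)  # one or both ids merged away; entry is dead
    return None


def merge_pair(state: MergeState, i: int, j: int) -> MergeState:
    """Merge communities i and j into a fresh community id, in place."""
    key = (i, j) if i < j else (j, i)
    if key not in state.sim:
        raise MergeContractError(f"pair {key} has zero similarity; merge is ineligible")
    dq = delta_q(state, i, j)
    k = state.next_id
    state.next_id += 1

    state.e_intra[k] = state.e_intra.pop(i) + state.e_intra.pop(j) + 2 * state.get_e(i, j)
    state.a[k] = state.a.pop(i) + state.a.pop(j)
    state.live.discard(i)
    state.live.discard(j)
    state.live.add(k)

    for table, partners in ((state.e_inter, state._e_partners),
                            (state.sim, state._sim_partners)):
        merged: dict[int, float] = {}
        for old in (i, j):
            for other in partners.pop(old, ()):
                if other in (i, j):
                    table.pop((min(old, other), max(old, other)), None)
                    continue  # the merged pair itself
                val = table.pop((min(old, other), max(old, other)))
                merged[other] = merged.get(other, 0.0) + val
                partners[other].discard(old)
        for other, val in merged.items():
            table[(other, k)] = val  # other < k: fresh ids are always largest
            partners[other].add(k)
        partners[k] = set(merged)
        if table is state.sim:
            for other in merged:
                state._push_candidate(other, k)
    state.q_current += dq
    state.trace.append((i, j, dq, state.q_current))
    state.merges.append((i, j, k))
    return state


def run_merging(graph: UndirectedGraph, seed_partition: Partition,
                policy: str = "max_q") -> tuple[Partition, list[tuple[int, int, float, float]]]:
    """Greedy similarity-gated agglomeration from a seed partition.

    ``policy="max_q"`` (default) merges until no eligible pair remains and
    returns the earliest maximal-Q level of the dendrogram (the untouched
    seed partition included).  ``policy="stop_at_nonpositive"`` stops at the
    first non-positive increment and returns the partition reached.
    """
    if policy not in ("max_q", "stop_at_nonpositive"):
        raise ValueError(f"unknown merge policy {policy!r}")
    state = init_merge_state(graph, seed_partition)
    q_levels = [state.q_current]  # level 0 = seed partition
    while True:
        pair = best_merge_pair(state)
        if pair is None:
            break
        if policy == "stop_at_nonpositive" and delta_q(state, *pair) <= 0:
            break
        merge_pair(state, *pair)
        q_levels.append(state.q_current)

    if policy == "max_q":
        best_level = max(range(len(q_levels)), key=lambda s: (q_levels[s], -s))
    else:
        best_level = len(q_levels) - 1

    # replay the first `best_level` merges over the seed communities
    groups: dict[int, list[int]] = {i: list(c)
                                    for i, c in enumerate(seed_partition.communities)}
    for i, j, new_id in state.merges[:best_level]:
        groups[new_id] = groups.pop(i) + groups.pop(j)
    partition = Partition.from_communities(groups.values(), graph.n_vertices)
    partition.validate(graph.n_vertices)
    return partition, list(state.trace)


def detect_communities(graph: UndirectedGraph, policy: str = "max_q"
                       ) -> tuple[Partition, list[tuple[int, int, float, float]], VoteState]:
    """Full pipeline: voting pass, then similarity-gated greedy merging.

    Deterministic end to end; raises on a graph without edges.
    """
    if graph.n_vertices == 0:
        raise ValueError("empty graph")
    if graph.n_edges == 0:
        raise ValueError("graph has no edges; community structure is undefined")
    seed_partition, vote_state = run_voting(graph)
    partition, trace = run_merging(graph, seed_partition, policy=policy)
    return partition, trace, vote_state


def write_trace(trace, path) -> None:
    """Export a merge trace as TSV: step, community_a, community_b, delta_q, q_after."""
    with open(path, "w") as fh:
        fh.write("step\tcommunity_a\tcommunity_b\tdelta_q\tq_after\n")
        for step, (i, j, dq, q_after) in enumerate(trace, start=1):
            fh.write(f"{step}\t{i}\t{j}\t{dq:.12g}\t{q_after:.12g}\n")
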