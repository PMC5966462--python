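"""Voting phase: seed clusters form around locally influential vertices.

Every vertex casts exactly one vote, in ascending order of local clustering
coefficient (so hubs, whose neighbourhoods are sparse, vote early and become
candidates).  The rules, applied on a vertex ``u``'s turn:

1. If ``u`` is already a nominated candidate, or no neighbour has strictly
   larger degree, ``u`` votes for itself and is a candidate.
2. Otherwise ``u`` picks the most similar strictly-larger-degree neighbour
   ``v``.  If ``sim(u, v) = 0`` there is nothing tying ``u`` to a hub and it
   nominates itself.
3. If ``v`` has not yet voted for anyone else, ``u`` nominates ``v`` and
   votes for it.
4. If ``v`` already voted for another vertex ``w``, ``u`` votes for ``w``
   as well (``w`` is always a candidate, so chains never exceed one hop).

Similarity is shared-neighbour overlap: ``|N(u) ∩ N(v)|`` over the union of
the two neighbourhoods with ``u`` and ``v`` themselves excluded.  The
candidates with their voters are the seed clusters handed to the merge phase.
Everything here is deterministic: ties in the voting order fall back to
degree (descending) then external label, and ties in similarity to degree
then label.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import Partition, UndirectedGraph

UNSET = -1


class VotingContractError(RuntimeError):
    """A voting operation was invoked out of turn or on invalid state."""


def clustering_coefficient(graph: UndirectedGraph, v: int) -> float:
    """Fraction of realised links among v's neighbours (ordered-pair form).

    ``cc(v) = |{(u,w) : u,w ∈ N(v), (u,w) ∈ E}| / (d(v)·(d(v)−1))``,
    with the convention ``cc(v) = 0`` when ``d(v) ≤ 1`` (the denominator
    degenerates; such vertices cannot head dense clusters).
    """
    if not 0 <= v < graph.n_vertices:
        raise IndexError(f"unknown vertex {v}")
    nbrs = graph.adjacency[v]
    d = len(nbrs)
    if d <= 1:
        return 0.0
    # each undirected link inside N(v) contributes two ordered pairs
    ordered = sum(len(graph.adjacency[u] & nbrs) for u in nbrs)
    return ordered / (d * (d - 1))


def vertex_similarity(graph: UndirectedGraph, u: int, v: int) -> float:
    """Shared-neighbour overlap ``|N(u)∩N(v)| / |(N(u)∪N(v)) \\ {u,v}|``.

    For adjacent ``u, v`` this equals ``|N(u)∩N(v)| / (|N(u)∪N(v)| − 2)``;
    the set form extends it to non-adjacent pairs (needed when summing over
    community cross pairs) and stays in ``[0, 1]``.  A zero denominator
    yields 0.  Symmetric in ``u`` and ``v``.
    """
    if u == v:
        raise ValueError("vertex similarity is undefined for u == v")
    nu, nv = graph.adjacency[u], graph.adjacency[v]
    inter = len(nu & nv)
    union = len(nu) + len(nv) - inter - (u in nv) - (v in nu)
    if union <= 0:
        return 0.0
    return inter / union


@dataclass
class VoteState:
    """Mutable record of the voting pass."""

    cc: list[float]
    order: list[int]
    target: list[int]          # UNSET before the vertex's turn (unless nominated)
    is_candidate: list[bool]
    turn: int = 0              # position in `order` of the next voter

    @classmethod
    def initial(cls, graph: UndirectedGraph) -> "VoteState":
        n = graph.n_vertices
        cc = [clustering_coefficient(graph, v) for v in range(n)]
        order = voting_order(graph, cc=cc)
        return cls(cc=cc, order=order, target=[UNSET] * n,
                   is_candidate=[False] * n)


def voting_order(graph: UndirectedGraph, cc: list[float] | None = None) -> list[int]:
    """Deterministic voting order: ascending cc, degree descending, label ascending."""
    if cc is None:
        cc = [clustering_coefficient(graph, v) for v in range(graph.n_vertices)]
    return sorted(range(graph.n_vertices),
                  key=lambda v: (cc[v], -graph.degree(v), graph.labels[v]))


def cast_vote(graph: UndirectedGraph, u: int, state: VoteState) -> VoteState:
    """Apply the voting rules for ``u`` (must be ``u``'s turn) in place."""
    if state.turn >= len(state.order) or state.order[state.turn] != u:
        raise VotingContractError(f"it is not vertex {u}'s turn")
    if state.target[u] != UNSET and not state.is_candidate[u]:
        raise VotingContractError(f"vertex {u} has already voted")

    deg_u = graph.degree(u)
    larger = [w for w in graph.adjacency[u] if graph.degree(w) > deg_u]
    if state.is_candidate[u] or not larger:
        # rule 1: pre-nominated, or locally maximal degree (ties count as maximal)
        state.target[u] = u
        state.is_candidate[u] = True
    else:
        v = min(larger, key=lambda w: (-vertex_similarity(graph, u, w),
                                       -graph.degree(w), graph.labels[w]))
        if vertex_similarity(graph, u, v) == 0.0:
            # rule 2: no overlap with any larger-degree neighbour
            state.target[u] = u
            state.is_candidate[u] = True
        elif state.target[v] in (UNSET, v):
            # rule 3: v has not voted for anyone else -> nominate v
            state.is_candidate[v] = True
            state.target[u] = v
        else:
            # rule 4: follow v's vote; its target is already a candidate
            w = state.target[v]
            assert state.is_candidate[w]
            state.target[u] = w
    state.turn += 1
    return state


def run_voting(graph: UndirectedGraph) -> tuple[Partition, VoteState]:
    """Run the full voting pass and group vertices by resolved vote target.

    Returns the seed-cluster partition (one cluster per candidate, in voting
    order of the candidates) and the final :class:`VoteState`.
    """
    state = VoteState.initial(graph)
    for u in state.order:
        cast_vote(graph, u, state)

    # post-conditions of the voting pass
    clusters: dict[int, list[int]] = {}
    for v in state.order:          # candidate discovery follows voting order
        t = state.target[v]
        assert t != UNSET, "vertex left without a vote target"
        assert state.is_candidate[t] and state.target[t] == t
        clusters.setdefault(t, []).append(v)
    partition = Partition.from_communities(clusters.values(), graph.n_vertices)
    partition.validate(graph.n_vertices)
    return partition, state
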