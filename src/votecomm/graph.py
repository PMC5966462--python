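"""Graph and partition data model plus file I/O.

The detection method operates on simple undirected, unweighted graphs.
:class:`UndirectedGraph` keeps an adjacency-set representation with dense
internal vertex indices ``0..n-1`` and a bidirectional map to the external
string labels found in input files.  :class:`Partition` is an exact cover of
the vertex set by disjoint, non-empty communities.

Readers normalise their input: self-loops are dropped and parallel edges
collapsed (the similarity and clustering-coefficient formulas assume a simple
graph); both are counted and reported through :mod:`logging`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class GraphParseError(ValueError):
    """Raised when an input file cannot be turned into a valid graph."""


class PartitionError(ValueError):
    """Raised when a membership file or partition is inconsistent with a graph."""


@dataclass
class UndirectedGraph:
    """Simple undirected unweighted graph with dense integer vertex indices.

    Attributes
    ----------
    adjacency:
        ``adjacency[v]`` is the set of neighbour indices ``N(v)``.
    labels:
        ``labels[v]`` is the external string label of vertex ``v``; indices
        are assigned in first-appearance order by the readers.
    """

    adjacency: list[set[int]]
    labels: list[str]
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.adjacency)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adjacency) // 2

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    def neighbors(self, v: int) -> set[int]:
        return self.adjacency[v]

    def has_edge(self, u: int, v: int) -> bool:
        return v in self.adjacency[u]

    def index_of(self, label: str) -> int:
        return self._index[label]

    def edges(self) -> Iterable[tuple[int, int]]:
        for u, nbrs in enumerate(self.adjacency):
            for v in nbrs:
                if u < v:
                    yield u, v

    # -- construction ----------------------------------------------------
    @classmethod
    def from_edge_labels(cls, pairs: Iterable[tuple[str, str]],
                         extra_vertices: Iterable[str] = ()) -> "UndirectedGraph":
        """Build a normalised graph from (label, label) pairs.

        Duplicate edges are collapsed, self-loops dropped, and indices
        assigned in first-appearance order (scanning each pair left to
        right).  ``extra_vertices`` adds isolated vertices.
        """
        index: dict[str, int] = {}
        labels: list[str] = []

        def idx(lab: str) -> int:
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
            return index[lab]

        adjacency: list[set[int]] = []
        n_self = n_dup = 0
        for a, b in pairs:
            u, v = idx(a), idx(b)
            while len(adjacency) < len(labels):
                adjacency.append(set())
            if u == v:
                n_self += 1
                continue
            if v in adjacency[u]:
                n_dup += 1
                continue
            adjacency[u].add(v)
            adjacency[v].add(u)
        for lab in extra_vertices:
            idx(lab)
        while len(adjacency) < len(labels):
            adjacency.append(set())
        if n_self or n_dup:
            logger.info("normalisation dropped %d self-loop(s) and %d duplicate edge(s)",
                        n_self, n_dup)
        return cls(adjacency=adjacency, labels=labels, _index=index)

    @classmethod
    def from_index_edges(cls, n: int, pairs: Iterable[tuple[int, int]],
                         labels: Sequence[str] | None = None) -> "UndirectedGraph":
        """Build from integer-index edges on a fixed vertex set ``0..n-1``."""
        if labels is None:
            labels = [str(i) for i in range(n)]
        adjacency: list[set[int]] = [set() for _ in range(n)]
        for u, v in pairs:
            if u == v:
                continue
            adjacency[u].add(v)
            adjacency[v].add(u)
        return cls(adjacency=adjacency, labels=list(labels))

    def validate(self) -> None:
        """Assert the structural invariants (no self-loops, symmetry, density)."""
        n = self.n_vertices
        assert len(self.labels) == n and len(self._index) == n
        for v, nbrs in enumerate(self.adjacency):
            assert v not in nbrs, f"self-loop at {v}"
            for u in nbrs:
                assert 0 <= u < n
                assert v in self.adjacency[u], f"asymmetric edge {v}-{u}"


@dataclass
class Partition:
    """Exact cover of the vertex set by disjoint non-empty communities."""

    membership: list[int]
    communities: list[list[int]]

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    @classmethod
    def from_membership(cls, membership: Sequence[int]) -> "Partition":
        """Build from a per-vertex community assignment.

        Community ids are compacted to ``0..k-1`` in order of first
        appearance.
        """
        remap: dict[int, int] = {}
        communities: list[list[int]] = []
        out: list[int] = []
        for v, c in enumerate(membership):
            if c not in remap:
                remap[c] = len(communities)
                communities.append([])
            ci = remap[c]
            communities[ci].append(v)
            out.append(ci)
        return cls(membership=out, communities=communities)

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[int]], n: int) -> "Partition":
        membership = [-1] * n
        comms: list[list[int]] = []
        for ci, members in enumerate(communities):
            members = sorted(members)
            if not members:
                raise PartitionError("empty community")
            for v in members:
                if membership[v] != -1:
                    raise PartitionError(f"vertex {v} in two communities")
                membership[v] = ci
            comms.append(members)
        if any(c == -1 for c in membership):
            missing = [v for v, c in enumerate(membership) if c == -1]
            raise PartitionError(f"vertices not covered: {missing[:10]}")
        return cls(membership=membership, communities=comms)

    def validate(self, n_vertices: int) -> None:
        assert len(self.membership) == n_vertices
        seen = 0
        for ci, members in enumerate(self.communities):
            assert members, "empty community"
            for v in members:
                assert self.membership[v] == ci
            seen += len(members)
        assert seen == n_vertices


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, comment_prefix: str = "#") -> UndirectedGraph:
    """Read a whitespace-separated edge list (two labels per line).

    Blank lines and lines starting with ``comment_prefix`` are ignored;
    extra tokens after the first two are ignored.  Raises
    :class:`GraphParseError` naming the line number on a malformed line,
    or if no usable edge remains.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(comment_prefix):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise GraphParseError(
                    f"{path}: line {lineno}: expected two vertex labels, got {stripped!r}")
            pairs.append((tokens[0], tokens[1]))
    if not pairs:
        raise GraphParseError(f"{path}: no edges found")
    graph = UndirectedGraph.from_edge_labels(pairs)
    if graph.n_edges == 0:
        raise GraphParseError(f"{path}: no usable edges after dropping self-loops")
    graph.validate()
    return graph


def read_gml(path: str | Path) -> UndirectedGraph:
    """Read the undirected subset of GML (graph/node/edge, id/label/source/target).

    A node's ``label`` attribute is used as its external label when present,
    otherwise its numeric id.  A ``directed 1`` flag triggers a warning and
    the edges are treated as undirected.
    """
    import networkx as nx

    try:
        g = nx.read_gml(str(path), label="id")
    except nx.NetworkXError as exc:
        if "duplicated" in str(exc):
            # duplicate edge records are legal input here and collapse to one
            text = Path(path).read_text().replace("graph [", "graph [\n  multigraph 1", 1)
            try:
                g = nx.parse_gml(text, label="id")
            except nx.NetworkXError as exc2:
                raise GraphParseError(f"{path}: {exc2}") from exc2
        else:
            raise GraphParseError(f"{path}: {exc}") from exc
    if g.is_directed():
        logger.warning("%s: directed flag set; treating edges as undirected", path)
        g = g.to_undirected()
    if g.is_multigraph():
        g = nx.Graph(g)

    def ext_label(node) -> str:
        lab = g.nodes[node].get("label")
        return str(lab) if lab is not None else str(node)

    names = {node: ext_label(node) for node in g.nodes}
    if len(set(names.values())) != len(names):
        raise GraphParseError(f"{path}: duplicate node labels")
    # first-appearance order follows the GML node ordering
    pairs = [(names[u], names[v]) for u, v in g.edges]
    isolated = [names[v] for v in g.nodes if g.degree(v) == 0]
    graph = UndirectedGraph.from_edge_labels(pairs, extra_vertices=isolated)
    graph.validate()
    return graph


def write_membership(partition: Partition, graph: UndirectedGraph,
                     path: str | Path) -> None:
    """Write a membership TSV: ``external_label <TAB> community_index``.

    Lines are sorted by external label and community indices renumbered
    ``0..k-1`` in order of each community's smallest member label, so the
    output is byte-stable across runs.
    """
    partition.validate(graph.n_vertices)
    order = sorted(range(partition.n_communities),
                   key=lambda ci: min(graph.labels[v] for v in partition.communities[ci]))
    renum = {ci: rank for rank, ci in enumerate(order)}
    lines = sorted((graph.labels[v], renum[partition.membership[v]])
                   for v in range(graph.n_vertices))
    with open(path, "w") as fh:
        for lab, ci in lines:
            fh.write(f"{lab}\t{ci}\n")


def read_membership(path: str | Path, graph: UndirectedGraph) -> Partition:
    """Read a membership TSV back into a :class:`Partition` for ``graph``."""
    assignment: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            tokens = stripped.split("\t")
            if len(tokens) < 2:
                raise GraphParseError(
                    f"{path}: line {lineno}: expected 'label<TAB>community'")
            lab, comm = tokens[0], tokens[1]
            if lab not in graph._index:
                raise PartitionError(f"{path}: unknown vertex {lab!r}")
            v = graph.index_of(lab)
            if v in assignment:
                raise PartitionError(f"{path}: vertex {lab!r} listed twice")
            assignment[v] = comm
    missing = [graph.labels[v] for v in range(graph.n_vertices) if v not in assignment]
    if missing:
        raise PartitionError(f"{path}: vertices missing from file: {missing[:10]}")
    labels_seen: dict[str, int] = {}
    membership = [0] * graph.n_vertices
    for v in range(graph.n_vertices):
        comm = assignment[v]
        if comm not in labels_seen:
            labels_seen[comm] = len(labels_seen)
        membership[v] = labels_seen[comm]
    part = Partition.from_membership(membership)
    part.validate(graph.n_vertices)
    return part
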