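"""Partition-quality (modularity) and partition-agreement (NMI) measures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Partition, UndirectedGraph
from .merging import modularity


@dataclass
class ContingencyTable:
    """Shared-vertex counts between the communities of two partitions."""

    counts: np.ndarray          # shape (k1, k2), non-negative ints
    n: int

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def contingency(p1: Partition, p2: Partition) -> ContingencyTable:
    """counts[i][j] = number of vertices shared by community i of p1 and j of p2."""
    if len(p1.membership) != len(p2.membership):
        raise ValueError("partitions cover different vertex sets")
    n = len(p1.membership)
    counts = np.zeros((p1.n_communities, p2.n_communities), dtype=np.int64)
    for v in range(n):
        counts[p1.membership[v], p2.membership[v]] += 1
    return ContingencyTable(counts=counts, n=n)


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalised mutual information, ``2·I(X;Y) / (H(X) + H(Y))``.

    Natural logarithms (the base cancels in the ratio).  1.0 iff the
    partitions are identical up to community relabelling; 0 when either
    partition has zero entropy (a single community), the standard limit of
    the 0/0 case.
    """
    table = contingency(p1, p2)
    n = table.n
    if n == 0:
        raise ValueError("empty vertex set")
    nij = table.counts
    ni = table.row_sums
    nj = table.col_sums

    def entropy(counts: np.ndarray) -> float:
        p = counts[counts > 0] / n
        return float(-(p * np.log(p)).sum())

    h1, h2 = entropy(ni), entropy(nj)
    if h1 + h2 == 0.0:
        return 0.0
    i_idx, j_idx = np.nonzero(nij)
    pij = nij[i_idx, j_idx] / n
    mi = float((pij * np.log(pij * n * n / (ni[i_idx] * nj[j_idx]))).sum())
    value = 2.0 * mi / (h1 + h2)
    # clamp tiny floating excursions outside [0, 1]
    return min(1.0, max(0.0, value))


def evaluate(graph: UndirectedGraph, predicted: Partition,
             truth: Partition | None = None) -> dict:
    """Standard evaluation report: Q, community count, and NMI when truth is known."""
    report = {
        "q": modularity(graph, predicted),
        "n_communities": predicted.n_communities,
    }
    if truth is not None:
        report["nmi"] = nmi(predicted, truth)
    return report


def format_report(report: dict) -> str:
    """Render an evaluation report as deterministic key<TAB>value lines."""
    lines = []
    for key in ("q", "n_communities", "nmi"):
        if key in report:
            value = report[key]
            lines.append(f"{key}\t{value:.6f}" if isinstance(value, float)
                         else f"{key}\t{value}")
    return "\n".join(lines)
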