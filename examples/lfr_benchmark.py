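"""Generate an LFR-style benchmark graph and measure detection quality.

Builds a 1000-vertex network with power-law degrees (mean 30, max 50),
power-law community sizes (30-100) and mixing parameter mu = 0.5 — i.e.
half of every vertex's edges leave its community — then runs detection and
scores the result against the planted partition.
"""

from votecomm import (LFR_1000, detect_communities, lfr_graph, modularity, nmi,
                      realized_mixing)

graph, truth = lfr_graph(LFR_1000.with_seed(1))
print(f"generated: n={graph.n_vertices}, m={graph.n_edges}, "
      f"{truth.n_communities} planted communities, "
      f"realised mu = {realized_mixing(graph, truth):.3f}")

partition, trace, _ = detect_communities(graph)
print(f"detected {partition.n_communities} communities after {len(trace)} merges")
print(f"Q   = {modularity(graph, partition):.4f}   "
      "(fraction of intra-community edge mass minus its random expectation)")
print(f"NMI = {nmi(partition, truth):.4f}   (1.0 would be exact recovery)")
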