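"""Detect communities in the classic twin-clique fixture.

Two 5-cliques joined by a single bridge edge.  The voting pass elects the
two bridge endpoints (the only degree-5 vertices) as candidates, every
clique-mate votes for its endpoint, and the merge phase refuses to join the
two seed clusters because doing so would lower modularity.
"""

from votecomm import detect_communities, modularity, ring_of_cliques

graph, truth = ring_of_cliques(2, 5)
partition, trace, vote_state = detect_communities(graph)

print(f"graph: {graph.n_vertices} vertices, {graph.n_edges} edges")
print(f"seed clusters (candidates): {sum(vote_state.is_candidate)}")
print(f"detected communities: {partition.n_communities}")
for members in partition.communities:
    print("  ", sorted(graph.labels[v] for v in members))
print(f"modularity Q = {modularity(graph, partition):.4f}")
print("merge trace (i, j, dQ, Q_after):", [tuple(round(x, 4) if isinstance(x, float)
      else x for x in t) for t in trace])
# The one candidate merge has dQ = 2(1/42 - 1/4) < 0, so the max-Q level of
# the dendrogram is the untouched seed partition: the two cliques.
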