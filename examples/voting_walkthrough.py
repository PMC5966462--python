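"""Step through the voting phase on a small star graph.

On a star K1,4 the centre has locally maximal degree and votes for itself;
each leaf's only larger-degree neighbour is the centre, but a leaf and the
centre share no neighbours, so their similarity is 0 and every leaf
self-nominates.  The voting phase therefore yields five singleton seed
clusters — seed clusters capture *dense* surroundings, and a star has none.
"""

from votecomm import UndirectedGraph, run_voting, clustering_coefficient

graph = UndirectedGraph.from_edge_labels(
    [("hub", "a"), ("hub", "b"), ("hub", "c"), ("hub", "d")])

for v in range(graph.n_vertices):
    print(f"cc({graph.labels[v]}) = {clustering_coefficient(graph, v):.2f}  "
          f"degree {graph.degree(v)}")

partition, state = run_voting(graph)
print(f"\nvoting order: {[graph.labels[v] for v in state.order]}")
print(f"vote targets: "
      f"{ {graph.labels[v]: graph.labels[state.target[v]] for v in range(5)} }")
print(f"seed clusters: {partition.n_communities} "
      "(every vertex is its own candidate)")
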