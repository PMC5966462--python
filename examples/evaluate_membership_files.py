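"""File-based workflow: write a graph and memberships, evaluate agreement.

Mirrors the CLI round trip (`votecomm detect` / `votecomm eval`) using the
library directly: generate a planted-partition graph, detect, persist both
partitions as TSV, read them back and score.
"""

import tempfile
from pathlib import Path

from votecomm import (detect_communities, evaluate, format_report, planted_partition,
                      read_membership, write_membership)

graph, truth = planted_partition(k=4, size=16, p_in=0.6, p_out=0.03, seed=5)
partition, _, _ = detect_communities(graph)

with tempfile.TemporaryDirectory() as tmp:
    pred_path = Path(tmp) / "predicted.tsv"
    truth_path = Path(tmp) / "truth.tsv"
    write_membership(partition, graph, pred_path)
    write_membership(truth, graph, truth_path)
    pred = read_membership(pred_path, graph)
    gold = read_membership(truth_path, graph)

report = evaluate(graph, pred, gold)
print(format_report(report))
# q: modularity of the detected partition; nmi: agreement with the planted
# blocks (1.0 = identical up to relabelling).
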