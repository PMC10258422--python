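"""Rank genes by network centrality to prioritise candidates.

Computes six centrality statistics on a backbone-pruned community network
and summarises them as a per-gene median rank (1 = most central).  Hub
regulators of the ground truth should surface at the top.
"""

import numpy as np

from netweave import (
    centralities,
    generate_grn,
    infer_suite,
    irp_aggregate,
    nc_backbone,
    prune_delta,
    simulate_expression,
)

grn = generate_grn(40, 8, 2, seed=2)
em = simulate_expression(grn, 300, 0.5, seed=3)
community = irp_aggregate(infer_suite(em, methods=["pearson", "spearman", "mi", "clr"])).table
pruned = prune_delta(nc_backbone(community.to_weighted()), 1.28)
print(f"backbone-pruned network: {pruned.n_edges} edges")

table = centralities(pruned)
top = table.sort_values("median_rank").head(8)
print("\ntop genes by median centrality rank:")
print(top[["strength", "page_rank", "betweenness", "median_rank"]].round(3))

out_degree = np.zeros(grn.n_genes)
for reg, _, _ in grn.edges:
    out_degree[reg] += 1
hubs = {grn.gene_ids[i] for i in np.argsort(-out_degree)[:5]}
recovered = hubs & set(top.index)
print(f"\n{len(recovered)} of the 5 highest out-degree true regulators appear "
      f"in the top 8 ({sorted(recovered)}): central nodes in the inferred "
      f"network track the hubs that generated the data.")
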