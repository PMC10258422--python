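"""Score a network against pathway- and interaction-style gold standards.

Builds a pathway co-membership standard and an interaction-list standard,
computes ROC/PR summaries and tests whether in-standard edges carry higher
weights than out-of-standard ones.
"""

from netweave import (
    f1_from_auc_aupr,
    generate_grn,
    grn_to_gold_standard,
    infer_suite,
    ingroup_outgroup_test,
    irp_aggregate,
    kegg_standard,
    roc_pr,
    simulate_expression,
)

grn = generate_grn(30, 6, 2, seed=4)
em = simulate_expression(grn, 250, 0.5, seed=5)
community = irp_aggregate(infer_suite(em, methods=["pearson", "spearman", "mi"])).table

# interaction-style standard: true edges positive, everything else negative
std = grn_to_gold_standard(grn)
curve = roc_pr(community, std)
f1 = f1_from_auc_aupr(curve.auc, curve.aupr)
print(f"interaction standard: {curve.n_pos} positives, {curve.n_neg} negatives")
print(f"  AUROC {curve.auc:.3f}  AUPR {curve.aupr:.3f}  F1 {f1:.3f}")

stat, p = ingroup_outgroup_test(community, std)
print(f"  in-group vs out-group rank-sum statistic {stat:.0f}, one-sided "
      f"p = {p:.2e} (in-standard edges score higher)")

# pathway-style standard: positives share a pathway, negatives share none
pathways = {g: {f"P{i % 3}"} for i, g in enumerate(grn.gene_ids[:12])}
kegg = kegg_standard(pathways)
kcurve = roc_pr(community, kegg)
print(f"\npathway standard over {len(kegg.universe)} annotated genes: "
      f"{kcurve.n_pos} co-pathway pairs, {kcurve.n_neg} cross-pathway pairs")
print(f"  AUROC {kcurve.auc:.3f} — co-annotation is only a proxy for true "
      f"regulation, so this is noisier than the interaction standard.")
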