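# netweave

Ensemble gene-network inference for expression data: infer gene–gene
association networks with several complementary algorithms, fuse them into a
single **community network** by inverse rank product, prune noisy edges with
a **noise-corrected backbone** filter, and evaluate or mine the result
(ROC/PR against gold standards, node centralities).

It is written for systems biologists who have a normalised expression matrix
(samples × genes, e.g. variance-stabilised counts) and want a robust
co-expression or regulatory network rather than the output of any single
inference algorithm, which is typically biased toward particular kinds of
interactions.

## Methods in brief

**Inference.** Eight methods spanning three families, each producing a full
gene × gene score matrix:

- *correlation*: Pearson r, Spearman ρ, shrinkage partial correlation
  (`R* = λI + (1−λ)R`, `p_ij = −ω_ij/√(ω_ii ω_jj)` with `Ω = (R*)⁻¹`, λ
  estimated analytically), and the topological overlap metric
  `TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` on the soft adjacency
  `a_ij = |r_ij|^β`;
- *mutual information*: a B-spline MI estimator (order-k basis weights over
  b bins; order 1 reduces to a plain histogram), optionally post-processed by
  CLR (`z_i(j) = max(0,(MI_ij − μ_i)/σ_i)`, `CLR_ij = √(z_i(j)² + z_j(i)²)`)
  or by the ARACNE data-processing inequality (remove edge (i,j) when
  `MI_ij < (1−ε)·min(MI_ik, MI_jk)` for some k);
- *regression*: a GENIE3-style random-forest importance network (directed).

**Aggregation.** Within each method, edges are ranked by strength (rank 1 =
strongest, average ranks for ties, unscored edges get the worst rank). The
community weight of an edge with per-method ranks r₁…r_M is the inverse rank
product `1 / (∏_m r_m)^{1/M}`.

**Backboning.** With marginals `N_i` and total `N`, each edge's lift is
`c_ij = (κ N_ij − 1)/(κ N_ij + 1)`, `κ = N/(N_i N_j)`; a beta-binomial
posterior for the edge propensity gives `sd_ij`, and the backbone at
stringency δ keeps edges with `c_ij ≥ δ·sd_ij`. δ = 2.32 and δ = 1.28
correspond to one-sided normal tails of ≈1% and ≈0.1. Density-matched hard
thresholds, scale-free fit R² and average clustering are provided for
comparison and threshold selection.

**Evaluation & mining.** Gold standards from pathway co-membership or
interaction lists; tie-aware ROC/PR curves (AUC equals the tie-corrected
Mann–Whitney concordance), F1 = harmonic mean of AUC and AUPR; six node
centralities summarised as a per-gene median rank.

A synthetic module (acyclic ground-truth network with preferential
attachment, linear-Gaussian steady-state expression) makes the whole
pipeline testable end to end.

## Worked example

```python
from netweave import (TreeEnsembleParams, generate_grn, simulate_expression,
                      grn_to_gold_standard, infer_suite, irp_aggregate, roc_pr)

grn = generate_grn(n_genes=40, n_regulators=8, mean_out_degree=2, seed=0)
em  = simulate_expression(grn, n_samples=300, noise_sd=0.5, seed=1)
std = grn_to_gold_standard(grn)
nets = infer_suite(em, tree_params=TreeEnsembleParams(n_trees=100, seed=0))
community = irp_aggregate(nets).table
print(roc_pr(community, std).auc)
```

Running `python examples/infer_and_aggregate.py` (this exact workflow)
prints:

```
truth: 80 regulatory edges over 40 genes, 300 samples
         pearson: AUROC 0.626  AUPR 0.270
        spearman: AUROC 0.627  AUPR 0.268
            pcor: AUROC 0.883  AUPR 0.625
             tom: AUROC 0.602  AUPR 0.317
              mi: AUROC 0.625  AUPR 0.241
             clr: AUROC 0.703  AUPR 0.352
          aracne: AUROC 0.680  AUPR 0.377
   tree_ensemble: AUROC 0.733  AUPR 0.427
       community: AUROC 0.787  AUPR 0.439
```

The community network ranks true regulatory edges better (AUROC 0.787) than
the median single method (0.654): aggregation buffers each algorithm's
blind spots. The other scripts in `examples/` walk through backbone pruning
(`backbone_pruning.py`), gold-standard evaluation
(`evaluate_against_standard.py`) and centrality-based gene prioritisation
(`centrality_ranking.py`).

A thin CLI mirrors the workflow for shell use:

```
netweave simulate --n-genes 40 --out-expression expr.tsv --out-standard std.tsv
netweave infer pearson expr.tsv pearson.nw
netweave infer mi expr.tsv mi.nw
netweave aggregate pearson.nw mi.nw community.nw
netweave backbone community.nw pruned.nw --delta 1.28
netweave roc pruned.nw std.tsv roc.tsv
netweave stats pruned.nw centralities.tsv
```

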