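# Methods

This note documents the models, estimators and numerical choices behind
netweave, in the order the pipeline runs them.

## Preprocessing

Expression input is a samples × genes matrix of already-normalised values
(e.g. variance-stabilised counts). Three operations are provided, applied in
this order when all are wanted: removal of zero-variance genes, per-sample
median-centering (subtract each sample's median expression from every gene
in that sample, damping sample-level shifts), and per-gene z-scoring. One
variance convention is used throughout the package: sample variance with the
n−1 denominator. Partial correlation and the tree ensemble standardise their
input internally; the other methods consume the matrix as given, so callers
decide whether to z-score (`--scale` in the CLI).

## Inference methods

*Pearson / Spearman.* Plain pairwise correlation; Spearman is Pearson on
average-tie ranks. Both retain the sign in the stored score but declare
|score| as the edge strength — a strong negative correlation is a strong
association.

*Shrinkage partial correlation.* The empirical correlation matrix R is
shrunk toward the identity, `R* = λI + (1−λ)R`. When λ is not supplied it is
estimated analytically as `λ̂ = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²`, clipped
to [0, 1], where `Var̂(r_ij)` comes from the per-sample products of the
standardised data. Partial correlations are read off the inverse:
`p_ij = −ω_ij/√(ω_ii ω_jj)`, `Ω = (R*)⁻¹`. At λ = 0 the inverse may not
exist; the error suggests λ > 0. This estimator measures *conditional*
association and is the strongest method on the synthetic benchmark, where
indirect correlations are pervasive.

*Topological overlap (TOM).* Unsigned soft adjacency `a_ij = |r_ij|^β`
(default β = 6, the conventional unsigned choice), connectivity
`k_i = Σ_u a_iu`, shared-neighbourhood term `l_ij = Σ_u a_iu a_uj`, and
`TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) ∈ [0, 1]`.

*B-spline mutual information.* Each vector is rescaled to the spline domain
[0, b−k+1]; the b B-spline basis functions of order k assign every sample a
soft bin membership (a partition of unity). Marginal probabilities are mean
weights, the joint is the mean outer product, and
`MI = Σ_ij p_ij ln(p_ij/(p_i p_j))` in nats with 0·ln 0 := 0. Defaults
b = 10, k = 3 follow the estimator's common usage. At k = 1 the estimator
degenerates to an equal-width histogram MI, which the tests exploit as an
independent oracle. A constant vector maps all samples to identical weights
and contributes zero information.

*CLR.* Every MI value is z-scored against its two genes' row backgrounds
(excluding the diagonal, n−1 s.d.), negatives clamped to zero, combined as
`√(z_i(j)² + z_j(i)²)`. Zero-spread rows contribute zero.

*ARACNE / data-processing inequality.* For every triplet (i, j, k), edge
(i, j) is marked when `MI_ij < (1−ε)·min(MI_ik, MI_jk)`; marked edges are
zeroed only after the full scan, so the result is order-independent.
Default ε = 0 (strict DPI); equality never removes an edge. Strict DPI on a
dense MI matrix is aggressive by design: it retains roughly a
maximum-spanning-tree-like skeleton of locally maximal edges (see
Limitations).

*Tree ensemble (GENIE3-style).* Each gene is regressed on all other z-scored
genes with a random forest (default 1000 trees, √p candidate predictors per
split, impurity-based importance normalised to sum to one per target). The
output is directed; per-target seeds are derived deterministically from the
user seed.

## Aggregation

Within a method, edges are ranked by declared strength (1 = strongest,
average ranks for ties). Directed networks are folded to undirected by the
stronger orientation before ranking, since the community is evaluated as
undirected. An edge a method did not score gets the worst rank
`E_valid + 1` — penalised, not discarded. The community score is the inverse
rank product: with per-method ranks r₁…r_M, `IRP = (∏ r_m)^{1/M}` and the
aggregated weight is 1/IRP. The geometric mean (rather than the raw product)
keeps scores comparable across different numbers of methods. Aggregation is
permutation-invariant and monotone: improving an edge's rank in one method
can never worsen its community rank (both are asserted as property tests).

## Backboning and thresholds

The noise-corrected backbone treats the symmetric weight matrix's row sums
`N_i` and grand sum `N` as marginals. Edge lift is
`c_ij = (κ N_ij − 1)/(κ N_ij + 1)` with `κ = N/(N_i N_j)` — positive when
the edge is heavier than the marginals predict, invariant under global
weight rescaling. The noise model places a beta prior on the edge propensity
with mean `N_i N_j/N²` and a hypergeometric-style variance
`N_i N_j (N−N_i)(N−N_j) / (N⁴(N−1))`; after observing `N_ij` the
beta-binomial posterior variance is propagated through the score transform
by the delta method (including `N_ij`'s effect on its own marginals) to give
`sd_ij`. Only observed (positive-weight) edges are scored. The backbone at
stringency δ keeps edges with `c_ij ≥ δ·sd_ij` (closed boundary, so δ = 0
means "all positive-lift edges"); the default grid is 0.1, 0.2, …, 3.5 — 35
thresholds. δ = 2.32 and δ = 1.28 correspond to one-sided standard-normal
tail probabilities of ≈1% and ≈0.1.

For comparison, `prune_hard_matched` keeps exactly the requested number of
heaviest edges, breaking boundary ties by canonical edge order so
density-matching is exact and deterministic. Threshold diagnostics report
edge count, edge density `E/(n(n−1)/2)`, the scale-free fit R² (degrees
binned into 10 equal-width log₁₀ bins, log-frequency regressed on log-mean
degree over occupied bins) and the average clustering coefficient of the
binarised graph (degree < 2 nodes contribute zero). Networks at or below
0.1% edge density are dropped by the density floor (strict inequality), as
sparser networks cannot support stable ROC evaluation.

## Evaluation

Gold standards are sets of labelled unordered pairs over a declared
universe: pathway co-membership (positives share ≥1 pathway, negatives are
annotated pairs sharing none) or interaction lists (listed pairs positive,
every other in-universe pair negative — the convention for databases without
true negatives). Evaluation restricts to edges present in the network whose
both genes lie in the universe and whose pair carries a label; this
restriction is deliberate and recorded here because different restriction
rules change the negative set substantially.

Curves sweep edges by decreasing strength with tied scores processed as one
block. AUC is the trapezoid area over (FPR, TPR), which equals the
tie-corrected Mann–Whitney concordance (asserted against scipy at 1e−9);
AUPR uses rectangular interpolation over (recall, precision), the standard
PR convention (trapezoids overestimate). F1 is reported as the harmonic mean
of AUC and AUPR, with 0 reserved for the doubly-degenerate case. Evidence
bias is summarised as the n−1 variance of per-subset F1 deviations from the
full-standard F1, divided by |F1_full|. The in-group/out-group separation
test is a one-sided rank-sum (equivalent to a two-group Kruskal–Wallis) with
tie-corrected normal approximation.

## Centralities

Six statistics on the weighted undirected network: PageRank (damping 0.85),
strength (weighted degree), eigenvector centrality (nonnegative unit-norm
principal eigenvector of the adjacency), Laplacian centrality, betweenness
and closeness. Path-based statistics use edge length 1/weight — a heavier
edge is a shorter distance. Closeness uses the harmonic-sum convention
(normalised by n−1) uniformly, which stays finite on disconnected graphs;
since the downstream use is rank-only, this differs from classic closeness
only by a monotone change on connected graphs' scale. Laplacian centrality
is the absolute drop in Laplacian energy `E_L = Σ s_i² + Σ_{i≠j} w_ij²`
(= Σλ² of the Laplacian) when the node and its edges are removed, computed
by the closed form `s_v² + 2(Ws)_v + Σ_u w_uv²` and verified against
explicit node deletion and the eigenvalue identity. The prioritisation
summary ranks nodes within each metric (1 = most central, ties averaged) and
takes the per-node median across metrics.

## Synthetic benchmark

The generator emulates the essentials of a regulatory benchmark corpus
without external data: gene indices are a topological order; the first
`n_regulators` genes may regulate any downstream gene;
`round(mean_out_degree × n_genes)` distinct edges are attached by
preferential regulator selection (probability ∝ out-degree + 1), giving a
heavy-tailed out-degree distribution; effect sizes are ±Uniform(0.5, 1.5).
Expression follows the linear structural equations in topological order:
roots ~ N(0, 1), targets = Σ effect·regulator + N(0, noise_sd). This is a
steady-state linear-Gaussian model — it has no kinetics, no feedback loops,
no measurement-specific noise structure and unbounded variance growth down
regulatory cascades, so passing benchmarks here demonstrates that the
machinery ranks genuinely dependent pairs above independent ones, not that
any method performs equivalently on real transcriptomes.

The desk-scale benchmark configuration used by the test suite and
`scripts/acceptance.py` is 60 genes, 10 regulators, mean out-degree 3
(180 true edges among 1770 pairs), 400 samples, noise s.d. 0.5, three
replicates, with the tree ensemble at 100 trees — a problem size chosen so
the full eight-method pipeline runs in well under a minute per replicate on
one core while every code path is exercised at realistic signal-to-noise.

## Known limitations

- Strict DPI (ε = 0) under the dense-truth benchmark conditions (an average
  of three parents per target) removes many true edges of multi-parent
  targets: zeroed edges tie at the bottom of the ranking, and ARACNE's
  stand-alone AUROC sits near 0.55 there while the other seven methods
  exceed 0.6. This is the expected behaviour of the algorithm on such data,
  not an implementation artefact — the B-spline MI it consumes ranks edges
  as well as Pearson does, and the community network (which ARACNE joins)
  is unaffected. On sparser truths (see `examples/infer_and_aggregate.py`,
  2 parents per target on average) ARACNE clears 0.6 comfortably.
- The λ = 0 (no-shrinkage) partial-correlation path fails on singular
  correlation matrices by design; use λ > 0 or the analytic estimate.
- The edge-table text format targets transparency and round-trip fidelity
  (8 significant digits), not storage efficiency; gzip by file extension is
  the supported compression.
- Aggregation assumes each method's ranks are comparable in meaning; no
  per-method calibration beyond ranking is attempted.
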