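"""Ground-truth regulatory network and steady-state expression simulator.

Provides a desk-scale stand-in for benchmark expression corpora: a sparse
directed acyclic regulatory network with a heavy-tailed out-degree
distribution, linear-Gaussian steady-state expression sampled from it, and
the matching gold standard.  Every operation is deterministic given its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix, GoldStandard, _upair

__all__ = ["GroundTruthGRN", "generate_grn", "simulate_expression", "grn_to_gold_standard"]


@dataclass
class GroundTruthGRN:
    """Directed weighted regulator -> target edge list over an acyclic order.

    Gene indices are already a topological order (every edge points from a
    lower to a higher index), so expression can be sampled in one pass.
    """

    gene_ids: list[str]
    edges: list[tuple[int, int, float]]  # (regulator, target, signed effect)
    n_regulators: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def generate_grn(
    n_genes: int, n_regulators: int, mean_out_degree: float, seed: int
) -> GroundTruthGRN:
    """Sample a sparse acyclic regulatory network.

    The first ``n_regulators`` genes in topological order are regulators.
    ``round(mean_out_degree * n_genes)`` distinct edges are attached by
    preferential selection of the regulator (probability proportional to
    current out-degree + 1, producing a heavy-tailed out-degree
    distribution) with a uniformly chosen downstream target.  Effect sizes
    are +-Uniform(0.5, 1.5).
    """
    if not 1 <= n_regulators <= n_genes:
        raise ValueError("need 1 <= n_regulators <= n_genes")
    if mean_out_degree < 1:
        raise ValueError("mean_out_degree must be >= 1")
    rng = np.random.default_rng(seed)
    n_edges = int(round(mean_out_degree * n_genes))
    capacity = sum(n_genes - 1 - r for r in range(n_regulators))
    if n_edges > capacity:
        raise ValueError(
            f"{n_edges} edges requested but only {capacity} regulator-target "
            "pairs exist; increase n_regulators or n_genes"
        )
    out_deg = np.zeros(n_regulators)
    chosen: set[tuple[int, int]] = set()
    edges: list[tuple[int, int, float]] = []
    while len(edges) < n_edges:
        p = (out_deg + 1.0) / (out_deg + 1.0).sum()
        reg = int(rng.choice(n_regulators, p=p))
        tgt = int(rng.integers(reg + 1, n_genes))
        if (reg, tgt) in chosen:
            continue
        chosen.add((reg, tgt))
        effect = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
        edges.append((reg, tgt, float(effect)))
        out_deg[reg] += 1
    width = len(str(n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    return GroundTruthGRN(gene_ids, edges, n_regulators)


def simulate_expression(
    grn: GroundTruthGRN, n_samples: int, noise_sd: float, seed: int
) -> ExpressionMatrix:
    """Linear structural-equation sampling of steady-state expression.

    Regulator-free genes draw from Normal(0, 1); every regulated gene is the
    effect-weighted sum of its regulators plus Normal(0, noise_sd) noise.
    Columns come out in gene (topological) order.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = grn.n_genes
    parents: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for reg, tgt, eff in grn.edges:
        parents[tgt].append((reg, eff))
    x = np.empty((n_samples, n))
    for g in range(n):
        if not parents[g]:
            x[:, g] = rng.normal(0.0, 1.0, n_samples)
        else:
            x[:, g] = sum(eff * x[:, reg] for reg, eff in parents[g])
            if noise_sd > 0:
                x[:, g] += rng.normal(0.0, noise_sd, n_samples)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    return ExpressionMatrix(samples, list(grn.gene_ids), x)


def grn_to_gold_standard(grn: GroundTruthGRN) -> GoldStandard:
    """Gold standard from the true network: undirected true edges are the
    positives, every other pair a negative, universe = all genes."""
    ids = grn.gene_ids
    positives = {_upair(ids[r], ids[t]) for r, t, _ in grn.edges}
    negatives = {
        _upair(ids[i], ids[j])
        for i in range(grn.n_genes)
        for j in range(i)
        if _upair(ids[i], ids[j]) not in positives
    }
    return GoldStandard(set(ids), positives, negatives)
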