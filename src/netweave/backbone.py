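"""Noise-corrected backboning, hard thresholding and threshold diagnostics.

The backbone filter compares each observed edge weight against its
expectation under a null model driven by the two endpoints' total weight
(their marginals).  The lift score ``c_ij = (kappa N_ij - 1)/(kappa N_ij + 1)``
with ``kappa = N / (N_i N_j)`` is positive when the edge is heavier than the
marginals predict; a beta-binomial posterior for the edge propensity yields a
standard deviation for the score, and an edge survives pruning at stringency
``delta`` when ``c_ij >= delta * sd_ij``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import linregress

from .data import WeightedNetwork, n_pairs, pair_indices

__all__ = [
    "BackboneScores",
    "nc_backbone",
    "prune_delta",
    "delta_grid",
    "prune_hard_matched",
    "edge_density",
    "density_floor_filter",
    "sft_r2",
    "avg_clustering",
    "threshold_scan",
]


@dataclass
class BackboneScores:
    """Noise-corrected score and its posterior s.d. per observed edge.

    Arrays run over canonical edge order; entries are NaN for pairs the
    input network does not connect (only observed edges are scored).
    ``weights`` keeps the original edge weights for reconstruction after
    pruning.
    """

    gene_ids: list[str]
    weights: np.ndarray
    score: np.ndarray
    sd: np.ndarray


def nc_backbone(net: WeightedNetwork) -> BackboneScores:
    """Score every observed edge with the noise-corrected lift and its s.d.

    Marginals are the full symmetric matrix's row sums ``N_i`` and grand sum
    ``N``.  The propensity prior is beta with mean ``N_i N_j / N^2`` and a
    hypergeometric-style variance; the posterior after observing ``N_ij`` is
    propagated through the score transform by the delta method to give
    ``sd_ij``.
    """
    w = net.weights
    present = np.isfinite(w)
    if np.any(w[present] < 0):
        raise ValueError("backboning requires nonnegative edge weights")
    if not np.any(w[present] > 0):
        raise ValueError("network has no positive edge weights")
    mat = net.to_matrix(absent=0.0)
    ni = mat.sum(axis=1)
    n_tot = mat.sum()
    src, tgt = pair_indices(net.n_genes)

    score = np.full(w.shape, np.nan)
    sd = np.full(w.shape, np.nan)
    obs = present & (w > 0)
    a, b = src[obs], tgt[obs]
    nij = w[obs]
    na, nb = ni[a], ni[b]

    kappa = n_tot / (na * nb)
    kn = kappa * nij
    score[obs] = (kn - 1.0) / (kn + 1.0)

    # beta prior on the edge propensity from the marginals
    mean_p = na * nb / n_tot**2
    var_p = (na * nb * (n_tot - na) * (n_tot - nb)) / (n_tot**4 * (n_tot - 1.0))
    alpha0 = (mean_p**2 / var_p) * (1.0 - mean_p) - mean_p
    beta0 = (mean_p / var_p) * (1.0 - mean_p**2) - (1.0 - mean_p)
    alpha_post = alpha0 + nij
    beta_post = n_tot - nij + beta0
    exp_p = alpha_post / (alpha_post + beta_post)
    var_nij = exp_p * (1.0 - exp_p) * n_tot

    # delta method through c = (kappa(N_ij) * N_ij - 1)/(kappa(N_ij) * N_ij + 1),
    # accounting for N_ij's contribution to its own marginals
    d = 1.0 / (na * nb) - n_tot * (na + nb) / (na * nb) ** 2
    deriv = 2.0 * (kappa + nij * d) / (kn + 1.0) ** 2
    sd[obs] = np.sqrt(var_nij * deriv**2)
    return BackboneScores(list(net.gene_ids), w.copy(), score, sd)


def prune_delta(bb: BackboneScores, delta: float) -> WeightedNetwork:
    """Keep the edges whose lift exceeds ``delta`` standard deviations.

    An edge survives iff ``c_ij >= delta * sd_ij`` (closed boundary);
    retained edges carry their original weights.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    keep = np.isfinite(bb.score) & (bb.score >= delta * bb.sd)
    weights = np.where(keep, bb.weights, np.nan)
    return WeightedNetwork(list(bb.gene_ids), weights)


def delta_grid(lo: float = 0.1, hi: float = 3.5, step: float = 0.1) -> np.ndarray:
    """Inclusive arithmetic grid of backbone stringencies (default: 35 values)."""
    if step <= 0:
        raise ValueError("step must be > 0")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    count = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return np.round(lo + step * np.arange(count), 10)


def prune_hard_matched(net: WeightedNetwork, target_edge_count: int) -> WeightedNetwork:
    """Keep exactly the ``target_edge_count`` heaviest edges.

    Boundary ties are broken by canonical edge order so the result is
    deterministic and the edge count exact — the density-matched counterpart
    to a backbone-pruned network.
    """
    present = np.flatnonzero(net.present())
    if not 0 <= target_edge_count <= present.size:
        raise ValueError(
            f"target edge count {target_edge_count} outside [0, {present.size}]"
        )
    order = present[np.lexsort((present, -net.weights[present]))]
    keep = order[:target_edge_count]
    weights = np.full(net.weights.shape, np.nan)
    weights[keep] = net.weights[keep]
    return WeightedNetwork(list(net.gene_ids), weights)


def edge_density(net: WeightedNetwork) -> float:
    """Fraction of realised edges among all n(n-1)/2 possible pairs."""
    if net.n_genes < 2:
        raise ValueError("edge density needs at least 2 genes")
    return net.n_edges / n_pairs(net.n_genes)


def density_floor_filter(
    nets: list[WeightedNetwork], floor: float = 0.001
) -> list[WeightedNetwork]:
    """Drop networks whose edge density is not strictly above ``floor``."""
    return [net for net in nets if edge_density(net) > floor]


def _degrees(net: WeightedNetwork) -> np.ndarray:
    src, tgt = pair_indices(net.n_genes)
    ok = net.present()
    deg = np.zeros(net.n_genes, dtype=int)
    np.add.at(deg, src[ok], 1)
    np.add.at(deg, tgt[ok], 1)
    return deg


def sft_r2(net: WeightedNetwork, n_bins: int = 10) -> float:
    """Scale-free topology fit: R^2 of the log-log degree-distribution line.

    Positive node degrees are binned into ``n_bins`` equal-width bins in
    log10 space; log10(frequency) is regressed on log10(mean degree) over
    non-empty bins.  A power-law degree distribution gives R^2 near 1.
    """
    deg = _degrees(net)
    deg = deg[deg > 0]
    if np.unique(deg).size < 2:
        raise ValueError("scale-free fit undefined: fewer than 2 distinct degrees")
    logd = np.log10(deg)
    edges = np.linspace(logd.min(), logd.max(), n_bins + 1)
    which = np.clip(np.digitize(logd, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = deg[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / deg.size))
    if len(xs) < 2:
        raise ValueError("scale-free fit undefined: fewer than 2 occupied bins")
    fit = linregress(xs, ys)
    return float(fit.rvalue**2)


def to_graph(net: WeightedNetwork, with_weights: bool = True) -> nx.Graph:
    """networkx view of the present edges (all genes added as nodes)."""
    g = nx.Graph()
    g.add_nodes_from(net.gene_ids)
    src, tgt = pair_indices(net.n_genes)
    ok = net.present()
    for i, j, w in zip(src[ok], tgt[ok], net.weights[ok]):
        if with_weights:
            g.add_edge(net.gene_ids[i], net.gene_ids[j], weight=float(w))
        else:
            g.add_edge(net.gene_ids[i], net.gene_ids[j])
    return g


def avg_clustering(net: WeightedNetwork) -> float:
    """Mean local clustering coefficient of the binarised graph.

    Nodes of degree < 2 contribute zero, matching the transitivity lead
    statistic used for hard-threshold selection.
    """
    g = to_graph(net, with_weights=False)
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(g, count_zeros=True))


def threshold_scan(net: WeightedNetwork, grid: np.ndarray) -> pd.DataFrame:
    """Hard-threshold diagnostics across a cutoff grid.

    For each cutoff, edges with weight below it are pruned and the edge
    count, edge density, scale-free fit R^2 (NaN where the fit is undefined)
    and average clustering coefficient are recorded.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("cutoff grid must be non-empty")
    rows = []
    for cut in np.sort(grid):
        pruned = WeightedNetwork(
            list(net.gene_ids),
            np.where(net.present() & (net.weights >= cut), net.weights, np.nan),
        )
        try:
            r2 = sft_r2(pruned)
        except ValueError:
            r2 = np.nan
        rows.append(
            {
                "cutoff": float(cut),
                "n_edges": pruned.n_edges,
                "density": edge_density(pruned),
                "sft_r2": r2,
                "avg_clustering": avg_clustering(pruned),
            }
        )
    return pd.DataFrame(rows)
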