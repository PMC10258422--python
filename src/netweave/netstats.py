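"""Node centrality statistics and the median-rank gene prioritisation summary.

Six centralities are computed on the weighted undirected network: PageRank,
strength (weighted degree), eigenvector, Laplacian, betweenness and
closeness.  Path-based statistics use edge length 1/weight (heavier edge =
closer).  To summarise, nodes are ranked within each metric (1 = most
central, ties averaged) and the per-node median rank across metrics is
reported; lower means more central overall.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import WeightedNetwork
from .backbone import to_graph

__all__ = ["centralities", "median_rank_summary", "laplacian_energy", "METRICS"]

METRICS = ["page_rank", "strength", "eigenvector", "laplacian", "betweenness", "closeness"]


def laplacian_energy(w: np.ndarray) -> float:
    """Laplacian energy of a weighted adjacency matrix.

    E_L = sum_i s_i^2 + sum_{i != j} w_ij^2, which equals the sum of squared
    Laplacian eigenvalues.
    """
    s = w.sum(axis=1)
    return float(np.sum(s**2) + np.sum(w**2) - np.sum(np.diag(w) ** 2))


def centralities(net: WeightedNetwork, damping: float = 0.85) -> pd.DataFrame:
    """Six node centralities plus the median-rank summary.

    PageRank uses the stated damping on the weighted graph; eigenvector
    centrality is the nonnegative unit-norm principal eigenvector of the
    adjacency; betweenness (unnormalised) and closeness run on shortest
    paths with edge length 1/weight, closeness via the harmonic-sum
    convention (finite on disconnected graphs); Laplacian centrality is the
    drop in Laplacian energy when the node is removed.
    """
    if net.n_genes < 2:
        raise ValueError("need at least 2 nodes")
    w = net.to_matrix(absent=0.0)
    if np.any(w < 0):
        raise ValueError("centralities require nonnegative weights")
    genes = net.gene_ids
    n = len(genes)

    g = to_graph(net)
    for _, _, d in g.edges(data=True):
        d["dist"] = 1.0 / d["weight"] if d["weight"] > 0 else np.inf

    pr = nx.pagerank(g, alpha=damping, weight="weight")
    strength = w.sum(axis=1)

    evals, evecs = np.linalg.eigh(w)
    vec = evecs[:, -1]
    vec = np.abs(vec)
    norm = np.linalg.norm(vec)
    eig = vec / norm if norm > 0 else vec

    # energy drop when node v is removed: its own strength term, each
    # neighbour's strength shrinking by w_uv, and the incident edge terms:
    # drop_v = s_v^2 + sum_u (2 s_u w_uv - w_uv^2) + 2 sum_u w_uv^2
    #        = s_v^2 + 2 (W s)_v + sum_u w_uv^2
    s = strength
    sq = (w**2).sum(axis=1)
    lap = s**2 + 2.0 * (w @ s) + sq

    btw = nx.betweenness_centrality(g, normalized=False, weight="dist")
    close = nx.harmonic_centrality(g, distance="dist")

    table = pd.DataFrame(
        {
            "page_rank": [pr[g_] for g_ in genes],
            "strength": strength,
            "eigenvector": eig,
            "laplacian": lap,
            "betweenness": [btw[g_] for g_ in genes],
            "closeness": [close[g_] / (n - 1) for g_ in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    table["median_rank"] = median_rank_summary(table)
    return table


def median_rank_summary(tbl: pd.DataFrame) -> pd.Series:
    """Median per-node rank across centrality metrics (1 = most central)."""
    metrics = [c for c in tbl.columns if c != "median_rank"]
    if not metrics:
        raise ValueError("no centrality metrics present")
    ranks = np.column_stack(
        [rankdata(-tbl[c].to_numpy(), method="average") for c in metrics]
    )
    return pd.Series(np.median(ranks, axis=1), index=tbl.index, name="median_rank")
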