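"""Rank edges within each method and fuse networks by inverse rank product.

The community network scores every unordered gene pair by the geometric mean
of its per-method ranks (rank 1 = strongest edge).  The aggregated weight is
the inverse of that rank product, so larger means stronger, and a final
average-tie ranking over the weights gives the community rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import MethodNetwork, RankedEdgeTable

__all__ = ["AggregationResult", "rank_edges", "irp_aggregate", "aggregate_tables"]


@dataclass
class AggregationResult:
    """Community network plus per-edge support (number of scoring methods)."""

    table: RankedEdgeTable
    support: np.ndarray


def rank_edges(net: MethodNetwork) -> np.ndarray:
    """Per-edge ranks for one method in canonical edge order.

    Strength is |score| for methods that rank on magnitude, the raw score
    otherwise; directed networks are folded to undirected by the stronger
    orientation.  Rank 1 is the strongest edge, ties receive their average
    rank, and edges the method did not score get the worst rank
    ``E_valid + 1``.
    """
    strength = net.pair_strengths()
    valid = np.isfinite(strength)
    if not valid.any():
        raise ValueError(f"method {net.method_name!r} scored no edges")
    ranks = np.full(strength.shape, float(valid.sum() + 1))
    ranks[valid] = rankdata(-strength[valid], method="average")
    return ranks


def irp_aggregate(nets: list[MethodNetwork]) -> AggregationResult:
    """Aggregate one or more method networks by inverse rank product.

    Per edge, ``IRP = (prod_m r_m)^(1/M)`` — the geometric mean of the
    per-method ranks — and the community weight is ``1 / IRP``.  Networks
    must share the same gene set; differing orders are aligned to the first
    network's order.
    """
    if not nets:
        raise ValueError("need at least one network to aggregate")
    genes = list(nets[0].gene_ids)
    gset = set(genes)
    for net in nets[1:]:
        other = set(net.gene_ids)
        if other != gset:
            diff = sorted(gset.symmetric_difference(other))
            raise ValueError(
                f"gene sets differ between {nets[0].method_name!r} and "
                f"{net.method_name!r}: {diff[:10]}"
            )
    aligned = [_align(net, genes) for net in nets]
    names = _unique_names([net.method_name for net in nets])

    ranks = np.column_stack([rank_edges(net) for net in aligned])
    scores = np.column_stack([net.pair_scores() for net in aligned])
    support = np.isfinite(np.column_stack([net.pair_strengths() for net in aligned])).sum(axis=1)

    irp = np.exp(np.mean(np.log(ranks), axis=1))
    weight = 1.0 / irp
    agg_rank = rankdata(irp, method="average")
    table = RankedEdgeTable(genes, names, scores, ranks, weight, agg_rank)
    return AggregationResult(table, support)


def aggregate_tables(
    tables: list[RankedEdgeTable], methods: list[str] | None = None
) -> AggregationResult:
    """Inverse-rank-product aggregation of already-ranked edge tables.

    Used when method networks arrive as written files: per-method ranks are
    taken as stored (missing entries get the worst rank), concatenated
    across tables, optionally filtered to ``methods``, and fused exactly as
    :func:`irp_aggregate` would.
    """
    if not tables:
        raise ValueError("need at least one edge table")
    genes = list(tables[0].gene_ids)
    for t in tables[1:]:
        if list(t.gene_ids) != genes:
            diff = sorted(set(genes).symmetric_difference(t.gene_ids))
            raise ValueError(f"gene sets differ between tables: {diff[:10]}")
    names = _unique_names([m for t in tables for m in t.method_names])
    scores = np.column_stack([t.scores for t in tables])
    ranks = np.column_stack([t.ranks for t in tables]).astype(float)
    if methods is not None:
        keep = [k for k, name in enumerate(names) if name in set(methods)]
        missing = set(methods) - {names[k] for k in keep}
        if missing:
            raise ValueError(f"methods not present in inputs: {sorted(missing)}")
        names = [names[k] for k in keep]
        scores, ranks = scores[:, keep], ranks[:, keep]
    for m in range(ranks.shape[1]):
        col = ranks[:, m]
        miss = ~np.isfinite(col)
        if miss.all():
            raise ValueError(f"method {names[m]!r} scored no edges")
        col[miss] = float((~miss).sum() + 1)
    irp = np.exp(np.mean(np.log(ranks), axis=1))
    weight = 1.0 / irp
    agg_rank = rankdata(irp, method="average")
    support = np.isfinite(scores).sum(axis=1)
    table = RankedEdgeTable(genes, names, scores, ranks, weight, agg_rank)
    return AggregationResult(table, support)


def _align(net: MethodNetwork, genes: list[str]) -> MethodNetwork:
    if list(net.gene_ids) == genes:
        return net
    perm = [net.gene_ids.index(g) for g in genes]
    return MethodNetwork(
        list(genes),
        net.scores[np.ix_(perm, perm)],
        net.method_name,
        directed=net.directed,
        rank_on_absolute=net.rank_on_absolute,
        higher_is_stronger=net.higher_is_stronger,
    )


def _unique_names(names: list[str]) -> list[str]:
    out, seen = [], {}
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out
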