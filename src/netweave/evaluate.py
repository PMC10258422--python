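"""Gold standards, ROC/PR evaluation and edge-weight separation tests.

Networks are scored against labelled gene pairs: positives (pairs supported
by the standard) and negatives (explicitly listed, or implicitly every other
pair in the standard's universe).  Curves sweep edges by decreasing strength
with tied scores processed as a single block, so the ROC area equals the
tie-corrected Mann-Whitney concordance of positives over negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import mannwhitneyu

from .data import (
    GoldStandard,
    MethodNetwork,
    RankedEdgeTable,
    WeightedNetwork,
    _upair,
    pair_indices,
)

__all__ = [
    "CurveResult",
    "kegg_standard",
    "interaction_standard",
    "roc_pr",
    "f1_from_auc_aupr",
    "bias_table",
    "ingroup_outgroup_test",
    "rank_sum_onesided",
]


@dataclass
class CurveResult:
    """ROC / precision-recall sweep: one vertex per tied score block."""

    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    auc: float
    aupr: float
    n_pos: int
    n_neg: int


# ---------------------------------------------------------------------------
# gold-standard construction

def kegg_standard(membership: Mapping[str, set[str]]) -> GoldStandard:
    """Pathway co-membership standard.

    A positive edge joins two genes sharing at least one pathway; a negative
    edge joins two annotated genes sharing none.  The universe is the set of
    annotated genes.
    """
    if not membership:
        raise ValueError("empty membership table")
    genes = sorted(membership)
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if membership[a] & membership[b]:
                positives.add(_upair(a, b))
            else:
                negatives.add(_upair(a, b))
    return GoldStandard(set(genes), positives, negatives)


def interaction_standard(
    pairs: list[tuple[str, str]], universe: set[str]
) -> GoldStandard:
    """Interaction-list standard with implicit negatives.

    Listed pairs (deduplicated as undirected) are positives; every other
    pair within the universe is labelled negative, the convention for
    curated interaction databases that record no true negatives.
    """
    positives: set[tuple[str, str]] = set()
    for a, b in pairs:
        if a not in universe or b not in universe:
            missing = a if a not in universe else b
            raise ValueError(f"pair member {missing!r} is outside the universe")
        positives.add(_upair(a, b))
    genes = sorted(universe)
    negatives = {
        _upair(a, b)
        for i, a in enumerate(genes)
        for b in genes[i + 1 :]
        if _upair(a, b) not in positives
    }
    return GoldStandard(set(universe), positives, negatives)


# ---------------------------------------------------------------------------
# curves

def pair_strengths(net) -> tuple[list[str], np.ndarray]:
    """Canonical-order edge strengths of any network container.

    RankedEdgeTable contributes its aggregated weight, MethodNetwork its
    declared strength (|score| where applicable, directed folded by max) and
    WeightedNetwork its raw weights.  NaN marks an absent/unscored edge.
    """
    if isinstance(net, RankedEdgeTable):
        return list(net.gene_ids), net.agg_scores.copy()
    if isinstance(net, MethodNetwork):
        return list(net.gene_ids), net.pair_strengths()
    if isinstance(net, WeightedNetwork):
        return list(net.gene_ids), net.weights.copy()
    raise TypeError(f"unsupported network container: {type(net).__name__}")


def _labelled_strengths(net, std: GoldStandard) -> tuple[np.ndarray, np.ndarray]:
    """Strengths of evaluable edges and their labels (True = positive).

    Evaluable edges have both genes in the standard's universe, carry a
    label, and are present in the network.
    """
    genes, strengths = pair_strengths(net)
    src, tgt = pair_indices(len(genes))
    values, labels = [], []
    for e in range(strengths.size):
        if not np.isfinite(strengths[e]):
            continue
        a, b = genes[src[e]], genes[tgt[e]]
        if a not in std.universe or b not in std.universe:
            continue
        pair = _upair(a, b)
        if pair in std.positives:
            values.append(strengths[e])
            labels.append(True)
        elif pair in std.negatives:
            values.append(strengths[e])
            labels.append(False)
    return np.asarray(values, dtype=float), np.asarray(labels, dtype=bool)


def roc_pr(net, std: GoldStandard) -> CurveResult:
    """ROC and precision-recall curves of a network against a standard.

    Edges are swept in decreasing strength, tied scores as one block.  AUC
    is the trapezoid area over (FPR, TPR) — identical to the tie-corrected
    Mann-Whitney concordance — and AUPR uses step-wise (rectangular)
    interpolation over (recall, precision).
    """
    values, labels = _labelled_strengths(net, std)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"need at least one labelled positive and negative edge "
            f"(got {n_pos} positives, {n_neg} negatives)"
        )
    order = np.argsort(-values, kind="stable")
    values, labels = values[order], labels[order]
    # block boundaries: indices where the score changes
    boundary = np.flatnonzero(np.diff(values)) + 1
    ends = np.append(boundary, values.size)
    cum_tp = np.cumsum(labels)[ends - 1]
    cum_fp = np.cumsum(~labels)[ends - 1]
    tpr = cum_tp / n_pos
    fpr = cum_fp / n_neg
    precision = cum_tp / (cum_tp + cum_fp)
    auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
    recall_steps = np.diff(np.r_[0.0, tpr])
    aupr = float(np.sum(recall_steps * precision))
    return CurveResult(tpr, fpr, precision, auc, aupr, n_pos, n_neg)


def f1_from_auc_aupr(auc: float, aupr: float) -> float:
    """F1-style summary: harmonic mean of AUC and AUPR (0 when both are 0)."""
    for name, v in (("auc", auc), ("aupr", aupr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if auc == 0.0 and aupr == 0.0:
        return 0.0
    return 2.0 * auc * aupr / (auc + aupr)


def bias_table(f1_by_subset: Mapping[str, float], f1_full: float) -> float:
    """Robustness summary across evidence subsets: relative variance.

    The sample variance (n-1) of the per-subset deviations from the
    full-standard F1, divided by |F1_full|.  Lower means the method's
    performance depends less on the evidence type — less biased.
    """
    if len(f1_by_subset) < 2:
        raise ValueError("need at least 2 evidence subsets")
    devs = np.array([f1 - f1_full for f1 in f1_by_subset.values()])
    return float(np.var(devs, ddof=1) / abs(f1_full))


# ---------------------------------------------------------------------------
# edge-weight separation

def rank_sum_onesided(ingroup: np.ndarray, outgroup: np.ndarray) -> tuple[float, float]:
    """One-sided rank-sum test that the in-group is stochastically larger.

    For two groups this is the one-sided equivalent of a Kruskal-Wallis
    test; the tie-corrected normal approximation is used.
    """
    ingroup = np.asarray(ingroup, dtype=float)
    outgroup = np.asarray(outgroup, dtype=float)
    if ingroup.size == 0 or outgroup.size == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = mannwhitneyu(
        ingroup, outgroup, alternative="greater", method="asymptotic"
    )
    return float(stat), float(p)


def ingroup_outgroup_test(net, std: GoldStandard) -> tuple[float, float]:
    """Do edges present in the standard score higher than absent ones?

    In-group = network strengths of positive-labelled pairs, out-group =
    strengths of negative-labelled pairs; returns the rank-sum statistic and
    one-sided p-value for "in-group larger".
    """
    values, labels = _labelled_strengths(net, std)
    return rank_sum_onesided(values[labels], values[~labels])
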