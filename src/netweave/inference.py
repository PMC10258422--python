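"""Per-method gene network inference.

Implements the correlation group (Pearson, Spearman, shrinkage partial
correlation, topological overlap), the mutual-information group (B-spline MI
with CLR and data-processing-inequality post-processing) and a random-forest
regression method (GENIE3-style).  Every method returns a
:class:`~netweave.data.MethodNetwork` whose metadata declares how its scores
are turned into edge strengths for aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

from .data import ExpressionMatrix, MethodNetwork, zscore_genes

__all__ = [
    "MIParams",
    "TOMParams",
    "DPIParams",
    "TreeEnsembleParams",
    "infer_pearson",
    "infer_spearman",
    "infer_pcor",
    "infer_tom",
    "estimate_mi_bspline",
    "infer_mi",
    "clr_transform",
    "aracne_transform",
    "infer_tree_ensemble",
]


# ---------------------------------------------------------------------------
# parameter blocks

@dataclass
class MIParams:
    """B-spline MI estimator settings: ``n_bins`` basis functions of spline
    order ``spline_order`` (order 1 = plain histogram).  MI is reported in
    nats."""

    n_bins: int = 10
    spline_order: int = 3

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 1 <= self.spline_order <= self.n_bins:
            raise ValueError("spline_order must satisfy 1 <= k <= n_bins")


@dataclass
class TOMParams:
    """Topological overlap settings: unsigned soft-threshold power beta."""

    soft_power: float = 6.0

    def __post_init__(self) -> None:
        if self.soft_power <= 0:
            raise ValueError("soft_power must be > 0")


@dataclass
class DPIParams:
    """Data-processing-inequality tolerance epsilon in [0, 1] (0 = strict)."""

    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError("DPI tolerance must lie in [0, 1]")


@dataclass
class TreeEnsembleParams:
    """Random-forest regression settings for the GENIE3-style method."""

    n_trees: int = 1000
    candidate_predictors_per_split: str | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


# ---------------------------------------------------------------------------
# correlation group

def _corr_input(em: ExpressionMatrix, min_samples: int = 3) -> np.ndarray:
    if em.n_samples < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {em.n_samples}")
    sd = em.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = em.gene_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"gene {bad!r} has zero variance; run drop_zero_variance first")
    return em.values


def infer_pearson(em: ExpressionMatrix) -> MethodNetwork:
    """Pairwise Pearson correlation; strength is |r|."""
    x = _corr_input(em)
    r = np.corrcoef(x, rowvar=False)
    return MethodNetwork(list(em.gene_ids), r, "pearson", rank_on_absolute=True)


def infer_spearman(em: ExpressionMatrix) -> MethodNetwork:
    """Pairwise Spearman correlation (Pearson on average ranks); strength is |rho|."""
    x = _corr_input(em)
    ranks = np.apply_along_axis(rankdata, 0, x)
    r = np.corrcoef(ranks, rowvar=False)
    return MethodNetwork(list(em.gene_ids), r, "spearman", rank_on_absolute=True)


def _shrinkage_lambda(x: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    lambda-hat = sum_{i != j} Var-hat(r_ij) / sum_{i != j} r_ij^2, where the
    variance of each empirical correlation is estimated from the per-sample
    products of the standardised data, clipped to [0, 1].
    """
    n = x.shape[0]
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    s = xs.T @ xs  # (n-1) * r
    r = s / (n - 1)
    m2 = (xs**2).T @ (xs**2)
    # sum_k (w_kij - wbar_ij)^2 with w_kij = xs_ki * xs_kj
    ss = m2 - s**2 / n
    var_r = n / (n - 1) ** 3 * ss
    off = ~np.eye(x.shape[1], dtype=bool)
    denom = np.sum(r[off] ** 2)
    if denom == 0:
        return 1.0
    return float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))


def infer_pcor(em: ExpressionMatrix, shrinkage: float | str = "auto") -> MethodNetwork:
    """Shrinkage partial correlation.

    The empirical correlation matrix is shrunk toward the identity,
    ``R* = lambda I + (1 - lambda) R``, with lambda estimated analytically
    when ``shrinkage='auto'``; partial correlations come from the inverse,
    ``p_ij = -w_ij / sqrt(w_ii w_jj)`` with ``W = inv(R*)``.  Strength is
    |partial correlation|.
    """
    x = _corr_input(em)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    if shrinkage == "auto":
        lam = _shrinkage_lambda(x)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
    r = np.corrcoef(x, rowvar=False)
    n = r.shape[0]
    r_star = lam * np.eye(n) + (1.0 - lam) * r
    try:
        omega = np.linalg.inv(r_star)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "shrunk correlation matrix is singular; use shrinkage > 0"
        ) from exc
    d = np.sqrt(np.diag(omega))
    p = -omega / np.outer(d, d)
    return MethodNetwork(list(em.gene_ids), p, "pcor", rank_on_absolute=True)


def infer_tom(em: ExpressionMatrix, params: TOMParams | None = None) -> MethodNetwork:
    """Topological overlap on an unsigned soft-threshold adjacency.

    a_ij = |r_ij|^beta (diagonal zero); with k_i = sum_u a_iu and
    l_ij = sum_u a_iu a_uj, TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    which lies in [0, 1] and measures shared network neighbourhoods.
    """
    params = params or TOMParams()
    x = _corr_input(em)
    r = np.corrcoef(x, rowvar=False)
    a = np.abs(r) ** params.soft_power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # u = i, j terms vanish because diag(a) = 0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    return MethodNetwork(list(em.gene_ids), np.clip(tom, 0.0, 1.0), "tom")


# ---------------------------------------------------------------------------
# mutual-information group

def _bspline_weights(x: np.ndarray, n_bins: int, order: int) -> np.ndarray:
    """Per-sample B-spline basis membership weights, shape (n, n_bins).

    Values are affinely rescaled to the spline domain [0, b - k + 1]; each
    row sums to 1 (partition of unity).  A constant vector maps every sample
    to the same weights, making its entropy contribution zero.
    """
    b, k = n_bins, order
    deg = k - 1
    span = b - deg  # = b - k + 1
    knots = np.concatenate([np.zeros(deg), np.arange(span + 1), np.full(deg, span)])
    x = np.asarray(x, dtype=float)
    ptp = x.max() - x.min()
    if ptp == 0:
        xs = np.zeros_like(x)
    else:
        xs = (x - x.min()) / ptp * span
    xs = np.clip(xs, 0.0, span)
    w = BSpline.design_matrix(xs, knots, deg, extrapolate=False).toarray()
    return w


def estimate_mi_bspline(
    x: np.ndarray, y: np.ndarray, params: MIParams | None = None
) -> float:
    """B-spline mutual information between two sample vectors, in nats.

    Marginal bin probabilities are mean basis weights; the joint is the mean
    outer product.  At spline order 1 this reduces to an equal-width
    histogram estimator.
    """
    params = params or MIParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 samples for MI estimation")
    wx = _bspline_weights(x, params.n_bins, params.spline_order)
    wy = _bspline_weights(y, params.n_bins, params.spline_order)
    return _mi_from_weights(wx, wy)


def _mi_from_weights(wx: np.ndarray, wy: np.ndarray) -> float:
    n = wx.shape[0]
    px = wx.mean(axis=0)
    py = wy.mean(axis=0)
    joint = wx.T @ wy / n
    outer = np.outer(px, py)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))


def infer_mi(em: ExpressionMatrix, params: MIParams | None = None) -> MethodNetwork:
    """Pairwise raw B-spline MI network (the input to CLR / DPI pruning)."""
    params = params or MIParams()
    if em.n_samples < 4:
        raise ValueError("need at least 4 samples for MI estimation")
    weights = [
        _bspline_weights(em.values[:, g], params.n_bins, params.spline_order)
        for g in range(em.n_genes)
    ]
    n = em.n_genes
    mi = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i):
            mi[i, j] = mi[j, i] = _mi_from_weights(weights[i], weights[j])
    return MethodNetwork(list(em.gene_ids), mi, "mi")


def _check_mi_input(mi: MethodNetwork) -> np.ndarray:
    m = mi.scores.copy()
    np.fill_diagonal(m, 0.0)
    if np.any(m < 0):
        raise ValueError("MI input must be nonnegative")
    return m


def clr_transform(mi: MethodNetwork) -> MethodNetwork:
    """Context-likelihood-of-relatedness transform of an MI network.

    Each MI value is z-scored against the background of its two genes' rows
    (excluding the diagonal, sample s.d.), negative z-scores clamped to zero,
    and combined as CLR_ij = sqrt(z_i(j)^2 + z_j(i)^2).  Rows with zero
    spread contribute zero.
    """
    m = _check_mi_input(mi)
    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    rows = np.where(off, m, np.nan)
    mu = np.nanmean(rows, axis=1, keepdims=True)
    sd = np.nanstd(rows, axis=1, keepdims=True, ddof=1) if n > 2 else np.zeros((n, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - mu) / sd
    z = np.where(np.broadcast_to(sd, z.shape) > 0, z, 0.0)
    z = np.maximum(z, 0.0)
    clr = np.sqrt(z**2 + z.T**2)
    return MethodNetwork(list(mi.gene_ids), clr, "clr")


def aracne_transform(mi: MethodNetwork, params: DPIParams | None = None) -> MethodNetwork:
    """Data-processing-inequality pruning of an MI network.

    For every triplet (i, j, k) the edge (i, j) is marked for removal when
    MI_ij < (1 - eps) * min(MI_ik, MI_jk); marked edges are zeroed only after
    all triplets are scanned, so the result is order-independent.
    """
    params = params or DPIParams()
    m = _check_mi_input(mi)
    n = m.shape[0]
    keep_factor = 1.0 - params.tolerance
    marked = np.zeros_like(m, dtype=bool)
    for k in range(n):
        # min(MI_ik, MI_jk) for all (i, j); diagonal entries are 0 so rows
        # and columns touching k can never trigger a strict inequality.
        thresh = keep_factor * np.minimum.outer(m[:, k], m[:, k])
        marked |= m < thresh
    out = np.where(marked, 0.0, m)
    np.fill_diagonal(out, np.nan)
    return MethodNetwork(list(mi.gene_ids), out, "aracne")


# ---------------------------------------------------------------------------
# regression group

def infer_tree_ensemble(
    em: ExpressionMatrix, params: TreeEnsembleParams | None = None
) -> MethodNetwork:
    """GENIE3-style random-forest regression network.

    Each gene in turn is regressed on all other (z-scored) genes with a
    random forest; the edge weight regulator -> target is the regulator's
    impurity-based importance, normalised to sum to one per target.  The
    result is directed and deterministic given the seed.
    """
    params = params or TreeEnsembleParams()
    if em.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if em.n_samples < 5:
        raise ValueError("need at least 5 samples")
    em = zscore_genes(em)
    n = em.n_genes
    mf = params.candidate_predictors_per_split
    if isinstance(mf, str) and mf != "sqrt":
        raise ValueError("candidate_predictors_per_split must be 'sqrt' or a fraction")
    scores = np.zeros((n, n))
    for t in range(n):
        predictors = [g for g in range(n) if g != t]
        rf = RandomForestRegressor(
            n_estimators=params.n_trees,
            max_features=mf,
            random_state=(params.seed * 1_000_003 + t) % (2**31 - 1),
            n_jobs=1,
        )
        rf.fit(em.values[:, predictors], em.values[:, t])
        imp = rf.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        scores[predictors, t] = imp
    return MethodNetwork(
        list(em.gene_ids), scores, "tree_ensemble", directed=True
    )
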