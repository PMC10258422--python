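"""Per-method inference algorithms against hand-computed and brute-force oracles."""

import numpy as np
import pytest

from netweave.data import ExpressionMatrix
from netweave.evaluate import roc_pr
from netweave.inference import (
    DPIParams,
    MIParams,
    TOMParams,
    TreeEnsembleParams,
    aracne_transform,
    clr_transform,
    estimate_mi_bspline,
    infer_mi,
    infer_pcor,
    infer_pearson,
    infer_spearman,
    infer_tom,
    infer_tree_ensemble,
)
from netweave.synthetic import grn_to_gold_standard, GroundTruthGRN


def make_em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"s{i}" for i in range(values.shape[0])],
        [f"g{i}" for i in range(values.shape[1])],
        values,
    )


def offdiag(m):
    return m[~np.eye(m.shape[0], dtype=bool)]


class TestCorrelation:
    def test_pearson_perfect_linear(self):
        x = np.arange(5.0)
        net = infer_pearson(make_em(np.column_stack([x, 2 * x])))
        assert net.scores[1, 0] == pytest.approx(1.0)

    def test_pearson_sign_flip(self):
        x = np.arange(5.0)
        net = infer_pearson(make_em(np.column_stack([x, -x])))
        assert net.scores[1, 0] == pytest.approx(-1.0)

    def test_pearson_hand_value(self):
        net = infer_pearson(make_em([[1, 1], [2, 3], [3, 2], [4, 4]]))
        assert net.scores[1, 0] == pytest.approx(0.8)

    def test_spearman_monotone_invariance(self):
        x = np.arange(6.0)
        net = infer_spearman(make_em(np.column_stack([x, np.exp(x)])))
        assert net.scores[1, 0] == pytest.approx(1.0)

    def test_spearman_hand_value(self):
        net = infer_spearman(make_em([[1, 1], [2, 3], [3, 2], [4, 4]]))
        assert net.scores[1, 0] == pytest.approx(0.8)

    def test_spearman_antitone(self):
        x = np.arange(6.0)
        net = infer_spearman(make_em(np.column_stack([x, x[::-1]])))
        assert net.scores[1, 0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            infer_pearson(make_em([[1, 5], [2, 5], [3, 5]]))

    @pytest.mark.parametrize("method", [infer_pearson, infer_spearman])
    def test_symmetry_and_range(self, method, rng):
        net = method(make_em(rng.normal(size=(30, 8))))
        np.testing.assert_allclose(net.scores, net.scores.T, atol=1e-9)
        assert np.all(np.abs(offdiag(net.scores)) <= 1 + 1e-9)


class TestPartialCorrelation:
    def test_full_shrinkage_gives_zeros(self, rng):
        net = infer_pcor(make_em(rng.normal(size=(20, 5))), shrinkage=1.0)
        np.testing.assert_allclose(offdiag(net.scores), 0.0, atol=1e-12)

    def test_independent_genes_near_zero(self, rng):
        net = infer_pcor(make_em(rng.normal(size=(2000, 6))))
        assert np.all(np.abs(offdiag(net.scores)) < 0.1)

    def test_chain_conditional_independence(self, rng):
        # X -> Y -> Z: pcor(X, Z | Y) should vanish while pcor(X, Y) stays big,
        # matching the regression-residual estimate of the partial correlation.
        n = 2000
        x = rng.normal(size=n)
        y = x + 0.5 * rng.normal(size=n)
        z = y + 0.5 * rng.normal(size=n)
        net = infer_pcor(make_em(np.column_stack([x, y, z])))
        p_xy, p_xz = abs(net.scores[1, 0]), abs(net.scores[2, 0])
        assert p_xz < 0.1 < 0.5 < p_xy
        # residual oracle for the X-Z partial correlation given Y
        rx = x - np.polyval(np.polyfit(y, x, 1), y)
        rz = z - np.polyval(np.polyfit(y, z, 1), y)
        oracle = np.corrcoef(rx, rz)[0, 1]
        assert net.scores[2, 0] == pytest.approx(oracle, abs=0.05)

    def test_bad_shrinkage_rejected(self, rng):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            infer_pcor(make_em(rng.normal(size=(10, 3))), shrinkage=1.5)

    def test_recovers_sparse_precision_structure(self):
        # Data drawn from a known sparse Gaussian graphical model: true
        # conditional edges must rank above null edges by |pcor|.
        rng = np.random.default_rng(7)
        p = 20
        prec = np.eye(p)
        true_edges = [(i, i + 1) for i in range(0, p - 1, 2)]
        for i, j in true_edges:
            prec[i, j] = prec[j, i] = 0.45
        cov = np.linalg.inv(prec)
        x = rng.multivariate_normal(np.zeros(p), cov, size=500)
        net = infer_pcor(make_em(x))
        grn = GroundTruthGRN([f"g{i}" for i in range(p)],
                             [(i, j, 1.0) for i, j in true_edges], p)
        curve = roc_pr(net, grn_to_gold_standard(grn))
        assert curve.auc > 0.8


class TestTOM:
    def test_three_genes_perfectly_correlated(self, rng):
        x = rng.normal(size=12)
        for beta in (1.0, 6.0, 12.0):
            net = infer_tom(make_em(np.column_stack([x, 2 * x, -x])), TOMParams(beta))
            np.testing.assert_allclose(offdiag(net.scores), 1.0, atol=1e-9)

    def test_orthogonal_genes_zero_overlap(self):
        # exactly orthogonal, mean-zero columns: adjacency vanishes
        x = np.array([[1, 1, 1], [1, -1, 1], [-1, 1, 1], [-1, -1, -3.0]])
        x[:, 2] -= x[:, 2].mean()
        net = infer_tom(make_em(x[:, :2]))
        np.testing.assert_allclose(offdiag(net.scores), 0.0, atol=1e-12)

    def test_isolated_perfect_pair(self, rng):
        x = rng.normal(size=200)
        others = rng.normal(size=(200, 2))
        net = infer_tom(make_em(np.column_stack([x, x, others])), TOMParams(6.0))
        assert net.scores[1, 0] == pytest.approx(1.0, abs=1e-3)

    def test_range_and_symmetry(self, rng):
        net = infer_tom(make_em(rng.normal(size=(25, 7))))
        vals = offdiag(net.scores)
        assert np.all((vals >= 0) & (vals <= 1))
        np.testing.assert_allclose(net.scores, net.scores.T, atol=1e-9)

    def test_bad_power_rejected(self):
        with pytest.raises(ValueError, match="soft_power"):
            TOMParams(0.0)


def histogram_mi(x, y, b):
    """Independent equal-width histogram MI oracle (natural log)."""
    def bins(v):
        ptp = v.max() - v.min()
        if ptp == 0:
            return np.zeros(len(v), dtype=int)
        return np.minimum(((v - v.min()) / ptp * b).astype(int), b - 1)
    joint = np.zeros((b, b))
    for i, j in zip(bins(x), bins(y)):
        joint[i, j] += 1
    joint /= len(x)
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    mask = joint > 0
    return np.sum(joint[mask] * np.log(joint[mask] / np.outer(px, py)[mask]))


class TestBsplineMI:
    def test_identical_two_level_vectors(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert estimate_mi_bspline(x, x, MIParams(2, 1)) == pytest.approx(np.log(2))

    def test_product_form_joint_is_zero(self):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        assert estimate_mi_bspline(x, y, MIParams(2, 1)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        p = MIParams(8, 3)
        assert estimate_mi_bspline(x, y, p) == pytest.approx(
            estimate_mi_bspline(y, x, p), abs=1e-12
        )

    def test_order_one_equals_histogram_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            b = int(rng.integers(2, 12))
            n = int(rng.integers(10, 80))
            x, y = rng.normal(size=n), rng.normal(size=n)
            ours = estimate_mi_bspline(x, y, MIParams(b, 1))
            assert ours == pytest.approx(histogram_mi(x, y, b), abs=1e-9)

    def test_nonnegative(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=40), rng.normal(size=40)
            assert estimate_mi_bspline(x, y, MIParams(10, 3)) > -1e-12

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError, match="spline_order"):
            MIParams(3, 5)


class TestMINetwork:
    def test_two_gene_matrix_matches_pairwise(self, rng):
        x = rng.normal(size=(60, 2))
        net = infer_mi(make_em(x), MIParams(6, 2))
        expected = estimate_mi_bspline(x[:, 0], x[:, 1], MIParams(6, 2))
        assert net.scores[1, 0] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_gene_dominates_row(self, rng):
        x = rng.normal(size=(80, 4))
        x[:, 1] = x[:, 0]
        net = infer_mi(make_em(x))
        row0 = net.scores[0, 1:]
        assert np.nanargmax(row0) == 0  # the duplicate pair wins gene 0's row
        assert np.nanmax(net.scores[1, :]) == net.scores[1, 0]

    def test_independent_genes_small_mi(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1000, 2))
        net = infer_mi(make_em(x), MIParams(10, 3))
        assert net.scores[1, 0] < 0.05


class TestCLR:
    def test_constant_rows_give_zero(self):
        m = np.full((4, 4), 0.3)
        net = clr_transform(_mi_net(m))
        np.testing.assert_allclose(offdiag(net.scores), 0.0)

    def test_hand_example_clamps_both_z(self):
        m = np.array([[0, 0.1, 0.5], [0.1, 0, 0.3], [0.5, 0.3, 0]])
        net = clr_transform(_mi_net(m))
        assert net.scores[1, 0] == pytest.approx(0.0)

    def test_nonnegative_everywhere(self, rng):
        m = np.abs(rng.normal(size=(6, 6)))
        m = (m + m.T) / 2
        net = clr_transform(_mi_net(m))
        assert np.all(offdiag(net.scores) >= 0)

    def test_negative_input_rejected(self):
        m = np.full((3, 3), -0.1)
        with pytest.raises(ValueError, match="nonnegative"):
            clr_transform(_mi_net(m))


def _mi_net(m):
    from netweave.data import MethodNetwork

    m = np.asarray(m, dtype=float).copy()
    np.fill_diagonal(m, np.nan)
    return MethodNetwork([f"g{i}" for i in range(m.shape[0])], m, "mi")


class TestARACNE:
    def test_triplet_removes_weakest(self):
        m = np.array([[0, 0.5, 0.9], [0.5, 0, 0.8], [0.9, 0.8, 0]])
        net = aracne_transform(_mi_net(m), DPIParams(0.0))
        assert net.scores[1, 0] == 0.0
        assert net.scores[2, 0] == pytest.approx(0.9)
        assert net.scores[2, 1] == pytest.approx(0.8)

    def test_two_genes_unchanged(self):
        m = np.array([[0, 0.4], [0.4, 0]])
        net = aracne_transform(_mi_net(m))
        assert net.scores[1, 0] == pytest.approx(0.4)

    def test_tolerance_one_disables_pruning(self, rng):
        m = np.abs(rng.normal(size=(5, 5)))
        m = (m + m.T) / 2
        net = aracne_transform(_mi_net(m), DPIParams(1.0))
        np.testing.assert_allclose(offdiag(net.scores), offdiag((m + m.T) / 2))

    def test_output_elementwise_below_input(self, rng):
        m = np.abs(rng.normal(size=(8, 8)))
        m = (m + m.T) / 2
        net = aracne_transform(_mi_net(m))
        inp = m.copy()
        np.fill_diagonal(inp, 0)
        out = net.scores.copy()
        out[~np.isfinite(out)] = 0
        assert np.all(out <= inp + 1e-12)
        assert net.gene_ids == [f"g{i}" for i in range(8)]


class TestTreeEnsemble:
    def test_copied_regulator_gets_top_importance(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=(60, 4))
            x[:, 3] = x[:, 0] + 0.01 * rng.normal(size=60)
            net = infer_tree_ensemble(
                make_em(x), TreeEnsembleParams(n_trees=50, seed=seed)
            )
            assert np.nanargmax(net.scores[:, 3]) == 0

    def test_importances_sum_to_one_per_target(self, rng):
        x = rng.normal(size=(40, 5))
        net = infer_tree_ensemble(make_em(x), TreeEnsembleParams(n_trees=20, seed=1))
        sums = np.nansum(net.scores, axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(30, 4))
        p = TreeEnsembleParams(n_trees=25, seed=9)
        a = infer_tree_ensemble(make_em(x), p)
        b = infer_tree_ensemble(make_em(x), p)
        np.testing.assert_array_equal(
            np.nan_to_num(a.scores), np.nan_to_num(b.scores)
        )

    def test_invalid_tree_count_rejected(self):
        with pytest.raises(ValueError, match="n_trees"):
            TreeEnsembleParams(n_trees=0)
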