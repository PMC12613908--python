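"""Spearman input, graphical-lasso solver, EBIC selection, predictability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.covariance import graphical_lasso as sklearn_glasso

from psynet.ggm import (
    GaussianGraphicalModel,
    EstimationError,
    ebic_score,
    graphical_lasso_precision,
    nearest_psd_correlation,
    partial_corr_from_precision,
    spearman_matrix,
)


class TestSpearmanMatrix:
    def test_duplicated_column_has_unit_correlation(self):
        x = np.arange(10.0)
        R = spearman_matrix(pd.DataFrame({"a": x, "b": x + 3}))
        assert R.loc["a", "b"] == pytest.approx(1.0)

    def test_perfect_monotone_decrease(self):
        R = spearman_matrix(np.column_stack([[1, 2, 3, 4], [8, 6, 4, 2]]))
        assert R.iloc[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        # ranks differ by d = (0, -1, 1, -1, 1), sum d^2 = 4:
        # rho = 1 - 6*4/(5*24) = 0.8
        R = spearman_matrix(np.column_stack([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]]))
        assert R.iloc[0, 1] == pytest.approx(0.8)

    def test_zero_variance_column_names_the_node(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="flat"):
            spearman_matrix(df)

    def test_monotone_transform_invariance(self, default_nodes):
        R1 = spearman_matrix(default_nodes)
        transformed = default_nodes.copy()
        transformed["SOI_DES"] = np.exp(transformed["SOI_DES"])
        transformed["PHQ1"] = transformed["PHQ1"] ** 3 + 1
        R2 = spearman_matrix(transformed)
        np.testing.assert_allclose(R1.to_numpy(), R2.to_numpy(), atol=1e-12)

    def test_psd_repair_restores_unit_diagonal(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_psd_correlation(R)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)


class TestGraphicalLasso:
    def test_full_shrinkage_gives_empty_network(self, chain_sample):
        R = spearman_matrix(chain_sample).to_numpy()
        K, _ = graphical_lasso_precision(R, rho=1.0)
        W = partial_corr_from_precision(K)
        assert np.abs(W).max() == 0.0

    def test_two_nodes_unpenalized_partial_equals_marginal(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        K, _ = graphical_lasso_precision(R, rho=0.0)
        W = partial_corr_from_precision(K)
        assert W[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_sklearn_solver(self):
        # independent implementation of the same objective
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 8))
        X[:, 1] += 0.5 * X[:, 0]
        X[:, 2] += 0.4 * X[:, 1]
        R = np.corrcoef(X.T)
        for alpha in (0.3, 0.1, 0.03):
            _, prec_ref = sklearn_glasso(R, alpha=alpha, max_iter=2000, tol=1e-10)
            K, _ = graphical_lasso_precision(R, alpha, tol=1e-8, max_sweeps=2000)
            np.testing.assert_allclose(
                partial_corr_from_precision(K),
                partial_corr_from_precision(prec_ref),
                atol=2e-3,
            )

    def test_chain_support_recovered(self, chain_sample):
        m = GaussianGraphicalModel().fit(chain_sample)
        W = m.partial_corr_
        assert W[0, 1] != 0 and W[1, 2] != 0
        assert W[0, 2] == 0.0
        assert W[0, 1] == pytest.approx(0.4, abs=0.05)

    def test_edge_count_monotone_along_path(self, default_nodes):
        m = GaussianGraphicalModel(n_lambdas=40).fit(default_nodes)
        counts = m.edge_counts_  # alphas_ descending
        assert (np.diff(counts) >= 0).all()

    def test_weight_matrix_is_symmetric_zero_diagonal(self, default_nodes):
        m = GaussianGraphicalModel(n_lambdas=30).fit(default_nodes)
        W = m.partial_corr_
        np.testing.assert_allclose(W, W.T, atol=1e-12)
        assert np.abs(np.diag(W)).max() == 0.0
        assert np.abs(W).max() < 1.0

    def test_oracle_partial_correlations_at_lambda_zero(self):
        # p <= 4: unpenalized glasso equals matrix-inversion partials
        rng = np.random.default_rng(3)
        for p in (3, 4):
            A = rng.standard_normal((p, p)) * 0.3
            S = A @ A.T + np.eye(p)
            d = np.sqrt(np.diag(S))
            R = S / np.outer(d, d)
            K, _ = graphical_lasso_precision(R, rho=0.0)
            expected = partial_corr_from_precision(np.linalg.inv(R))
            np.testing.assert_allclose(
                partial_corr_from_precision(K), expected, atol=1e-6
            )

    def test_non_psd_input_rejected(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(EstimationError, match="PSD"):
            GaussianGraphicalModel().fit_correlation(R, 100)

    def test_ebic_counts_edges(self):
        K = np.array([[1.0, -0.2, 0.0], [-0.2, 1.0, 0.0], [0.0, 0.0, 1.0]])
        R = np.linalg.inv(K)
        d = np.sqrt(np.diag(R)); R = R / np.outer(d, d)
        _, E = ebic_score(K, R, 100, 0.5)
        assert E == 1


class TestPredictability:
    def test_isolated_node_has_zero_r2(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
        m = GaussianGraphicalModel().fit(X)  # independent data: empty net
        r2, _ = m.predictability(X)
        assert (r2 == 0).all()

    def test_exact_copy_gives_r2_one(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(400)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.standard_normal(400)})
        m = GaussianGraphicalModel().fit(X)
        r2, _ = m.predictability(X)
        assert r2["a"] == pytest.approx(1.0, abs=1e-6)

    def test_chain_center_matches_direct_ols(self, chain_sample):
        m = GaussianGraphicalModel().fit(chain_sample)
        r2, _ = m.predictability(chain_sample)
        # oracle: straight OLS of b on (a, c) in the same sample
        y = chain_sample["b"].to_numpy()
        A = np.column_stack(
            [np.ones(len(y)), chain_sample["a"], chain_sample["c"]]
        )
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        oracle = 1 - resid.var() / y.var()
        assert r2["b"] == pytest.approx(oracle, abs=0.03)

    def test_construct_averages_on_default_cohort(self, default_nodes):
        m = GaussianGraphicalModel(n_lambdas=40).fit(default_nodes)
        per_node, per_construct = m.predictability(default_nodes)
        assert ((per_node >= 0) & (per_node <= 1)).all()
        assert set(per_construct.index) == {
            "PHQ", "GAD", "UCLA", "RSES", "MSPSS", "SOI", "SIHS"
        }
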