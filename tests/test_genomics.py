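"""OLS/fold effects, Spearman scans, gene-set tests, mediation, ElasticNet,
housekeeping normalization and fold ranges."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmscreen.genomics import (
    elasticnet_cv,
    elasticnet_kkt_residual,
    expression_sensitivity_scan,
    fold_range,
    gene_set_shift_test,
    housekeeping_normalize,
    ic50_fold_effect,
    mediation,
    ols_fit,
)
from pharmscreen.simulate import ChainSimConfig, simulate_expression_chain


class TestOLS:
    def test_exact_linear_relation(self):
        X = pd.DataFrame({"a": [0.0, 1, 2, 3, 4], "b": [1.0, 0, 2, 1, 3]})
        y = 2.0 + 3.0 * X["a"] - 1.5 * X["b"]
        fit = ols_fit(y, X)
        assert fit.params["a"] == pytest.approx(3.0, abs=1e-10)
        assert fit.params["b"] == pytest.approx(-1.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_hand_normal_equations(self):
        X = pd.DataFrame({"x1": [1.0, 2, 3, 5], "x2": [0.0, 1, 1, 2]})
        y = np.array([1.0, 2.5, 3.1, 5.2])
        fit = ols_fit(y, X)
        A = np.column_stack([np.ones(4), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-12)
        assert fit.params["x1"] == pytest.approx(beta[1], abs=1e-12)
        assert fit.params["x2"] == pytest.approx(beta[2], abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = rng.normal(size=20)
        fit1 = ols_fit(y, X)
        perm = rng.permutation(20)
        fit2 = ols_fit(y[perm], X.iloc[perm].reset_index(drop=True))
        assert fit1.params["a"] == pytest.approx(fit2.params["a"])
        assert fit1.pvalues["b"] == pytest.approx(fit2.pvalues["b"])

    def test_closed_form_on_random_designs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n, p = int(rng.integers(10, 50)), int(rng.integers(1, 5))
            X = pd.DataFrame(rng.normal(size=(n, p)))
            y = rng.normal(size=n)
            fit = ols_fit(y, X)
            A = np.column_stack([np.ones(n), X.to_numpy()])
            beta = np.linalg.lstsq(A, y, rcond=None)[0]
            np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_collinear_design_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="collinear design"):
            ols_fit([1.0, 2, 3, 4], X)


class TestFoldEffect:
    def test_zero_and_unit_coefficients(self):
        assert ic50_fold_effect(0.0)["fold"] == pytest.approx(1.0)
        res = ic50_fold_effect(1.0)
        assert res["fold"] == pytest.approx(10.0)
        assert res["direction"] == "increase"

    def test_negative_coefficient_is_decrease(self):
        res = ic50_fold_effect(-np.log10(10.9), (-1.3, -0.8))
        assert res["fold"] == pytest.approx(10.9)
        assert res["direction"] == "decrease"
        assert res["fold_ci"][0] <= res["fold"] <= res["fold_ci"][1]


class TestSpearmanScan:
    def test_monotone_gene_rho_one(self):
        sens = np.array([1.0, 2, 3, 4, 5, 6])
        expr = pd.DataFrame({"s%d" % i: [np.exp(v)] for i, v in enumerate(sens)},
                            index=["g"])
        scan = expression_sensitivity_scan(expr, sens)
        assert scan.loc["g", "spearman_rho"] == pytest.approx(1.0)

    def test_matches_brute_force_rank_covariance(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(10, 5)),
                            index=[f"g{i}" for i in range(10)])
        sens = rng.normal(size=5)
        scan = expression_sensitivity_scan(expr, sens)
        for g in expr.index:
            rho, p = stats.spearmanr(expr.loc[g], sens)
            assert scan.loc[g, "spearman_rho"] == pytest.approx(rho, abs=1e-12)
            assert scan.loc[g, "p_value"] == pytest.approx(p, abs=1e-9)

    def test_constant_gene_reported_missing(self):
        expr = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]], index=["flat", "ok"])
        scan = expression_sensitivity_scan(expr, np.arange(5.0))
        assert np.isnan(scan.loc["flat", "spearman_rho"])
        assert np.isfinite(scan.loc["ok", "spearman_rho"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(5, 8)))
        sens = rng.normal(size=8)
        s1 = expression_sensitivity_scan(expr, sens)
        s2 = expression_sensitivity_scan(np.exp(expr), np.exp(sens))
        np.testing.assert_allclose(s1["spearman_rho"], s2["spearman_rho"],
                                   atol=1e-12)


class TestGeneSetShift:
    def test_power_with_shifted_set(self):
        rng = np.random.default_rng(5)
        rhos = pd.Series(rng.normal(0, 0.1, 1011),
                         index=[f"g{i}" for i in range(1011)])
        members = [f"g{i}" for i in range(11)]
        rhos[members] += 0.5
        _, p = gene_set_shift_test(rhos, members)
        assert p < 1e-6

    def test_empty_set_rejected(self):
        rhos = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError, match="non-empty"):
            gene_set_shift_test(rhos, ["zzz"])

    def test_paired_requires_pairing(self):
        rhos = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError, match="pairing required"):
            gene_set_shift_test(rhos, ["a"], mode="paired")


class TestMediation:
    def test_independent_mediator_leaves_marginal_unchanged(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        m = rng.normal(size=30)  # independent of exposure
        y = 2.0 * x  # noiseless direct effect
        res = mediation(y, x, m)
        assert res.conditional_exposure_coef == pytest.approx(
            res.marginal_exposure_coef, abs=1e-10)

    def test_collinear_mediator_rejected(self):
        x = np.arange(12.0)
        with pytest.raises(ValueError, match="collinear mediator"):
            mediation(np.arange(12.0), x, x * 2.0 + 1.0)

    def test_full_mediation_structure(self):
        cfg = ChainSimConfig(feature_effect=0.0, seed=7)
        expr, sens, _, _ = simulate_expression_chain(cfg)
        res = mediation(sens, np.log2(expr.loc["MYCN"] + 1),
                        np.log2(expr.loc["TOP2B"] + 1))
        assert res.marginal_exposure_p < 0.05
        assert res.conditional_exposure_p > 0.05
        assert res.conditional_mediator_p <= 0.01


class TestElasticNet:
    def test_large_lambda_all_zero(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        y = rng.normal(size=40)
        res = elasticnet_cv(X, y, lambda_grid=[1e6], k=5, seed=0)
        assert np.all(res.coefficients == 0)

    def test_zero_lambda_matches_ols(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(0, 0.1, 50)
        res = elasticnet_cv(X, y.to_numpy(), lambda_grid=[0.0], k=5, seed=0)
        A = np.column_stack([np.ones(50), X.to_numpy()])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(res.coefficients.to_numpy(), beta[1:],
                                   atol=1e-6)

    def test_kkt_conditions_at_solution(self):
        expr, _, feats, truth = simulate_expression_chain(
            ChainSimConfig(n_samples=88, seed=10))
        y = np.log2(expr.loc["TOP2B"].to_numpy(dtype=float) + 1.0)
        res = elasticnet_cv(feats, y, seed=10)
        Xs = ((feats - feats.mean()) / feats.std(ddof=0)).to_numpy()
        kkt = elasticnet_kkt_residual(
            Xs, y - y.mean(), res.coefficients_std, 0.0, res.lambda_, res.alpha)
        assert kkt <= 1e-6

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"ok": rng.normal(size=30), "flat": np.ones(30)})
        res = elasticnet_cv(X, rng.normal(size=30), k=5, seed=0)
        assert res.dropped == ["flat"]

    def test_too_few_samples_for_folds(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="too few samples"):
            elasticnet_cv(X, np.zeros(5), k=10)


class TestHousekeepingAndFoldRange:
    def test_equal_to_housekeeping_is_zero(self):
        expr = pd.DataFrame(
            {"s1": [100.0, 100.0, 100.0]}, index=["TOP2B", "ACTB", "GAPDH"])
        norm = housekeeping_normalize(expr, "TOP2B")
        assert norm["s1"] == pytest.approx(0.0)

    def test_fourfold_gene(self):
        expr = pd.DataFrame(
            {"s1": [4000.0, 1000.0, 1000.0]}, index=["TOP2B", "ACTB", "GAPDH"])
        assert housekeeping_normalize(expr, "TOP2B")["s1"] == pytest.approx(
            2.0, abs=0.01)

    def test_three_sample_hand_table(self):
        expr = pd.DataFrame(
            [[100.0, 200.0, 50.0], [50.0, 100.0, 100.0], [200.0, 100.0, 25.0]],
            index=["TOP2B", "ACTB", "GAPDH"], columns=["s1", "s2", "s3"])
        norm = housekeeping_normalize(expr, "TOP2B")
        for s in expr.columns:
            expected = np.log2(expr.loc["TOP2B", s] + 1) - 0.5 * (
                np.log2(expr.loc["ACTB", s] + 1) + np.log2(expr.loc["GAPDH", s] + 1))
            assert norm[s] == pytest.approx(expected, abs=1e-12)

    def test_missing_housekeeping_gene(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["TOP2B"])
        with pytest.raises(ValueError, match="housekeeping gene absent"):
            housekeeping_normalize(expr, "TOP2B")

    def test_fold_range_examples(self):
        assert fold_range([1.0, 2.0, 8.0]) == pytest.approx(8.0)
        assert fold_range([3.0, 3.0, 3.0]) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="non-positive"):
            fold_range([1.0, -2.0])
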