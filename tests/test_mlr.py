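"""The multiple logistic regression core: IRLS, Wald, LRT, interactions, L1."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import kstest

from tadborder.binning import FeatureMatrix, assemble_matrix
from tadborder.enrichment import enrichment_test
from tadborder.mlr import (
    BorderLogit,
    CollinearityError,
    ConvergenceError,
    all_pairs,
    expand_interactions,
    fit_logistic_irls,
    fit_logistic_l1,
    fit_metrics,
    lrt,
    wald_inference,
)


def matrix_of(Y, X, names=None, mode="coordinate"):
    names = names or [f"x{j + 1}" for j in range(np.atleast_2d(X.T).T.shape[1])]
    return FeatureMatrix(Y=np.asarray(Y), X=np.asarray(X, dtype=float),
                         feature_names=names, mode=mode)


def reference_mle(X, y):
    """Independent oracle: generic numerical maximum likelihood."""
    design = np.column_stack([np.ones(len(y)), X])

    def negll(beta):
        mu = np.clip(expit(design @ beta), 1e-12, 1 - 1e-12)
        return -np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))

    def grad(beta):
        mu = expit(design @ beta)
        return -design.T @ (y - mu)

    res = minimize(negll, np.zeros(design.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x


class TestIRLS:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 25 + [0] * 75)
        m = matrix_of(y, np.empty((100, 0)), names=[])
        fit = fit_logistic_irls(m)
        assert fit.beta0 == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2)

    def test_single_binary_feature_matches_enrichment_test(self):
        Y = np.concatenate([np.ones(5500), np.zeros(202000)])
        x = np.concatenate([np.ones(500), np.zeros(5000), np.ones(2000), np.zeros(200000)])
        fit = fit_logistic_irls(matrix_of(Y, x.reshape(-1, 1)))
        et = enrichment_test(Y, x)
        assert fit.betas.iloc[0] == pytest.approx(np.log(10), abs=1e-6)
        assert fit.betas.iloc[0] == pytest.approx(et.beta, abs=1e-8)
        assert fit.bse.iloc[1] == pytest.approx(et.se, rel=1e-6)

    def test_agrees_with_generic_mle_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(80, 400))
            p = int(rng.integers(1, 5))
            X = rng.random((n, p)) < 0.4
            beta = rng.normal(0, 1, p)
            y = (rng.random(n) < expit(-1.0 + X @ beta)).astype(float)
            if y.sum() < 3 or y.sum() > n - 3:
                continue
            try:
                fit = fit_logistic_irls(matrix_of(y, X.astype(float)))
            except (ConvergenceError, CollinearityError):
                continue
            oracle = reference_mle(X.astype(float), y)
            np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-6)

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 600
        X = (rng.random((n, 3)) < 0.3).astype(float)
        y = (rng.random(n) < expit(-1.5 + X @ np.array([1.0, -0.5, 0.3]))).astype(float)
        fit = fit_logistic_irls(matrix_of(y, X))
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, rtol=1e-4)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_collapse_fast_path_is_exact(self, rng):
        # binary design triggers internal pattern collapsing; forcing the
        # row-level path via a non-binary epsilon column must agree
        n = 30000
        X = (rng.random((n, 3)) < 0.1).astype(float)
        y = (rng.random(n) < expit(-2.5 + X @ np.array([1.0, 0.5, -0.8]))).astype(float)
        fit_fast = fit_logistic_irls(matrix_of(y, X))
        X_slow = X.copy()
        X_slow[0, 0] += 1e-12  # breaks binarity, not the solution
        fit_slow = fit_logistic_irls(matrix_of(y, X_slow))
        np.testing.assert_allclose(
            fit_fast.params.to_numpy(), fit_slow.params.to_numpy(), atol=1e-6
        )
        assert fit_fast.llf == pytest.approx(fit_slow.llf, abs=1e-5)

    def test_freq_weights_equal_expanded_rows(self):
        Xc = np.array([[0.0], [1.0], [0.0], [1.0]])
        yc = np.array([0.0, 0.0, 1.0, 1.0])
        w = np.array([50.0, 30.0, 10.0, 20.0])
        collapsed = BorderLogit(yc, Xc, ["x"], freq_weights=w).fit()
        X = np.repeat(Xc, w.astype(int), axis=0)
        y = np.repeat(yc, w.astype(int))
        expanded = BorderLogit(y, X, ["x"]).fit()
        np.testing.assert_allclose(
            collapsed.params.to_numpy(), expanded.params.to_numpy(), atol=1e-8
        )
        assert collapsed.llf == pytest.approx(expanded.llf)

    def test_coverage_of_true_parameters(self, rng):
        # MLE +/- 3 SE covers the truth for nearly all coefficients
        from tadborder.simulate import simulate_logistic_response, synth_feature_matrix

        hits = total = 0
        for seed in range(5):
            X = synth_feature_matrix(100_000, 6, seed=rng)
            ds = simulate_logistic_response(X, rng)
            try:
                fit = fit_logistic_irls(ds.to_feature_matrix())
            except ConvergenceError:
                continue
            err = np.abs(fit.betas.to_numpy() - ds.true_betas)
            hits += int((err < 3 * fit.bse.to_numpy()[1:]).sum())
            total += 6
        assert hits / total >= 0.85

    def test_separation_raises_with_diagnostics(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(ConvergenceError) as exc_info:
            fit_logistic_irls(matrix_of(y, x.reshape(-1, 1)))
        assert exc_info.value.last_params is not None

    def test_collinear_columns_named(self, rng):
        n = 500
        x1 = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        X = np.column_stack([x1, x1])
        with pytest.raises(CollinearityError) as exc_info:
            fit_logistic_irls(matrix_of(y, X, names=["a", "a_dup"]))
        assert "a_dup" in exc_info.value.columns or "a" in exc_info.value.columns

    def test_requires_both_classes(self):
        with pytest.raises(ValueError, match="both classes"):
            BorderLogit(np.zeros(10), np.ones((10, 1)))


class TestWaldInference:
    def test_statistic_arithmetic(self):
        assert 2.3026 / 0.5 == pytest.approx(4.6052)

    def test_wald_frame_values(self, rng):
        n = 4000
        x = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < expit(-2.0 + 1.2 * x)).astype(float)
        fit = fit_logistic_irls(matrix_of(y, x.reshape(-1, 1), names=["f"]))
        frame = wald_inference(fit, alpha=0.05)
        row = frame.loc["f"]
        assert row["W"] == pytest.approx(row["beta"] / row["se"])
        from scipy.stats import norm

        assert row["p_value"] == pytest.approx(2 * norm.sf(abs(row["W"])))
        assert row["ci_low"] == pytest.approx(row["beta"] - norm.ppf(0.975) * row["se"])

    def test_bonferroni_divisor(self, rng):
        n = 6000
        X = (rng.random((n, 4)) < 0.3).astype(float)
        y = (rng.random(n) < expit(-2.0 + 0.8 * X[:, 0])).astype(float)
        fit = fit_logistic_irls(matrix_of(y, X))
        frame = wald_inference(fit, alpha=0.05, n_tests=4)
        assert (frame["significant"] == (frame["p_value"] < 0.05 / 4)).all()

    def test_l1_fit_has_no_wald(self, rng):
        n = 2000
        X = (rng.random((n, 3)) < 0.3).astype(float)
        y = (rng.random(n) < 0.2).astype(float)
        fit = fit_logistic_l1(matrix_of(y, X), lambda_grid=np.array([0.01]), n_folds=3)
        with pytest.raises(ValueError, match="L1"):
            wald_inference(fit)


class TestLRT:
    def test_all_zero_column_gives_null_result(self, rng):
        n = 500
        x = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        m = matrix_of(y, np.column_stack([x, np.zeros(n)]), names=["a", "z"])
        res = lrt(m, "z")
        assert res.D == 0.0 and res.p_value == 1.0 and res.df == 1

    def test_causal_feature_detected(self, rng):
        n = 50000
        x = (rng.random(n) < 0.05).astype(float)
        y = (rng.random(n) < expit(-3.0 + 2.0 * x)).astype(float)
        res = lrt(matrix_of(y, x.reshape(-1, 1), names=["c"]), "c")
        assert res.D > 20
        assert res.p_value < 1e-5

    def test_unknown_feature_rejected(self, rng):
        m = matrix_of(np.array([0, 1, 0, 1]), np.array([[0.0], [1.0], [1.0], [0.0]]))
        with pytest.raises(KeyError):
            lrt(m, "nope")

    def test_null_distribution_is_chi2_1(self, rng):
        # D for a null feature over replicates follows chi-squared(1)
        stats = []
        for _ in range(300):
            n = 1500
            x1 = (rng.random(n) < 0.4).astype(float)
            xnull = (rng.random(n) < 0.4).astype(float)
            y = (rng.random(n) < expit(-1.0 + 0.5 * x1)).astype(float)
            try:
                res = lrt(matrix_of(y, np.column_stack([x1, xnull]),
                                    names=["a", "null"]), "null")
            except RuntimeError:
                continue
            stats.append(res.D)
        ks = kstest(stats, "chi2", args=(1,))
        assert ks.pvalue > 0.01

    def test_wald_close_to_lrt_on_dense_data(self, rng):
        n = 20000
        x = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < expit(-0.5 + 0.4 * x)).astype(float)
        m = matrix_of(y, x.reshape(-1, 1), names=["f"])
        fit = fit_logistic_irls(m)
        p_w = fit.pvalues.loc["f"]
        p_l = lrt(m, "f").p_value
        assert abs(np.log10(p_w) - np.log10(p_l)) < 1.0


class TestInteractions:
    def test_product_column(self):
        m = matrix_of(np.array([0, 1, 0]), np.array([[1, 1], [0, 1], [1, 0]], dtype=float),
                      names=["X1", "X2"])
        out = expand_interactions(m, [("X1", "X2")])
        np.testing.assert_allclose(out.X[:, 2], [1, 0, 0])
        assert out.feature_names[-1] == "X1:X2"

    def test_fractional_product(self):
        m = matrix_of(np.array([0, 1]), np.array([[0.5, 0.5], [1.0, 0.0]]),
                      names=["a", "b"])
        out = expand_interactions(m, [("a", "b")])
        assert out.X[0, 2] == pytest.approx(0.25)

    def test_empty_spec_is_identity(self):
        m = matrix_of(np.array([0, 1]), np.array([[1.0], [0.0]]), names=["a"])
        out = expand_interactions(m, [])
        assert out.feature_names == ["a"]
        np.testing.assert_array_equal(out.X, m.X)

    def test_missing_feature_rejected(self):
        m = matrix_of(np.array([0, 1]), np.array([[1.0], [0.0]]), names=["a"])
        with pytest.raises(KeyError):
            expand_interactions(m, [("a", "b")])

    def test_all_pairs_count(self):
        assert len(all_pairs(["a", "b", "c", "d"])) == 6


class TestConditionalIndependence:
    """The two discriminating scenarios that motivate the joint model."""

    def test_colocalized_passenger_zeroed_by_mlr(self, rng):
        # A causal, B = noisy copy of A: ET sees both, MLR only A
        n = 150_000
        xa = (rng.random(n) < 0.03).astype(float)
        flip = rng.random(n) < 0.01
        xb = np.abs(xa - flip.astype(float))
        y = (rng.random(n) < expit(-4.0 + 2.0 * xa)).astype(float)
        et_b = enrichment_test(y, xb, feature="B")
        assert et_b.beta > 0.5 and et_b.p_value < 1e-5
        fit = fit_logistic_irls(matrix_of(y, np.column_stack([xa, xb]),
                                          names=["A", "B"]))
        assert fit.betas["A"] > 1.0
        ci = fit.conf_int()
        assert ci.loc["B", "ci_low"] < 0 < ci.loc["B", "ci_high"]

    def test_pure_interaction_effect_found_only_in_product_term(self, rng):
        n = 200_000
        xa = (rng.random(n) < 0.15).astype(float)
        xb = (rng.random(n) < 0.15).astype(float)
        y = (rng.random(n) < expit(-3.5 + 2.5 * xa * xb)).astype(float)
        m = expand_interactions(
            matrix_of(y, np.column_stack([xa, xb]), names=["A", "B"]), [("A", "B")]
        )
        fit = fit_logistic_irls(m)
        frame = wald_inference(fit, alpha=1e-3, n_tests=3)
        assert frame.loc["A:B", "beta"] > 1.0 and frame.loc["A:B", "significant"]
        ci = fit.conf_int()
        for name in ("A", "B"):
            assert ci.loc[name, "ci_low"] < 0 < ci.loc[name, "ci_high"]


class TestL1:
    def test_heavy_penalty_shrinks_all_to_zero(self, rng):
        n = 3000
        X = (rng.random((n, 4)) < 0.3).astype(float)
        y = (rng.random(n) < expit(-1.0 + X @ np.array([1.0, 0, 0, -0.5]))).astype(float)
        fit = fit_logistic_l1(matrix_of(y, X), lambda_grid=np.array([10.0]), n_folds=3)
        assert (fit.betas == 0).all()
        ybar = y.mean()
        assert fit.beta0 == pytest.approx(np.log(ybar / (1 - ybar)), abs=0.02)

    def test_vanishing_penalty_matches_irls(self, rng):
        n = 4000
        X = (rng.random((n, 3)) < 0.4).astype(float)
        y = (rng.random(n) < expit(-1.0 + X @ np.array([0.8, -0.4, 0.2]))).astype(float)
        m = matrix_of(y, X)
        l1 = fit_logistic_l1(m, lambda_grid=np.array([1e-9]), n_folds=3)
        irls = fit_logistic_irls(m)
        np.testing.assert_allclose(
            l1.params.to_numpy(), irls.params.to_numpy(), atol=1e-4
        )

    def test_cv_selects_support_recovering_lambda(self, rng):
        # scaled-down analogue of selecting among hundreds of motifs:
        # 40 sparse correlated candidates, 5 causal
        from tadborder.simulate import synth_feature_matrix

        n, p = 30_000, 40
        X = synth_feature_matrix(n, p, sparsity=0.9, correlation=0.1, seed=rng)
        causal = [0, 9, 19, 29, 39]
        beta = np.zeros(p)
        beta[causal] = 2.0
        y = (rng.random(n) < expit(-2.5 + X @ beta)).astype(float)
        fit = fit_logistic_l1(
            matrix_of(y, X, names=[f"m{j}" for j in range(p)]),
            n_lambdas=25, n_folds=4, seed=3,
        )
        support = set(fit.support)
        assert sum(f"m{j}" in support for j in causal) >= 4
        assert fit.lambda_ is not None and fit.method == "l1"

    def test_all_zero_design_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_logistic_l1(
                matrix_of(np.array([0, 1, 0, 1]), np.zeros((4, 1))),
                lambda_grid=np.array([0.1]), n_folds=2,
            )


class TestFitMetrics:
    def test_intercept_only_aic(self):
        y = np.array([1] * 10 + [0] * 30)
        fit = fit_logistic_irls(matrix_of(y, np.empty((40, 0)), names=[]))
        ratio, aic = fit_metrics(fit)
        assert aic == pytest.approx(-2 * fit.llf + 2)
        assert ratio == pytest.approx(1.0)

    def test_deviance_ratio_variants(self, rng):
        n = 5000
        x = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < expit(-1.0 + 1.5 * x)).astype(float)
        fit = fit_logistic_irls(matrix_of(y, x.reshape(-1, 1)))
        assert 0 < fit.deviance_ratio() < 1
        assert fit.deviance_ratio(explained=True) == pytest.approx(
            1 - fit.deviance_ratio()
        )

    def test_aic_improves_with_causal_feature(self, rng):
        n = 30000
        x = (rng.random(n) < 0.1).astype(float)
        y = (rng.random(n) < expit(-2.5 + 1.5 * x)).astype(float)
        with_x = fit_logistic_irls(matrix_of(y, x.reshape(-1, 1)))
        without = fit_logistic_irls(matrix_of(y, np.empty((n, 0)), names=[]))
        assert with_x.aic < without.aic

    def test_near_perfect_fit_drives_deviance_down(self, rng):
        # deterministic-in-the-limit response: fitted deviance shrinks
        # far below the null deviance
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < expit(-4.0 + 8.0 * x)).astype(float)
        fit = fit_logistic_irls(matrix_of(y, x.reshape(-1, 1)))
        assert fit.deviance_ratio() < 0.15


def test_summary_renders(rng):
    n = 2000
    x = (rng.random(n) < 0.3).astype(float)
    y = (rng.random(n) < expit(-1.0 + x)).astype(float)
    fit = fit_logistic_irls(matrix_of(y, x.reshape(-1, 1), names=["BEAF32"]))
    text = fit.summary()
    assert "BEAF32" in text and "AIC" in text and "irls" in text
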