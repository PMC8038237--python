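import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import tiltam as tm
from tiltam import TermSpec, backfit, model_df, predict
from tiltam.local_linear import cv_bandwidth, weight_matrix


class TestBackfit:
    def test_single_smooth_term_equals_direct_smoother(self, sine_data):
        x, y, _ = sine_data
        X = pd.DataFrame({"x": x})
        h = cv_bandwidth(x, y)
        fit = backfit(y, X, [TermSpec("x", "smooth", bandwidth=h, tilt=False)])
        direct = weight_matrix(x, x, h) @ (y - y.mean()) + y.mean()
        fitted = fit.intercept + fit.contributions["x"]
        assert np.abs(fitted - direct).max() < 1e-8

    def test_constant_outcome(self, rng):
        X = pd.DataFrame({"a": rng.uniform(0, 1, 60), "b": rng.standard_normal(60)})
        y = np.full(60, 4.2)
        fit = backfit(y, X, [TermSpec("a", "smooth"), TermSpec("b", "linear")])
        assert fit.intercept == pytest.approx(4.2, abs=1e-8)
        for v in fit.contributions.values():
            np.testing.assert_allclose(v, 0.0, atol=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_identity_and_centering(self, two_term_data):
        X, y, _, terms = two_term_data
        fit = backfit(y, X, terms)
        total = fit.intercept + sum(fit.contributions.values()) + fit.residuals
        np.testing.assert_allclose(total, y, atol=1e-10)
        assert abs(fit.contributions["x1"].mean()) < 1e-8  # smooth centred
        assert fit.rss == pytest.approx(float(fit.residuals @ fit.residuals), rel=1e-10)

    def test_rss_nonincreasing_over_sweeps(self, two_term_data):
        X, y, _, terms = two_term_data
        fit = backfit(y, X, terms)
        path = np.asarray(fit.rss_path)
        assert np.all(np.diff(path) <= 1e-10 * (1.0 + path[:-1]))

    def test_all_linear_equals_ols(self, rng):
        n = 150
        Z = rng.standard_normal((n, 4))
        y = 2.0 + Z @ [1.0, -0.5, 0.25, 3.0] + rng.normal(0, 0.5, n)
        X = pd.DataFrame(Z, columns=list("abcd"))
        fit = backfit(y, X, [TermSpec(c, "linear") for c in "abcd"])
        ref = sm.OLS(y, sm.add_constant(Z)).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        for i, c in enumerate("abcd"):
            assert fit.coefficients[c]["estimate"] == pytest.approx(ref.params[i + 1], abs=1e-6)
            assert fit.coefficients[c]["std_error"] == pytest.approx(ref.bse[i + 1], rel=1e-6)

    def test_two_term_recovery(self, two_term_data):
        X, y, f1, terms = two_term_data
        fit = backfit(y, X, terms)
        assert fit.converged
        assert fit.coefficients["x2"]["estimate"] == pytest.approx(2.0, abs=0.1)
        truth = np.sin(2 * np.pi * X["x1"].to_numpy())
        truth -= truth.mean()
        rms = np.sqrt(np.mean((fit.contributions["x1"] - truth) ** 2))
        assert rms < 0.1

    def test_term_order_does_not_matter_at_convergence(self, rng):
        n = 300
        x1 = rng.uniform(0, 1, n)
        x2 = rng.uniform(0, 1, n)
        y = np.sin(2 * np.pi * x1) + np.cos(2 * np.pi * x2) + rng.normal(0, 0.2, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        bw = {}
        f_a = backfit(y, X, [TermSpec("x1", "smooth"), TermSpec("x2", "smooth")],
                      bandwidth_cache=bw)
        f_b = backfit(y, X, [TermSpec("x2", "smooth"), TermSpec("x1", "smooth")],
                      bandwidth_cache=bw)
        assert np.abs(f_a.contributions["x1"] - f_b.contributions["x1"]).max() < 1e-3

    def test_categorical_reference_cell(self, rng):
        n = 400
        g = rng.choice(["a", "b", "c"], n)
        y = 1.0 + 0.5 * (g == "b") + 2.0 * (g == "c") + rng.normal(0, 0.1, n)
        X = pd.DataFrame({"g": g})
        fit = backfit(y, X, [TermSpec("g", "categorical")])
        assert fit.coefficients["g[b]"]["estimate"] == pytest.approx(0.5, abs=0.05)
        assert fit.coefficients["g[c]"]["estimate"] == pytest.approx(2.0, abs=0.05)
        assert fit.term_df["g"] == 2.0

    def test_rank_deficient_block_names_term(self, rng):
        n = 80
        a = rng.standard_normal(n)
        X = pd.DataFrame({"a": a, "b": 2.0 * a})
        with pytest.raises(ValueError, match="rank deficient.*'b'"):
            backfit(a + rng.standard_normal(n), X, [TermSpec("a", "linear"), TermSpec("b", "linear")])

    def test_missing_values_rejected(self, rng):
        X = pd.DataFrame({"a": [0.1, np.nan, 0.5, 0.7, 0.9, 0.2]})
        with pytest.raises(ValueError, match="missing"):
            backfit(np.ones(6), X, [TermSpec("a", "linear")])

    def test_nonconvergence_warns_not_raises(self, two_term_data):
        X, y, _, terms = two_term_data
        with pytest.warns(UserWarning, match="did not converge"):
            fit = backfit(y, X, terms, tol=1e-15, max_iter=2)
        assert not fit.converged
        assert fit.n_iter == 2


class TestPredict:
    def test_training_points_reconstruct(self, two_term_data):
        X, y, _, terms = two_term_data
        fit = backfit(y, X, terms)
        pred = predict(fit, X)
        np.testing.assert_allclose(pred, y - fit.residuals, atol=1e-8)

    def test_extrapolation_flagged(self, two_term_data):
        X, y, _, terms = two_term_data
        fit = backfit(y, X, terms)
        X_new = pd.DataFrame({"x1": [0.5, 2.5], "x2": [0.0, 0.0]})
        _, mask = predict(fit, X_new, return_extrapolation_mask=True)
        assert list(mask) == [False, True]

    def test_heldout_rmse_below_twice_noise(self, rng):
        n = 700
        x1 = rng.uniform(0, 1, n)
        x2 = rng.standard_normal(n)
        y = 1.0 + np.sin(2 * np.pi * x1) + 2.0 * x2 + rng.normal(0, 0.2, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        terms = [TermSpec("x1", "smooth"), TermSpec("x2", "linear")]
        fit = backfit(y[:500], X.iloc[:500].reset_index(drop=True), terms)
        pred = predict(fit, X.iloc[500:])
        rmse = np.sqrt(np.mean((pred - y[500:]) ** 2))
        assert rmse < 0.4  # 2 x noise SD

    def test_unseen_level_rejected(self, rng):
        n = 120
        g = rng.choice(["a", "b"], n)
        X = pd.DataFrame({"g": g})
        fit = backfit(rng.standard_normal(n), X, [TermSpec("g", "categorical")])
        with pytest.raises(ValueError, match="'z'"):
            predict(fit, pd.DataFrame({"g": ["a", "z"]}))


class TestModelDf:
    def test_all_linear_df_counts_parameters(self, rng):
        n = 100
        Z = rng.standard_normal((n, 3))
        X = pd.DataFrame(Z, columns=list("abc"))
        fit = backfit(Z @ [1.0, 1.0, 1.0] + rng.standard_normal(n), X,
                      [TermSpec(c, "linear") for c in "abc"])
        assert model_df(fit) == pytest.approx(4.0)

    def test_huge_bandwidth_smooth_acts_like_line(self, rng):
        x = rng.uniform(0, 1, 80)
        X = pd.DataFrame({"x": x})
        fit = backfit(x + rng.normal(0, 0.1, 80), X,
                      [TermSpec("x", "smooth", bandwidth=1e6, tilt=False)])
        assert model_df(fit) == pytest.approx(2.0, abs=0.01)  # intercept + 1

    def test_smooth_df_is_trace_minus_one(self, rng):
        from tiltam import tilted_smoother_matrix

        x = rng.uniform(0, 1, 20)
        X = pd.DataFrame({"x": x})
        fit = backfit(np.sin(2 * np.pi * x) + rng.normal(0, 0.1, 20), X,
                      [TermSpec("x", "smooth", bandwidth=0.2)])
        st = fit._smooth["x"]
        oracle = tilted_smoother_matrix(x, st.p, 0.2).effective_df
        assert fit.term_df["x"] == pytest.approx(oracle, abs=1e-10)
        assert model_df(fit) == pytest.approx(1.0 + oracle - 1.0, abs=1e-10)
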