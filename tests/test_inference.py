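import numpy as np
import pandas as pd
import pytest

import tiltam as tm
from tiltam import TermSpec, backfit, bootstrap_band, linearity_f_test, linearity_report
from tiltam.inference import normality_report, residual_diagnostics
from tiltam.inference import test_all_terms as run_all_term_tests


def three_predictor_data(seed, curvature=0.0, n=200):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["x1", "x2", "x3"])
    y = (
        1.0 + 1.0 * X.x1 + 0.5 * X.x2 - 0.5 * X.x3
        + curvature * X.x1**2 + rng.standard_normal(n)
    ).to_numpy()
    terms = [TermSpec("x1", "smooth"), TermSpec("x2", "linear"), TermSpec("x3", "linear")]
    return y, X, terms


class TestLinearityFTest:
    def test_noiseless_linear_truth_gives_no_evidence(self, rng):
        n = 120
        X = pd.DataFrame({"x1": rng.uniform(0, 1, n), "x2": rng.standard_normal(n)})
        y = (2.0 + 3.0 * X.x1 - X.x2).to_numpy()
        terms = [TermSpec("x1", "smooth"), TermSpec("x2", "linear")]
        r = linearity_f_test(y, X, terms, "x1")
        assert r.rss_linear == pytest.approx(0.0, abs=1e-12)
        # smooth fit cannot beat an exact linear fit: no evidence reported
        assert not r.nonlinear

    def test_strong_curvature_detected(self):
        y, X, terms = three_predictor_data(3, curvature=0.5)
        r = linearity_f_test(y, X, terms, "x1")
        assert r.f_value > 0
        assert r.p_value < 0.05
        assert r.nonlinear

    def test_f_statistic_affine_invariant(self):
        y, X, terms = three_predictor_data(11, curvature=0.3)
        bw: dict = {}
        r1 = linearity_f_test(y, X, terms, "x1", bandwidth_cache=bw)
        r2 = linearity_f_test(100.0 * y - 7.0, X, terms, "x1", bandwidth_cache=bw)
        assert r2.f_value == pytest.approx(r1.f_value, rel=1e-6)

    def test_categorical_target_rejected(self, small_cohort):
        y = small_cohort.table["AOV"].to_numpy()
        terms = [TermSpec("Age", "linear"), TermSpec("Gender", "categorical")]
        with pytest.raises(ValueError, match="continuous"):
            linearity_f_test(y, small_cohort.table, terms, "Gender")


class TestTestAllTerms:
    def test_report_columns_match_convention(self):
        y, X, terms = three_predictor_data(5)
        results = run_all_term_tests(y, X, terms)
        report = linearity_report(results)
        assert list(report.columns) == ["Predictor", "RSS L", "RSS N", "df N", "F Value", "p-Value"]
        assert list(report["Predictor"]) == ["x1", "x2", "x3"]

    def test_empty_continuous_list_gives_empty_report(self, rng):
        g = rng.choice(["a", "b"], 80)
        X = pd.DataFrame({"g": g})
        results = run_all_term_tests(rng.standard_normal(80), X, [TermSpec("g", "categorical")])
        assert results == []
        assert len(linearity_report(results)) == 0

    def test_mostly_nonsignificant_under_linear_truth(self):
        flagged = 0
        reps = 12
        for s in range(reps):
            y, X, terms = three_predictor_data(100 + s, n=300)
            results = run_all_term_tests(y, X, terms)
            flagged += sum(r.nonlinear for r in results)
        # 3 terms x reps tests at nominal 0.05: expect ~5% flagged
        assert flagged <= 0.15 * 3 * reps


class TestBootstrapBand:
    @pytest.fixture(scope="class")
    def band_fit(self):
        rng = np.random.default_rng(42)
        n = 250
        x1 = rng.uniform(0, 1, n)
        x2 = rng.standard_normal(n)
        y = 1.0 + np.sin(2 * np.pi * x1) + 2.0 * x2 + rng.normal(0, 0.2, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        terms = [TermSpec("x1", "smooth"), TermSpec("x2", "linear")]
        return backfit(y, X, terms), X

    def test_band_contains_estimate(self, band_fit):
        fit, X = band_fit
        band = bootstrap_band(fit, X, "x1", n_boot=120, seed=1)
        assert np.all(band.lower <= band.estimate + 1e-12)
        assert np.all(band.estimate <= band.upper + 1e-12)
        assert band.n_boot >= 108  # at most 10% dropped

    def test_deterministic_given_seed(self, band_fit):
        fit, X = band_fit
        b1 = bootstrap_band(fit, X, "x1", n_boot=120, seed=5)
        b2 = bootstrap_band(fit, X, "x1", n_boot=120, seed=5)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_band_widens_with_level(self, band_fit):
        fit, X = band_fit
        widths = []
        for level in (0.90, 0.95, 0.99):
            b = bootstrap_band(fit, X, "x1", n_boot=150, level=level, seed=2)
            widths.append(float(np.mean(b.upper - b.lower)))
        assert widths[0] < widths[1] < widths[2]

    def test_band_shrinks_with_vanishing_noise(self, rng):
        n = 250
        x1 = rng.uniform(0, 1, n)
        X = pd.DataFrame({"x1": x1})
        terms = [TermSpec("x1", "smooth")]
        y = np.sin(2 * np.pi * x1) + rng.normal(0, 1e-4, n)
        fit = backfit(y, X, terms)
        band = bootstrap_band(fit, X, "x1", n_boot=120, seed=3)
        interior = (band.grid > 0.1) & (band.grid < 0.9)
        assert np.mean((band.upper - band.lower)[interior]) < 0.01

    def test_requires_smooth_term_and_enough_boots(self, band_fit):
        fit, X = band_fit
        with pytest.raises(ValueError, match="smooth"):
            bootstrap_band(fit, X, "x2", n_boot=120, seed=1)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_band(fit, X, "x1", n_boot=50, seed=1)


class TestResidualDiagnostics:
    def test_gaussian_residuals_rarely_rejected(self):
        rejections = 0
        for s in range(100):
            r = np.random.default_rng(s).standard_normal(168)
            rep = normality_report(r)
            rejections += int(rep["shapiro_p"] < 0.05)
        assert rejections <= 10

    def test_exponential_residuals_rejected(self):
        rejections = 0
        for s in range(40):
            r = np.random.default_rng(s).exponential(1.0, 168)
            rep = normality_report(r - r.mean())
            rejections += int(rep["shapiro_p"] < 0.05)
        assert rejections >= 38

    def test_zero_residuals_skipped_with_notice(self):
        rep = normality_report(np.zeros(50))
        assert "degenerate" in rep["note"]
        assert np.isnan(rep["shapiro_w"])

    def test_large_sample_skipped_with_notice(self, rng):
        rep = normality_report(rng.standard_normal(6000))
        assert "5000" in rep["note"]

    def test_diagnostics_from_fit(self, two_term_data):
        X, y, _, terms = two_term_data
        fit = backfit(y, X, terms)
        rep = residual_diagnostics(fit)
        assert rep["n"] == len(y)
        assert 0.9 < rep["shapiro_w"] <= 1.0
        assert len(rep["hist_counts"]) == 20
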