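"""Inference for the tilted additive model.

Three pieces: a per-term linearity F-test, pointwise residual-bootstrap
confidence bands for smooth term curves, and residual normality
diagnostics.

The linearity test compares, in the presence of all other declared terms,
model A with the target entering linearly against model B with the target
entering as a tilted smooth. Writing df(.) for the trace-based effective
model degrees of freedom,

    F = [(RSS_A - RSS_B) / (df_B - df_A)] / [RSS_B / (n - df_B)],

referred to an F distribution with (df_B - df_A, n - df_B) degrees of
freedom (fractional df are fine). A smoother fit can have a *larger* RSS
than the linear fit, giving F <= 0; the raw F is reported but the p-value
is declared undefined and the term treated as showing no evidence of
nonlinearity. No multiplicity correction is applied across terms; results
are reported per term.

Bands are residual-bootstrap percentile intervals: resample the fit's
residuals with replacement, add them back to the fitted values, refit the
full model with the design (and bandwidths) held fixed, and take pointwise
percentiles of the refitted term curves on a fixed grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .additive import AdditiveFit, TermSpec, backfit, model_df
from .local_linear import weight_matrix

__all__ = [
    "LinearityTestResult",
    "ConfidenceBand",
    "linearity_f_test",
    "test_all_terms",
    "linearity_report",
    "bootstrap_band",
    "residual_diagnostics",
    "normality_report",
]


@dataclass
class LinearityTestResult:
    term: str
    rss_linear: float
    rss_nonlinear: float
    df_linear: float
    df_nonlinear: float
    f_value: float
    p_value: float  # nan when undefined (F <= 0)
    note: str = ""

    @property
    def nonlinear(self) -> bool:
        """Significant evidence of nonlinearity at the 0.05 level."""
        return np.isfinite(self.p_value) and self.p_value < 0.05


@dataclass
class ConfidenceBand:
    term: str
    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_boot: int


def _with_kind(terms: Sequence[TermSpec], target: str, kind: str) -> list[TermSpec]:
    out = []
    for t in terms:
        if t.name == target:
            out.append(TermSpec(target, kind, t.bandwidth, t.tilt))
        else:
            out.append(t)
    return out


def linearity_f_test(
    Y,
    X: pd.DataFrame,
    terms: Sequence[TermSpec],
    target: str,
    *,
    bandwidth_cache: Optional[dict] = None,
    fit_cache: Optional[dict] = None,
    **fit_kwargs,
) -> LinearityTestResult:
    """Test linear vs smooth entry of one continuous term.

    bandwidth_cache / fit_cache allow sharing work across the per-term
    tests of a model; fits are keyed by the tuple of (name, kind) pairs.
    """
    kinds = {t.name: t.kind for t in terms}
    if kinds.get(target) == "categorical":
        raise ValueError(f"linearity test applies to continuous terms, not {target!r}")
    if target not in kinds:
        raise ValueError(f"unknown term {target!r}")
    if bandwidth_cache is None:
        bandwidth_cache = {}
    if fit_cache is None:
        fit_cache = {}

    def _fit(term_list: Sequence[TermSpec]) -> AdditiveFit:
        key = tuple((t.name, t.kind) for t in term_list)
        if key not in fit_cache:
            fit_cache[key] = backfit(
                Y, X, term_list, bandwidth_cache=bandwidth_cache, **fit_kwargs
            )
        return fit_cache[key]

    fit_a = _fit(_with_kind(terms, target, "linear"))
    fit_b = _fit(_with_kind(terms, target, "smooth"))
    n = len(fit_a.residuals)
    df_a, df_b = model_df(fit_a), model_df(fit_b)
    ddiff = df_b - df_a
    if ddiff <= 0:
        raise ValueError(
            f"smooth fit for {target!r} did not exceed the linear complexity "
            f"(df difference {ddiff:.3g}); widen the bandwidth grid"
        )
    dres = n - df_b
    f_value = ((fit_a.rss - fit_b.rss) / ddiff) / (fit_b.rss / dres)
    if f_value > 0:
        p = float(stats.f.sf(f_value, ddiff, dres))
        note = ""
    else:
        p = float("nan")
        note = "no evidence of nonlinearity (smooth fit did not reduce RSS)"
    return LinearityTestResult(
        term=target,
        rss_linear=fit_a.rss,
        rss_nonlinear=fit_b.rss,
        df_linear=df_a,
        df_nonlinear=df_b,
        f_value=float(f_value),
        p_value=p,
        note=note,
    )


def test_all_terms(Y, X: pd.DataFrame, terms: Sequence[TermSpec], **fit_kwargs):
    """Linearity test for every continuous term, sharing fitted models."""
    bandwidth_cache: dict = {}
    fit_cache: dict = {}
    results = []
    for t in terms:
        if t.kind == "categorical":
            continue
        results.append(
            linearity_f_test(
                Y, X, terms, t.name,
                bandwidth_cache=bandwidth_cache, fit_cache=fit_cache, **fit_kwargs,
            )
        )
    return results


def _mark(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return " **"
    if p < 0.05:
        return " *"
    return ""


def linearity_report(results: Sequence[LinearityTestResult]) -> pd.DataFrame:
    """Tabular report: one row per tested predictor.

    "df N" is the degrees of freedom spent by the smooth entry of the
    target beyond the rest of the model (model df difference plus the one
    linear df), i.e. the target term's trace-based df minus the centring
    constraint. Significance marks: ** below 0.001, * below 0.05.
    """
    rows = []
    for r in results:
        p_str = "" if not np.isfinite(r.p_value) else f"{r.p_value:.4g}{_mark(r.p_value)}"
        rows.append(
            {
                "Predictor": r.term,
                "RSS L": round(r.rss_linear, 6),
                "RSS N": round(r.rss_nonlinear, 6),
                "df N": round(r.df_nonlinear - r.df_linear + 1.0, 3),
                "F Value": round(r.f_value, 3),
                "p-Value": p_str,
            }
        )
    return pd.DataFrame(rows, columns=["Predictor", "RSS L", "RSS N", "df N", "F Value", "p-Value"])


def _term_curve(fit: AdditiveFit, term: str, grid: np.ndarray) -> np.ndarray:
    st = fit._smooth[term]
    W = weight_matrix(st.x, grid, st.h, fit.kernel)
    return W @ (st.x.size * st.p * st.partial_residual) - st.center


def bootstrap_band(
    fit: AdditiveFit,
    data: pd.DataFrame,
    term: str,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
    grid_size: int = 100,
    undersmooth: object = "auto",
) -> ConfidenceBand:
    """Pointwise residual-bootstrap percentile band for a smooth term curve.

    Band construction undersmooths: the model is refitted with every smooth
    bandwidth scaled by n**(-1/20) (or the factor given), and the band is
    built around that refit. At the cross-validated bandwidth the smoothing
    bias is of the same order as the band width, which makes naive
    percentile bands undercover; shrinking h makes the bias asymptotically
    negligible relative to the width. Pass undersmooth=1.0 to disable.
    """
    if not fit.converged:
        raise ValueError("bootstrap bands require a converged fit")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    kinds = {t.name: t.kind for t in fit.terms}
    if kinds.get(term) != "smooth":
        raise ValueError(f"{term!r} is not a smooth term of this fit")

    n_obs = len(fit.residuals)
    factor = float(n_obs) ** (-1.0 / 20.0) if undersmooth == "auto" else float(undersmooth)
    if factor != 1.0:
        y_obs = fit.fitted_values + fit.residuals
        bw_us = {
            t.name: fit._smooth[t.name].h * factor
            for t in fit.terms
            if t.kind == "smooth"
        }
        fit = backfit(
            y_obs, data, fit.terms, kernel=fit.kernel, bandwidth_cache=bw_us
        )
        if not fit.converged:
            raise ValueError("undersmoothed band refit did not converge")

    st = fit._smooth[term]
    grid = np.linspace(st.x.min(), st.x.max(), grid_size)
    W = weight_matrix(st.x, grid, st.h, fit.kernel)
    estimate = W @ (st.x.size * st.p * st.partial_residual) - st.center

    fitted = fit.fitted_values
    resid = fit.residuals
    n = resid.size
    rng = np.random.default_rng(seed)
    bw_cache = {t.name: fit._smooth[t.name].h for t in fit.terms if t.kind == "smooth"}

    curves = []
    dropped = 0
    for _ in range(n_boot):
        y_star = fitted + rng.choice(resid, size=n, replace=True)
        refit = backfit(
            y_star, data, fit.terms, kernel=fit.kernel,
            bandwidth_cache=dict(bw_cache), reuse_design_from=fit, freeze_tilt=True,
        )
        if not refit.converged:
            dropped += 1
            continue
        rst = refit._smooth[term]
        curves.append(W @ (n * rst.p * rst.partial_residual) - rst.center)
    if dropped > 0.1 * n_boot:
        raise RuntimeError(
            f"{dropped}/{n_boot} bootstrap refits failed to converge; band unreliable"
        )
    if dropped:
        warnings.warn(f"{dropped} bootstrap replicates dropped (non-convergent refits)")

    C = np.asarray(curves)
    a = (1.0 - level) / 2.0
    lower = np.quantile(C, a, axis=0)
    upper = np.quantile(C, 1.0 - a, axis=0)
    # the band is forced to cover the point estimate at every grid point
    lower = np.minimum(lower, estimate)
    upper = np.maximum(upper, estimate)
    return ConfidenceBand(
        term=term, grid=grid, estimate=estimate, lower=lower, upper=upper,
        level=level, n_boot=len(curves),
    )


def normality_report(residuals) -> dict:
    """Shapiro-Wilk test plus histogram / QQ data for a residual vector."""
    r = np.asarray(residuals, dtype=float)
    report: dict = {"n": int(r.size)}
    if r.size == 0 or np.allclose(r, 0.0):
        report["note"] = "degenerate residuals (all ~0); normality test not applicable"
        report["shapiro_w"] = report["shapiro_p"] = float("nan")
        return report
    if not (3 <= r.size <= 5000):
        report["note"] = "sample size outside Shapiro-Wilk validity range [3, 5000]; test skipped"
        report["shapiro_w"] = report["shapiro_p"] = float("nan")
    else:
        w, p = stats.shapiro(r)
        report["shapiro_w"] = float(w)
        report["shapiro_p"] = float(p)
        report["note"] = ""
    counts, edges = np.histogram(r, bins=20)
    (osm, osr), _ = stats.probplot(r, dist="norm")
    report["hist_counts"] = counts
    report["hist_edges"] = edges
    report["qq_theoretical"] = osm
    report["qq_sample"] = osr
    return report


def residual_diagnostics(fit: AdditiveFit) -> dict:
    """Goodness-of-fit diagnostics for the Gaussian identity-link model.

    With an identity link the deviance residuals equal the ordinary
    residuals, so the report is built directly from fit.residuals.
    """
    return normality_report(fit.residuals)
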