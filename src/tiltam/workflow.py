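"""End-to-end analysis workflow.

Mirrors the study's analysis sequence: test every continuous predictor for
linearity in the presence of all the others, demote terms without
significant nonlinearity to linear entry, refit the resulting
semiparametric model, compute bootstrap bands for the surviving smooth
terms, and run residual diagnostics. All outputs are plain CSV/JSON with
the configuration and seed embedded so a rerun reproduces them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .additive import TermSpec, backfit, model_df
from .inference import (
    bootstrap_band,
    linearity_report,
    residual_diagnostics,
    test_all_terms,
)
from .io import RunConfig, load_table

__all__ = ["run_workflow", "select_final_terms", "coefficient_table", "fit_to_dict"]

log = logging.getLogger("tiltam")


def select_final_terms(results, terms, *, prefer_simple_on_borderline=True,
                       borderline_window=(0.04, 0.05), alpha=0.05):
    """Demotion rule: keep a term smooth only with significant nonlinearity.

    Terms with F <= 0 (undefined p) become linear. A p-value inside the
    borderline window is treated as linear when prefer_simple_on_borderline
    is set — a simple model is preferred on the borderline.
    """
    by_term = {r.term: r for r in results}
    final = []
    for t in terms:
        if t.kind == "categorical" or t.name not in by_term:
            final.append(t)
            continue
        r = by_term[t.name]
        smooth = np.isfinite(r.p_value) and r.p_value < alpha
        if (
            smooth
            and prefer_simple_on_borderline
            and borderline_window[0] <= r.p_value <= borderline_window[1]
        ):
            smooth = False
        final.append(TermSpec(t.name, "smooth" if smooth else "linear", t.bandwidth, t.tilt))
    return final


def coefficient_table(fit) -> pd.DataFrame:
    """Linear-part coefficient table: Estimate, Std. Error, t Value, p-Value."""
    rows = [
        {
            "Predictor": name,
            "Estimate": c["estimate"],
            "Std. Error": c["std_error"],
            "t Value": c["t_value"],
            "p-Value": c["p_value"],
        }
        for name, c in fit.coefficients.items()
    ]
    return pd.DataFrame(rows, columns=["Predictor", "Estimate", "Std. Error", "t Value", "p-Value"])


def fit_to_dict(fit, curve_grid_size: int = 100) -> dict:
    """JSON-serialisable summary of an additive fit, with term curves."""
    from .local_linear import weight_matrix

    out = {
        "intercept": fit.intercept,
        "coefficients": fit.coefficients,
        "term_df": fit.term_df,
        "model_df": model_df(fit),
        "rss": fit.rss,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "curves": {},
    }
    for t in fit.terms:
        if t.kind != "smooth":
            continue
        st = fit._smooth[t.name]
        grid = np.linspace(st.x.min(), st.x.max(), curve_grid_size)
        W = weight_matrix(st.x, grid, st.h, fit.kernel)
        curve = W @ (st.x.size * st.p * st.partial_residual) - st.center
        out["curves"][t.name] = {
            "grid": grid.tolist(),
            "estimate": curve.tolist(),
            "bandwidth": st.h,
        }
    return out


def run_workflow(config: RunConfig, df: pd.DataFrame | None = None) -> dict:
    """Run the full pipeline and (optionally) write its artifacts.

    Returns a bundle with the linearity report, the final term list, the
    refitted model, coefficient table, bands and diagnostics. When
    config.output_dir is set, each piece is also written as CSV/JSON.
    """
    if df is None:
        modelled = [config.outcome] + [t.name for t in config.terms]
        df = load_table(config.data, required=modelled)
    config.validate(df)
    Y = np.asarray(df[config.outcome], dtype=float)
    X = df

    fit_kwargs = dict(
        tol=config.tol, max_iter=config.max_iter, kernel=config.kernel,
        tilt_grid_size=config.tilt_grid_size, comparator_factor=config.comparator_factor,
    )

    results = test_all_terms(Y, X, config.terms, **fit_kwargs)
    report = linearity_report(results)

    final_terms = select_final_terms(
        results, config.terms,
        prefer_simple_on_borderline=config.prefer_simple_on_borderline,
        borderline_window=config.borderline_window,
    )
    final_fit = backfit(Y, X, final_terms, **fit_kwargs)
    coef = coefficient_table(final_fit)

    bands = {}
    for t in final_terms:
        if t.kind == "smooth":
            bands[t.name] = bootstrap_band(
                final_fit, X, t.name,
                n_boot=config.n_boot, level=config.level, seed=config.seed,
            )
    diag = residual_diagnostics(final_fit)

    bundle = {
        "linearity_results": results,
        "linearity_report": report,
        "final_terms": final_terms,
        "fit": final_fit,
        "coefficients": coef,
        "bands": bands,
        "diagnostics": diag,
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "linearity.csv", index=False)
        coef.to_csv(outdir / "coefficients.csv", index=False)
        for name, b in bands.items():
            pd.DataFrame(
                {"x": b.grid, "est": b.estimate, "lo": b.lower, "hi": b.upper}
            ).to_csv(outdir / f"band_{name}.csv", index=False)
        diag_json = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in diag.items()
        }
        (outdir / "diagnostics.json").write_text(json.dumps(diag_json, indent=2))
        cfg = dataclasses.asdict(config)
        cfg["kernel"] = {"family": config.kernel.family, "taper": config.kernel.taper}
        cfg["terms"] = [dataclasses.asdict(t) for t in config.terms]
        cfg["final_terms"] = [dataclasses.asdict(t) for t in final_terms]
        (outdir / "config_used.json").write_text(json.dumps(cfg, indent=2, default=str))
        (outdir / "fit.json").write_text(json.dumps(fit_to_dict(final_fit), indent=2))
        log.info("workflow artifacts written to %s", outdir)

    return bundle
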