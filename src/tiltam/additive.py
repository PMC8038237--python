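"""Backfitted additive model with tilted smooth terms.

The model is Gaussian with identity link:

    Y = alpha + f_1(X_1) + ... + f_p(X_p) + eps,

where each term is declared smooth (tilted local-linear), linear, or
categorical (reference-cell dummies). Fitting is Gauss-Seidel backfitting:
each sweep refits every term on the partial residual that removes the
current contributions of all other terms. The parametric terms are refit
jointly in a single least-squares block per sweep (stable, and exactly OLS
when every term is parametric); the smooth terms are refit one at a time in
their declared order. Each smooth contribution is centred to mean zero after
its refit, with the mean absorbed into the intercept — the standard
identifiability constraint for additive models.

For a smooth term the per-sweep refit is: (optionally, first sweep only)
select the bandwidth by leave-one-out cross-validation on the partial
residual; build the flat-top comparator curve on the matching grid from the
same partial residual; solve the tilting program against that comparator;
apply the tilted smoother. The per-term effective degrees of freedom is the
trace of the term's tilted smoother matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .kernels import KernelSpec, flat_top_regression_estimate
from .local_linear import cv_bandwidth, default_h_grid, weight_matrix
from .tilted import solve_tilting

__all__ = ["TermSpec", "AdditiveFit", "backfit", "predict", "model_df"]


@dataclass(frozen=True)
class TermSpec:
    """Declaration of one model term.

    bandwidth is "auto" (leave-one-out CV) or a positive number; tilt
    switches the tilting step on for smooth terms. Both are ignored for
    parametric terms. Categorical terms use the first sorted level as the
    reference cell.
    """

    name: str
    kind: str  # smooth | linear | categorical
    bandwidth: object = "auto"
    tilt: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("smooth", "linear", "categorical"):
            raise ValueError(f"unknown term kind {self.kind!r} for {self.name!r}")
        if self.bandwidth != "auto" and not (
            np.isscalar(self.bandwidth) and float(self.bandwidth) > 0
        ):
            raise ValueError(f"bandwidth for {self.name!r} must be 'auto' or positive")


@dataclass
class _SmoothState:
    x: np.ndarray
    h: float
    L: np.ndarray          # (n, n) local-linear weights at design points
    L_diag: np.ndarray
    grid: np.ndarray       # tilting matching grid
    L_grid: np.ndarray     # (G, n) weights on the matching grid
    comp_W: np.ndarray     # (G, n) flat-top NW weights on the grid
    p: np.ndarray
    partial_residual: np.ndarray
    center: float
    trace: float
    tilt_status: str = "untilted"


@dataclass
class _ParametricState:
    names: list                      # column labels of Z, per dummy/linear col
    term_of_col: list                # term name owning each Z column
    levels: dict                     # categorical term -> sorted levels
    Z: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    beta: Optional[np.ndarray] = None


@dataclass
class AdditiveFit:
    """Result of backfitting; carries enough state to predict and refit."""

    intercept: float
    contributions: dict              # term name -> length-n vector
    coefficients: dict               # coef label -> {estimate, std_error, t_value, p_value}
    term_df: dict                    # term name -> effective df (trace for smooth)
    rss: float
    residuals: np.ndarray
    n_iter: int
    converged: bool
    rss_path: list = field(default_factory=list)
    terms: Sequence[TermSpec] = ()
    kernel: KernelSpec = KernelSpec()
    _smooth: dict = field(default_factory=dict)      # name -> _SmoothState
    _parametric: Optional[_ParametricState] = None
    _train_index: Optional[np.ndarray] = None

    @property
    def fitted_values(self) -> np.ndarray:
        total = np.full(self.residuals.shape, self.intercept)
        for v in self.contributions.values():
            total = total + v
        return total


def _build_parametric(X: pd.DataFrame, terms: Sequence[TermSpec]) -> Optional[_ParametricState]:
    cols, names, owner, levels = [], [], [], {}
    for t in terms:
        if t.kind == "linear":
            cols.append(np.asarray(X[t.name], dtype=float))
            names.append(t.name)
            owner.append(t.name)
        elif t.kind == "categorical":
            lv = sorted(pd.unique(X[t.name]).tolist(), key=str)
            levels[t.name] = lv
            for level in lv[1:]:
                cols.append((np.asarray(X[t.name]) == level).astype(float))
                names.append(f"{t.name}[{level}]")
                owner.append(t.name)
    if not cols:
        return None
    Z = np.column_stack(cols)
    n = Z.shape[0]
    design = np.column_stack([np.ones(n), Z])
    Q, R = np.linalg.qr(design)
    diag = np.abs(np.diag(R))
    bad = diag <= 1e-10 * max(diag.max(), 1.0)
    if np.any(bad):
        j = int(np.argmax(bad))
        label = "Intercept" if j == 0 else names[j - 1]
        term = "Intercept" if j == 0 else owner[j - 1]
        raise ValueError(
            f"parametric block is rank deficient at column {label!r} (term {term!r})"
        )
    return _ParametricState(names=names, term_of_col=owner, levels=levels, Z=Z, Q=Q, R=R)


def _tilt_grid(x: np.ndarray, size: int) -> np.ndarray:
    lo, hi = np.percentile(x, [5.0, 95.0])
    if hi <= lo:
        raise ValueError("cannot form a tilting grid: predictor nearly constant")
    return np.linspace(lo, hi, size)


def backfit(
    Y,
    X: pd.DataFrame,
    terms: Sequence[TermSpec],
    tol: float = 1e-6,
    max_iter: int = 100,
    kernel: KernelSpec = KernelSpec(),
    *,
    tilt_grid_size: int = 50,
    comparator_factor: float = 1.2,
    flat_top_taper: float = 0.5,
    tilt_sweeps: int = 5,
    bandwidth_cache: Optional[dict] = None,
    reuse_design_from: Optional[AdditiveFit] = None,
    freeze_tilt: bool = False,
) -> AdditiveFit:
    """Fit the additive model by backfitting.

    bandwidth_cache maps term name -> bandwidth and is read/written so that
    repeated fits on the same design (model comparisons, bootstrap) skip the
    cross-validation. reuse_design_from shares the precomputed per-term
    weight matrices of an earlier fit on the *same predictor columns*, which
    makes residual-bootstrap refits cheap. freeze_tilt keeps each smooth
    term's tilting weights at their reuse_design_from values instead of
    re-estimating them — the bootstrap conditions on the selected smoother.
    Tilting weights are re-estimated during the first tilt_sweeps sweeps
    only and then held fixed: with fixed weights every refit is linear, so
    the remaining iteration converges like ordinary backfitting instead of
    chasing a moving tilt.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.size
    if X.isna().any().any() or np.any(~np.isfinite(Y)):
        raise ValueError("missing values present; apply complete-case filtering first")
    names = [t.name for t in terms]
    if len(set(names)) != len(names):
        raise ValueError("duplicate term names")
    for t in terms:
        if t.name not in X.columns:
            raise ValueError(f"term {t.name!r} not found in the data columns")

    smooth_terms = [t for t in terms if t.kind == "smooth"]
    par = _build_parametric(X, terms)
    n_par = 1 + (par.Z.shape[1] if par is not None else 0)
    if n <= n_par + 2 * len(smooth_terms):
        raise ValueError("too few observations for the declared model complexity")

    # --- per-smooth-term design state -----------------------------------
    states: dict[str, _SmoothState] = {}
    if bandwidth_cache is None:
        bandwidth_cache = {}
    donor = reuse_design_from._smooth if reuse_design_from is not None else {}

    contributions = {t.name: np.zeros(n) for t in terms}
    alpha = float(Y.mean())
    smooth_total = np.zeros(n)

    def _make_state(t: TermSpec, resid: np.ndarray) -> _SmoothState:
        x = np.asarray(X[t.name], dtype=float)
        if t.name in donor and np.array_equal(donor[t.name].x, x):
            d = donor[t.name]
            return _SmoothState(
                x=x, h=d.h, L=d.L, L_diag=d.L_diag, grid=d.grid, L_grid=d.L_grid,
                comp_W=d.comp_W, p=d.p.copy(),
                partial_residual=resid.copy(), center=0.0, trace=0.0,
            )
        if t.bandwidth != "auto":
            h = float(t.bandwidth)
        elif t.name in bandwidth_cache:
            h = float(bandwidth_cache[t.name])
        else:
            h = cv_bandwidth(x, resid, default_h_grid(x), kernel)
            bandwidth_cache[t.name] = h
        L = weight_matrix(x, x, h, kernel)
        grid = _tilt_grid(x, tilt_grid_size)
        L_grid = weight_matrix(x, grid, h, kernel)
        from .kernels import kernel_eval  # local import avoids cycle at module load
        ft = KernelSpec("flat_top", flat_top_taper)
        # Comparator: flat-top kernel regression in local-linear form. The
        # local-linear structure reproduces affine trends exactly at any
        # bandwidth, so tilting toward the comparator never destroys a
        # linear component; the flat-top kernel keeps its bias of
        # arbitrarily high order for the curvature. A Nadaraya-Watson
        # average is the fallback when the signed-kernel moment matrix
        # degenerates at some grid point.
        try:
            comp_W = weight_matrix(x, grid, comparator_factor * h, ft)
        except ValueError:
            W = kernel_eval(ft, (grid[:, None] - x[None, :]) / (comparator_factor * h))
            denom = W.sum(axis=1)
            if np.any(np.abs(denom) < 1e-10 * n * kernel_eval(ft, 0.0)):
                raise ValueError(
                    f"flat-top comparator degenerate for term {t.name!r}; "
                    "increase the comparator bandwidth factor"
                )
            comp_W = W / denom[:, None]
        return _SmoothState(
            x=x, h=h, L=L, L_diag=np.diag(L).copy(), grid=grid, L_grid=L_grid,
            comp_W=comp_W, p=np.full(n, 1.0 / n),
            partial_residual=resid.copy(), center=0.0, trace=0.0,
        )

    # --- backfitting sweeps ---------------------------------------------
    rss_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_change = 0.0

        # parametric block first (joint least squares)
        if par is not None:
            R_par = Y - smooth_total
            beta = solve_triangular(par.R, par.Q.T @ R_par, lower=False)
            par.beta = beta
            alpha = float(beta[0])
            start = 1
            new_contrib: dict[str, np.ndarray] = {}
            for t in terms:
                if t.kind == "linear":
                    new_contrib[t.name] = par.Z[:, start - 1] * beta[start]
                    start += 1
                elif t.kind == "categorical":
                    k = len(par.levels[t.name]) - 1
                    new_contrib[t.name] = par.Z[:, start - 1 : start - 1 + k] @ beta[start : start + k]
                    start += k
            for name, v in new_contrib.items():
                max_change = max(max_change, float(np.sqrt(np.mean((v - contributions[name]) ** 2))))
                contributions[name] = v
        else:
            # intercept-only parametric part
            alpha = float(np.mean(Y - smooth_total))

        # smooth terms, declared order
        for t in smooth_terms:
            others = sum(
                (contributions[s.name] for s in terms if s.name != t.name),
                np.zeros(n),
            )
            resid = Y - alpha - others
            if t.name not in states:
                states[t.name] = _make_state(t, resid)
            st = states[t.name]
            st.partial_residual = resid

            if t.tilt and not freeze_tilt and it <= tilt_sweeps:
                comp = st.comp_W @ resid
                sol = solve_tilting(
                    st.x, resid, st.h, comp, st.grid, kernel,
                    grid_weights=st.L_grid, warm_start=st.p,
                )
                # Tilt intensity by leave-one-out CV: candidates interpolate
                # between uniform weights (no tilt) and the full QP solution,
                # all inside the simplex. The LOO residuals use the linear-
                # smoother diagonal shortcut. Full tilting is applied only
                # when it predicts better; ties favour less tilting.
                uni = np.full(n, 1.0 / n)
                best = (np.inf, uni)  # untilted fallback always available
                for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
                    p_lam = (1.0 - lam) * uni + lam * sol.p
                    diag = n * p_lam * st.L_diag
                    if np.any(diag >= 1.0 - 1e-8):
                        continue
                    f_lam = st.L @ (n * p_lam * resid)
                    r_loo = (resid - f_lam) / (1.0 - diag)
                    score = float(r_loo @ r_loo)
                    if score < best[0] * (1.0 - 1e-10):
                        best = (score, p_lam)
                st.p = best[1]
                st.tilt_status = sol.solver_status
            fit_vals = st.L @ (n * st.p * resid)
            m = float(fit_vals.mean())
            alpha += m
            new_c = fit_vals - m
            st.center = m
            st.trace = float(np.sum(n * st.p * st.L_diag))
            max_change = max(max_change, float(np.sqrt(np.mean((new_c - contributions[t.name]) ** 2))))
            contributions[t.name] = new_c
            smooth_total = sum((contributions[s.name] for s in smooth_terms), np.zeros(n))

        resid_all = Y - alpha - sum(contributions.values(), np.zeros(n))
        rss_path.append(float(resid_all @ resid_all))
        if max_change < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"backfitting did not converge in {max_iter} sweeps "
            f"(last max contribution change {max_change:.3g})"
        )

    residuals = Y - alpha - sum(contributions.values(), np.zeros(n))
    rss = float(residuals @ residuals)

    # --- degrees of freedom and parametric coefficient table -------------
    term_df: dict[str, float] = {}
    for t in terms:
        if t.kind == "smooth":
            term_df[t.name] = states[t.name].trace
        elif t.kind == "linear":
            term_df[t.name] = 1.0
        else:
            term_df[t.name] = float(len(par.levels[t.name]) - 1)

    coefficients = _coef_table(
        Y, contributions, terms, par, smooth_terms, states, rss,
        model_df_value=1.0
        + sum(
            (term_df[t.name] - 1.0) if t.kind == "smooth" else term_df[t.name]
            for t in terms
        ),
    )

    return AdditiveFit(
        intercept=alpha,
        contributions=contributions,
        coefficients=coefficients,
        term_df=term_df,
        rss=rss,
        residuals=residuals,
        n_iter=it,
        converged=converged,
        rss_path=rss_path,
        terms=tuple(terms),
        kernel=kernel,
        _smooth=states,
        _parametric=par,
        _train_index=np.arange(n),
    )


def _smooth_only_residualise(v: np.ndarray, smooth_terms, states, tol=1e-10, max_iter=50):
    """Residual of v after backfitting only the (frozen) smooth terms.

    The frozen tilted smoothers and the mean are applied as in the main
    loop; what is returned is v minus its projection onto the smooth part,
    the (I - S)v of partially linear model theory.
    """
    n = v.size
    a = float(v.mean())
    contrib = {t.name: np.zeros(n) for t in smooth_terms}
    for _ in range(max_iter):
        change = 0.0
        for t in smooth_terms:
            st = states[t.name]
            r = v - a - sum(
                (contrib[s.name] for s in smooth_terms if s.name != t.name),
                np.zeros(n),
            )
            f = st.L @ (n * st.p * r)
            m = float(f.mean())
            a += m
            new_c = f - m
            change = max(change, float(np.max(np.abs(new_c - contrib[t.name]))))
            contrib[t.name] = new_c
        if change < tol:
            break
    return v - a - sum(contrib.values(), np.zeros(n))


def _coef_table(Y, contributions, terms, par, smooth_terms, states, rss, model_df_value) -> dict:
    """Coefficient table for the parametric block.

    Point estimates are the backfitting solution (equivalently, OLS of
    Y minus the smooth contributions on the parametric design). Standard
    errors follow the partially-linear-model form: each parametric column
    is residualised against the frozen smooth terms and the covariance is
    sigma^2 (Z~' Z~)^-1 — conditional standard errors would understate the
    uncertainty of covariates correlated with the smooth predictors.
    """
    if par is None:
        return {}
    n = len(Y)
    endog = np.asarray(Y, dtype=float) - sum(
        (contributions[t.name] for t in smooth_terms), np.zeros(n)
    )
    labels = ["Intercept"] + list(par.names)

    if not smooth_terms:
        # purely parametric model: classical OLS table
        import statsmodels.api as sm

        res = sm.OLS(endog, sm.add_constant(par.Z, has_constant="add")).fit()
        return {
            lab: {
                "estimate": float(res.params[i]),
                "std_error": float(res.bse[i]),
                "t_value": float(res.tvalues[i]),
                "p_value": float(res.pvalues[i]),
            }
            for i, lab in enumerate(labels)
        }

    design = np.column_stack([np.ones(n), par.Z])
    beta = solve_triangular(par.R, par.Q.T @ endog, lower=False)

    if smooth_terms:
        Zt = np.column_stack(
            [_smooth_only_residualise(design[:, j], smooth_terms, states) for j in range(design.shape[1])]
        )
        # the intercept column residualises to ~0; restore it so the
        # covariance stays well defined (its own SE is conditional)
        if np.linalg.norm(Zt[:, 0]) < 1e-6 * np.sqrt(n):
            Zt[:, 0] = 1.0
    else:
        Zt = design
    df_res = max(n - model_df_value, 1.0)
    sigma2 = rss / df_res
    cov = sigma2 * np.linalg.inv(Zt.T @ Zt)
    bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    from scipy import stats as sps

    tvals = beta / bse
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_res)
    return {
        lab: {
            "estimate": float(beta[i]),
            "std_error": float(bse[i]),
            "t_value": float(tvals[i]),
            "p_value": float(pvals[i]),
        }
        for i, lab in enumerate(labels)
    }


def predict(fit: AdditiveFit, X_new: pd.DataFrame, return_extrapolation_mask: bool = False):
    """Evaluate the fitted model at new predictor values.

    Smooth terms re-apply the stored tilted weights to the final partial
    residuals at the new points. Rows with any smooth predictor outside its
    training range are extrapolations (request the mask to identify them);
    there the smooth contribution is held at its boundary value, since
    kernel weights carry no information beyond the design.
    """
    m = len(X_new)
    total = np.full(m, fit.intercept)
    extrap = np.zeros(m, dtype=bool)
    par = fit._parametric
    for t in fit.terms:
        if t.name not in X_new.columns:
            raise ValueError(f"column {t.name!r} missing from prediction data")
        if t.kind == "smooth":
            st = fit._smooth[t.name]
            xnew = np.asarray(X_new[t.name], dtype=float)
            extrap |= (xnew < st.x.min()) | (xnew > st.x.max())
            xnew = np.clip(xnew, st.x.min(), st.x.max())
            L = weight_matrix(st.x, xnew, st.h, fit.kernel)
            total = total + L @ (st.x.size * st.p * st.partial_residual) - st.center
        elif t.kind == "linear":
            beta = fit.coefficients[t.name]["estimate"]
            total = total + beta * np.asarray(X_new[t.name], dtype=float)
        else:
            lv = par.levels[t.name]
            vals = X_new[t.name]
            unseen = set(pd.unique(vals)) - set(lv)
            if unseen:
                raise ValueError(
                    f"unseen level {sorted(unseen, key=str)[0]!r} for categorical term {t.name!r}"
                )
            for level in lv[1:]:
                eff = fit.coefficients[f"{t.name}[{level}]"]["estimate"]
                total = total + eff * (np.asarray(vals) == level)
    if return_extrapolation_mask:
        return total, extrap
    return total


def model_df(fit: AdditiveFit) -> float:
    """Total effective degrees of freedom of the fitted model.

    1 for the intercept, the parametric column counts, and for each smooth
    term the trace of its tilted smoother matrix minus 1 (the centring
    constraint absorbs one degree of freedom into the intercept).
    """
    total = 1.0
    for t in fit.terms:
        if t.kind == "smooth":
            total += fit.term_df[t.name] - 1.0
        else:
            total += fit.term_df[t.name]
    return total
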