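"""Tilted local-linear smoother.

Tilting replaces the uniform empirical weights 1/n on the observations with
a general probability vector p on the simplex. The tilted local-linear
estimate at x is

    fhat(x | p, h) = sum_i n p_i l_i(x) Y_i,

where l_i are the standard local-linear weights. The explicit factor n makes
uniform tilting (p_i = 1/n) recover the untilted smoother exactly; since
sum_i l_i(x) = 1, omitting it would shrink the fit by n. The tilt vector is
chosen by minimising the L2 distance, over a matching grid, between the
tilted fit and a low-bias comparator curve (an infinite-order flat-top
kernel regression), subject to p >= 0 and sum p = 1.

That matching problem is a convex quadratic program over the probability
simplex. It is solved by an accelerated projected-gradient method (FISTA
with a monotone restart) started at the uniform vector, with a tiny ridge
toward uniform that picks the minimal-tilt solution when the grid equations
underdetermine p. The returned objective is the pure matching distance,
without the ridge term.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .kernels import KernelSpec
from .local_linear import SmootherMatrix, weight_matrix

__all__ = ["TiltingSolution", "tilted_fit", "solve_tilting", "tilted_smoother_matrix"]

_SIMPLEX_TOL = 1e-6


@dataclass
class TiltingSolution:
    p: np.ndarray
    objective: float
    grid: np.ndarray
    solver_status: str  # optimal | max_iter | infeasible


def _check_simplex(p: np.ndarray) -> None:
    if np.any(p < -_SIMPLEX_TOL) or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError(
            f"tilting weights off the simplex: min={p.min():.3g}, sum={p.sum():.6g}"
        )


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-based)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    rho = np.nonzero(u - css / idx > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def tilted_fit(X, Y, p, h: float, x, kernel: KernelSpec = KernelSpec()):
    """Evaluate the tilted local-linear fit at one point or an array of points."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.shape != X.shape:
        raise ValueError("p must have one weight per observation")
    _check_simplex(p)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    L = weight_matrix(X, xs, h, kernel)
    vals = L @ (X.size * p * Y)
    return float(vals[0]) if np.isscalar(x) or np.ndim(x) == 0 else vals


def solve_tilting(
    X,
    Y,
    h: float,
    comparator,
    grid,
    kernel: KernelSpec = KernelSpec(),
    *,
    max_iter: int = 5000,
    tol: float = 1e-9,
    ridge: float = 1e-8,
    grid_weights=None,
    warm_start=None,
) -> TiltingSolution:
    """Choose tilting weights matching the comparator curve on the grid.

    Minimises sum_g (fhat(x_g | p, h) - comparator_g)^2 over the simplex.
    grid_weights may carry precomputed local-linear weights on the grid
    (shape (G, n)) to avoid recomputation in repeated fits. On solver
    trouble the uniform vector is returned with a warning rather than
    raising: tilting must never break the surrounding fit.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    c = np.asarray(comparator, dtype=float)
    if grid.size < 10:
        raise ValueError("matching grid must contain at least 10 points")
    if grid.shape != c.shape or not np.all(np.isfinite(c)):
        raise ValueError("comparator must be finite and aligned with the grid")
    n = X.size
    uniform = np.full(n, 1.0 / n)

    try:
        L = grid_weights if grid_weights is not None else weight_matrix(X, grid, h, kernel)
    except ValueError as exc:
        warnings.warn(f"tilting skipped (degenerate weights): {exc}")
        return TiltingSolution(uniform, np.nan, grid, "infeasible")

    A = n * L * Y[None, :]  # (G, n): column i multiplies p_i

    def match_obj(p: np.ndarray) -> float:
        r = A @ p - c
        return float(r @ r)

    # Spectral norm via the small Gram matrix (G x G).
    M = A @ A.T
    sig2 = float(np.linalg.eigvalsh(M).max())
    gamma = ridge * max(sig2, 1.0)
    lip = 2.0 * (sig2 + gamma)

    # Fast path: the equality-constrained (sum p = 1) minimiser has a closed
    # form in the G-dimensional grid space via the Woodbury identity. When it
    # is already (numerically) nonnegative, it solves the full program.
    from scipy.linalg import cho_factor, cho_solve

    try:
        cho = cho_factor(M + gamma * np.eye(M.shape[0]))

        def _binv(v: np.ndarray) -> np.ndarray:
            return (v - A.T @ cho_solve(cho, A @ v)) / gamma

        q1 = _binv(A.T @ c + gamma * uniform)
        q2 = _binv(np.ones(n))
        p_eq = q1 - ((q1.sum() - 1.0) / q2.sum()) * q2
    except np.linalg.LinAlgError:
        p_eq = None

    if p_eq is not None and np.all(np.isfinite(p_eq)) and p_eq.min() >= -1e-9 * max(1.0, 1.0 / n):
        p_fast = np.maximum(p_eq, 0.0)
        p_fast /= p_fast.sum()
        if match_obj(p_fast) <= match_obj(uniform) + 1e-12:
            return TiltingSolution(p_fast, match_obj(p_fast), grid, "optimal")
    warm_candidates = [warm_start]
    if p_eq is not None and np.all(np.isfinite(p_eq)):
        warm_candidates.append(project_simplex(p_eq))

    def full_obj(p: np.ndarray) -> float:
        d = p - uniform
        return match_obj(p) + gamma * float(d @ d)

    def grad(p: np.ndarray) -> np.ndarray:
        return 2.0 * (A.T @ (A @ p - c)) + 2.0 * gamma * (p - uniform)

    p = uniform.copy()
    for cand in warm_candidates:
        if cand is None:
            continue
        cand = project_simplex(np.asarray(cand, dtype=float))
        if full_obj(cand) < full_obj(p):
            p = cand
    z = p.copy()
    t = 1.0
    f_best = full_obj(p)
    p_best = p.copy()
    status = "max_iter"
    for _ in range(max_iter):
        p_new = project_simplex(z - grad(z) / lip)
        f_new = full_obj(p_new)
        if f_new > f_best:  # monotone restart
            z = p_best.copy()
            t = 1.0
            p_new = project_simplex(z - grad(z) / lip)
            f_new = full_obj(p_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = p_new + ((t - 1.0) / t_new) * (p_new - p)
        improvement = f_best - f_new
        if f_new < f_best:
            f_best, p_best = f_new, p_new.copy()
        p, t = p_new, t_new
        if 0.0 <= improvement <= tol * (1.0 + f_best):
            status = "optimal"
            break

    if not np.all(np.isfinite(p_best)) or match_obj(p_best) > match_obj(uniform) + 1e-12:
        warnings.warn("tilting solver failed to improve on uniform weights; using uniform")
        return TiltingSolution(uniform, match_obj(uniform), grid, "infeasible")
    return TiltingSolution(p_best, match_obj(p_best), grid, status)


def tilted_smoother_matrix(X, p, h: float, kernel: KernelSpec = KernelSpec()) -> SmootherMatrix:
    """Smoother matrix of the tilted fit; entry (r, i) = n p_i l_i(X_r).

    Rows are deliberately not renormalised: the tilted estimator is defined
    without renormalisation, so for non-uniform p the rows need not sum to 1.
    """
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float)
    _check_simplex(p)
    L = weight_matrix(X, X, h, kernel)
    S = L * (X.size * p)[None, :]
    return SmootherMatrix(matrix=S, effective_df=float(np.trace(S)))
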