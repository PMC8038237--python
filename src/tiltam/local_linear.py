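"""Standard local-linear kernel smoother.

The smoother at a target point x fits a kernel-weighted least-squares line
and reads off its value at x. Writing S_{n,j}(x) = sum_i K((X_i-x)/h)(X_i-x)^j,
the raw weight on observation i is

    b_i(x) = K((X_i - x)/h) * (S_{n,2}(x) - (X_i - x) S_{n,1}(x)),

and the normalised weights l_i(x) = b_i(x) / sum_j b_j(x) satisfy
sum_i l_i(x) = 1 and sum_i l_i(x)(X_i - x) = 0, which is why the smoother
reproduces affine functions exactly. Stacking the weight vectors evaluated
at every design point gives the smoother matrix; its trace is the effective
degrees of freedom of the fit.

Bandwidth selection is leave-one-out cross-validation. For this smoother the
diagonal shortcut (drop the self-weight and renormalise the row) coincides
exactly with refitting without the held-out point, because the moment sums
S_{n,1}, S_{n,2} at x = X_r are unchanged when observation r is removed
(the (X_r - X_r)^j factors vanish).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import KernelSpec, kernel_eval

__all__ = [
    "SmootherWeights",
    "SmootherMatrix",
    "moment_sum",
    "local_linear_weights",
    "smoother_matrix",
    "cv_bandwidth",
    "default_h_grid",
]


@dataclass
class SmootherWeights:
    at_point: float
    weights: np.ndarray
    bandwidth: float
    kernel: KernelSpec


@dataclass
class SmootherMatrix:
    matrix: np.ndarray
    effective_df: float


def _check_h(h: float) -> None:
    if not (np.isfinite(h) and h > 0):
        raise ValueError(f"bandwidth h must be a positive real, got {h!r}")


def moment_sum(X, x: float, h: float, j: int, kernel: KernelSpec = KernelSpec()) -> float:
    """Kernel moment sum S_{n,j}(x) = sum_i K((X_i - x)/h) (X_i - x)^j."""
    _check_h(h)
    if j not in (0, 1, 2):
        raise ValueError(f"moment order j must be 0, 1 or 2, got {j!r}")
    X = np.asarray(X, dtype=float)
    d = X - x
    return float(np.sum(kernel_eval(kernel, d / h) * d**j))


def _raw_weight_matrix(
    X: np.ndarray, xs: np.ndarray, h: float, kernel: KernelSpec, K: np.ndarray | None = None
) -> np.ndarray:
    """Rows of b_i(x) for each evaluation point in xs; shape (m, n)."""
    D = X[None, :] - xs[:, None]  # (m, n), entry = X_i - x
    if K is None:
        K = kernel_eval(kernel, D / h)
    # rescale rows by their largest absolute weight: cancels in the
    # normalised l_i but keeps the moment products away from underflow
    rowmax = np.abs(K).max(axis=1, keepdims=True)
    K = K / np.maximum(rowmax, 1e-300)
    KD = K * D
    S1 = np.sum(KD, axis=1, keepdims=True)
    S2 = np.sum(KD * D, axis=1, keepdims=True)
    return K * S2 - KD * S1


def _normalise_rows(B: np.ndarray, K: np.ndarray, xs: np.ndarray, h: float) -> np.ndarray:
    denom = B.sum(axis=1)
    # For a nonnegative kernel, sum b = S0*S2 - S1^2 >= 0 (Cauchy-Schwarz);
    # it degenerates when fewer than 2 distinct points carry kernel mass.
    scale = np.maximum(np.abs(B).sum(axis=1), 1e-300)
    nz = (K > 0).sum(axis=1)
    bad = (np.abs(denom) <= 1e-12 * scale) | (nz < 2)
    if np.any(bad):
        x_bad = xs[np.argmax(bad)]
        raise ValueError(
            f"degenerate local-linear window at x={x_bad:.6g} with h={h:.6g}: "
            "fewer than two distinct observations receive kernel weight"
        )
    return B / denom[:, None]


def local_linear_weights(X, x: float, h: float, kernel: KernelSpec = KernelSpec()) -> SmootherWeights:
    """Normalised local-linear weights l_i(x); sums to 1 and is orthogonal to X - x."""
    _check_h(h)
    X = np.asarray(X, dtype=float)
    xs = np.asarray([x], dtype=float)
    K = kernel_eval(kernel, (X[None, :] - xs[:, None]) / h)
    B = _raw_weight_matrix(X, xs, h, kernel, K)
    L = _normalise_rows(B, K, xs, h)
    return SmootherWeights(at_point=float(x), weights=L[0], bandwidth=float(h), kernel=kernel)


def weight_matrix(X, xs, h: float, kernel: KernelSpec = KernelSpec()) -> np.ndarray:
    """Matrix of local-linear weights, row g = l_.(xs[g]); shape (len(xs), n)."""
    _check_h(h)
    X = np.asarray(X, dtype=float)
    xs = np.asarray(xs, dtype=float)
    K = kernel_eval(kernel, (X[None, :] - xs[:, None]) / h)
    B = _raw_weight_matrix(X, xs, h, kernel, K)
    return _normalise_rows(B, K, xs, h)


def smoother_matrix(X, h: float, kernel: KernelSpec = KernelSpec()) -> SmootherMatrix:
    """Smoother matrix at the design points; effective df is its trace."""
    X = np.asarray(X, dtype=float)
    L = weight_matrix(X, X, h, kernel)
    return SmootherMatrix(matrix=L, effective_df=float(np.trace(L)))


def default_h_grid(X, num: int = 20) -> np.ndarray:
    """Log-spaced bandwidth grid from 0.05 to 1.0 times sd(X)."""
    s = float(np.std(np.asarray(X, dtype=float)))
    if s <= 0:
        raise ValueError("predictor is constant; no bandwidth grid can be formed")
    return s * np.geomspace(0.05, 1.0, num)


def _loo_residuals_fused(
    D: np.ndarray, Y: np.ndarray, h: float, kernel: KernelSpec
) -> np.ndarray:
    """Exact leave-one-out residuals from a precomputed distance matrix.

    Removing observation r leaves S_{n,1}(X_r) and S_{n,2}(X_r) unchanged
    (the dropped summands carry (X_r - X_r)^j = 0), so only the row sum of
    the raw weights loses the self-term b_r = K(0) S_{n,2}. Everything
    reduces to row sums and two matrix-vector products — no n x n raw
    weight matrix is formed. Raises ValueError when a held-out window
    degenerates (bandwidth too small for the design).
    """
    K = kernel_eval(kernel, D / h)
    np.fill_diagonal(K, 0.0)  # self point held out
    # per-row rescaling: the scale cancels in b_i / sum b_j but prevents
    # underflow of the moment products at isolated design points
    rowmax = K.max(axis=1)
    if np.any(rowmax <= 0.0):
        raise ValueError(f"degenerate leave-one-out window for h={h:.6g}")
    K = K / rowmax[:, None]
    KD = K * D
    S0 = K.sum(axis=1)
    S1 = KD.sum(axis=1)
    S2 = np.einsum("ij,ij->i", KD, D)
    denom = S0 * S2 - S1 * S1  # >= 0 by Cauchy-Schwarz
    scale = np.maximum(S0 * S2 + S1 * S1, 1e-300)
    nz = (K > 0).sum(axis=1)  # neighbours excluding self
    if np.any((np.abs(denom) <= 1e-12 * scale) | (nz < 2)):
        raise ValueError(f"degenerate leave-one-out window for h={h:.6g}")
    numer = S2 * (K @ Y) - S1 * (KD @ Y)
    return Y - numer / denom


def _loo_residuals(X: np.ndarray, Y: np.ndarray, h: float, kernel: KernelSpec) -> np.ndarray:
    """Exact leave-one-out residuals Y_r - fhat_{-r}(X_r) for one bandwidth."""
    X = np.asarray(X, dtype=float)
    D = X[None, :] - X[:, None]
    return _loo_residuals_fused(D, np.asarray(Y, dtype=float), h, kernel)


def cv_bandwidth(X, Y, h_grid=None, kernel: KernelSpec = KernelSpec()) -> float:
    """Bandwidth minimising the leave-one-out CV score over a grid.

    Bandwidths whose windows degenerate once a point is held out are
    excluded. Ties (scores equal within a 1e-10 relative band) are broken
    toward the larger bandwidth, preferring the smoother fit.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if h_grid is None:
        h_grid = default_h_grid(X)
    h_grid = np.sort(np.asarray(h_grid, dtype=float))
    if h_grid.size == 0:
        raise ValueError("empty bandwidth grid")
    D = X[None, :] - X[:, None]  # shared across the grid
    scores: list[tuple[float, float]] = []
    for h in h_grid:
        _check_h(h)
        try:
            r = _loo_residuals_fused(D, Y, h, kernel)
        except ValueError:
            continue
        scores.append((float(h), float(np.sum(r * r))))
    if not scores:
        raise ValueError("no bandwidth in the grid yields valid leave-one-out windows")
    best = min(s for _, s in scores)
    tol = 1e-10 * (1.0 + best)
    return max(h for h, s in scores if s <= best + tol)
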