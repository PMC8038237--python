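"""Kernel functions for local smoothing and the flat-top comparator.

Two roles are covered here. The second-order kernels (Gaussian,
Epanechnikov) weight observations inside the local-linear smoother. The
flat-top kernel is an *infinite-order* kernel: its characteristic function
equals 1 on a neighbourhood of the origin, which drives the bias of a kernel
estimate below any polynomial order for sufficiently smooth targets. A
Nadaraya-Watson regression built on it serves as the low-bias comparator
curve that the tilting step tries to match.

The flat-top family implemented is the trapezoidal-spectrum one: the
characteristic function is 1 on [-1, 1] and decays linearly to 0 at
+-(1 + taper). Its inverse Fourier transform has the closed form

    K(u) = (cos u - cos((1 + taper) u)) / (pi * taper * u^2),

with K(0) = (2 + taper) / (2 pi). K integrates to 1, is symmetric, attains
its maximum at 0, and takes negative values in its oscillating tails, as any
infinite-order kernel must.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "KernelSpec",
    "kernel_eval",
    "flat_top_regression_estimate",
]

_FAMILIES = ("gaussian", "epanechnikov", "flat_top")


@dataclass(frozen=True)
class KernelSpec:
    """Identity of a smoothing kernel.

    Parameters
    ----------
    family : {"gaussian", "epanechnikov", "flat_top"}
        Kernel family. ``gaussian`` and ``epanechnikov`` are the standard
        second-order choices for local-linear smoothing; ``flat_top`` is the
        infinite-order comparator kernel.
    taper : float
        Flat-top only: width of the linear spectral taper as a fraction of
        the flat region. The characteristic function is 1 on [-1, 1] and
        reaches 0 at ``1 + taper``.
    """

    family: str = "gaussian"
    taper: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.family == "flat_top" and not (np.isfinite(self.taper) and self.taper > 0):
            raise ValueError(f"flat_top taper must be a positive real, got {self.taper!r}")


def _flat_top(u: np.ndarray, taper: float) -> np.ndarray:
    """Closed-form trapezoidal-spectrum flat-top kernel, stable near 0."""
    u = np.asarray(u, dtype=float)
    a = 1.0 + taper
    small = np.abs(u) < 1e-5
    us = np.where(small, 1.0, u)  # placeholder to avoid 0/0
    out = (np.cos(us) - np.cos(a * us)) / (np.pi * taper * us * us)
    # 4th-order Taylor expansion around 0 for the removable singularity
    series = ((a * a - 1.0) / 2.0 - (a**4 - 1.0) * u * u / 24.0) / (np.pi * taper)
    return np.where(small, series, out)


def kernel_eval(spec: KernelSpec, u):
    """Evaluate the kernel K(u); vectorised over `u`.

    Gaussian and Epanechnikov values are nonnegative; the flat-top kernel
    oscillates below zero in its tails. All families are symmetric in u.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("kernel argument u must be finite")
    if spec.family == "gaussian":
        # standard normal density, written out: scipy's dist machinery is
        # far too slow on the large distance matrices used in smoothing
        return np.exp(-0.5 * u * u) * (1.0 / np.sqrt(2.0 * np.pi))
    if spec.family == "epanechnikov":
        inside = np.abs(u) <= 1.0
        return np.where(inside, 0.75 * (1.0 - u * u), 0.0)
    return _flat_top(u, spec.taper)


def flat_top_regression_estimate(
    X,
    Y,
    h_ft: float,
    grid,
    taper: float = 0.5,
):
    """Nadaraya-Watson regression estimate with the flat-top kernel.

    This is the comparator curve for the tilting step: m(g) =
    sum_i K((X_i - g)/h) Y_i / sum_i K((X_i - g)/h). Because the flat-top
    kernel is signed, the denominator can vanish for badly chosen
    bandwidths; that condition is reported as an error naming the grid
    point rather than returning a non-finite value.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if X.shape != Y.shape or X.ndim != 1:
        raise ValueError("X and Y must be one-dimensional with equal length")
    if X.size < 3:
        raise ValueError("flat-top regression needs at least 3 observations")
    if not (np.isfinite(h_ft) and h_ft > 0):
        raise ValueError(f"bandwidth h_ft must be positive, got {h_ft!r}")

    spec = KernelSpec("flat_top", taper)
    W = kernel_eval(spec, (grid[:, None] - X[None, :]) / h_ft)  # (G, n)
    denom = W.sum(axis=1)
    scale = X.size * kernel_eval(spec, 0.0)
    bad = np.abs(denom) < 1e-10 * scale
    if np.any(bad):
        g_bad = grid[np.argmax(bad)]
        raise ValueError(
            f"flat-top comparator degenerate at grid point {g_bad:.6g}: "
            f"total kernel weight ~ 0 (bandwidth {h_ft:.6g} too small)"
        )
    return (W @ Y) / denom
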