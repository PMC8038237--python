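"""Synthetic diabetic ocular-surface cohorts.

The generator emulates the statistical structure of the study data behind
the tilted additive model: marginal means and SDs of the clinical
covariates, the reported pairwise Pearson correlations, right-skew for
daily urinary protein excretion (UPE) and hypertension duration (HTN_Dur),
a binary Gender and a 4-level eye Area factor, and an outcome (AOV, the
fraction of the ocular-surface image occupied by vessels) built from known
linear effects plus smooth nonlinear component functions with documented
shapes: the A1C effect peaks near 9%, the UPE effect is flat below ~650
mg/d then rises, the BMI effect has maxima near 24 and 39, and the BUN
effect oscillates with a dip over 15-20.

Continuous covariates are drawn through a Gaussian copula. Marginals are
normal except UPE and HTN_Dur, which are lognormal moment-matched to the
target mean/SD. Because a lognormal transform attenuates Pearson
correlation, the latent Gaussian correlations are pre-corrected with the
exact normal/lognormal attenuation formulas so the *observed* Pearson
correlations hit their targets. Every cohort carries its ground truth
(component functions evaluated per row, coefficients, noise draws), so the
outcome is exactly reconstructible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .additive import TermSpec

__all__ = [
    "CohortParams",
    "SyntheticCohort",
    "generate_cohort",
    "default_structural_model",
    "study_terms",
]

_VARS = ["Age", "BMI", "HTN_Dur", "UPE", "GFR", "A1C", "BUN", "FBS", "S_cr", "MAP"]

_DEFAULT_MARGINALS = {
    "Age": (47.79, 3.70),
    "BMI": (28.66, 4.81),
    "HTN_Dur": (23.98, 29.56),
    "UPE": (433.3, 310.70),
    "GFR": (80.14, 25.76),
    "A1C": (8.824, 1.85),
    "BUN": (13.55, 4.44),
    "FBS": (166.20, 54.76),
    "S_cr": (1.11, 0.20),
    "MAP": (100.06, 15.43),
}

_SKEWED = ("HTN_Dur", "UPE")  # lognormal marginals

_DEFAULT_CORRELATIONS = [
    ("Age", "HTN_Dur", 0.22),
    ("Age", "GFR", -0.16),
    ("Age", "A1C", 0.21),
    ("BMI", "HTN_Dur", 0.45),
    ("BMI", "GFR", 0.16),
    ("BMI", "S_cr", 0.25),
    ("BMI", "MAP", 0.30),
    ("HTN_Dur", "A1C", 0.20),
    ("HTN_Dur", "MAP", 0.19),
    ("HTN_Dur", "BUN", -0.20),
    ("UPE", "BUN", -0.20),
    ("UPE", "S_cr", 0.46),
    ("GFR", "BUN", -0.23),
    ("GFR", "S_cr", -0.35),
    ("A1C", "BUN", -0.23),
    ("BUN", "S_cr", 0.17),
    ("S_cr", "MAP", 0.24),
]


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration; defaults are the study's reported values.

    noise_sd (0.012 on the AOV scale) and the smooth-component SD
    (component_sd = 0.01) are calibration choices documented in the methods
    note, not reported quantities. The intercept places the mean AOV near
    0.15 so essentially no draw leaves (0, 1).
    """

    n: int = 168
    seed: int = 0
    marginals: dict = field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    correlations: tuple = tuple(_DEFAULT_CORRELATIONS)
    female_fraction: float = 60.0 / 168.0
    linear_effects: dict = field(
        default_factory=lambda: {"Age": -0.002, "MAP": 0.0005, "Area3": 0.0123}
    )
    noise_sd: float = 0.012
    intercept: float = 0.1925
    component_sd: float = 0.01


@dataclass
class SyntheticCohort:
    table: pd.DataFrame
    truth: dict
    params: CohortParams

    @property
    def n_clipped(self) -> int:
        return int(self.truth["clipped"].sum())


def _lognormal_sigma(mean: float, sd: float) -> float:
    return math.sqrt(math.log1p((sd / mean) ** 2))


def _attenuation_factor(name: str, marginals: dict) -> float:
    """Pearson correlation shrink factor of a marginal vs its latent normal."""
    if name not in _SKEWED:
        return 1.0
    mean, sd = marginals[name]
    s = _lognormal_sigma(mean, sd)
    return s / math.sqrt(math.expm1(s * s))


def _latent_rho(a: str, b: str, rho: float, marginals: dict) -> float:
    """Latent Gaussian correlation that yields Pearson rho after transforms."""
    if a in _SKEWED and b in _SKEWED:
        sa = _lognormal_sigma(*marginals[a])
        sb = _lognormal_sigma(*marginals[b])
        inner = rho * math.sqrt(math.expm1(sa * sa) * math.expm1(sb * sb))
        return math.log1p(inner) / (sa * sb)
    return rho / (_attenuation_factor(a, marginals) * _attenuation_factor(b, marginals))


def _latent_correlation_matrix(params: CohortParams) -> np.ndarray:
    k = len(_VARS)
    R = np.eye(k)
    idx = {v: i for i, v in enumerate(_VARS)}
    for a, b, rho in params.correlations:
        z = _latent_rho(a, b, rho, params.marginals)
        if abs(z) >= 0.999:
            warnings.warn(f"latent correlation for ({a}, {b}) clipped to +-0.999")
            z = math.copysign(0.999, z)
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = z
    w = np.linalg.eigvalsh(R)
    if w.min() < 1e-10:
        warnings.warn("correlation matrix not positive definite; applying nearest-PD repair")
        w, V = np.linalg.eigh(R)
        R = V @ np.diag(np.maximum(w, 1e-8)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        if np.linalg.eigvalsh(R).min() < 1e-12:
            raise ValueError("correlation matrix remains non-positive-definite after repair")
    return R


# ---------------------------------------------------------------------------
# Structural model: the ground-truth effects on AOV
# ---------------------------------------------------------------------------

def _raw_shapes() -> dict:
    """Unscaled nonlinear shapes, before centring and amplitude scaling."""
    return {
        "A1C": lambda x: np.exp(-((x - 9.0) ** 2) / (2 * 1.2**2)),
        "UPE": lambda x: np.logaddexp(0.0, (x - 650.0) / 100.0),  # smooth ramp from ~650
        "BMI": lambda x: (
            np.exp(-((x - 24.0) ** 2) / (2 * 2.5**2))
            + 0.9 * np.exp(-((x - 39.0) ** 2) / (2 * 3.0**2))
        ),
        "BUN": lambda x: (
            0.5 * np.sin(2 * np.pi * (x - 5.0) / 10.0)
            - np.exp(-((x - 17.5) ** 2) / (2 * 1.5**2))
        ),
    }


def _marginal_quantiles(name: str, marginals: dict, m: int = 20001) -> np.ndarray:
    mean, sd = marginals[name]
    probs = np.linspace(5e-5, 1 - 5e-5, m)
    if name in _SKEWED:
        s = _lognormal_sigma(mean, sd)
        mu = math.log(mean) - s * s / 2.0
        return stats.lognorm.ppf(probs, s, scale=math.exp(mu))
    return stats.norm.ppf(probs, loc=mean, scale=sd)


def default_structural_model(params: CohortParams | None = None) -> dict:
    """Ground-truth effect specification used to build AOV.

    Linear slopes: Age -0.002 per year, MAP +0.0005 per unit; Area level 3
    offset +0.0123 (levels 2 and 4 at 0, level 1 reference). Smooth
    components for A1C (peak at 9), UPE (flat, then rising past ~650 mg/d),
    BMI (maxima near 24 and 39) and BUN (oscillation with a dip over
    15-20), each centred to mean ~0 against its marginal distribution and
    scaled so its SD on the AOV scale is component_sd. FBS is generated but
    carries no effect.
    """
    if params is None:
        params = CohortParams()
    raw = _raw_shapes()
    smooth = {}
    for name, fn in raw.items():
        q = _marginal_quantiles(name, params.marginals)
        vals = fn(q)
        scale = params.component_sd / float(np.std(vals))
        center = float(np.mean(vals)) * scale
        smooth[name] = _CenteredShape(fn, scale, center)
    return {
        "linear": {"Age": params.linear_effects.get("Age", -0.002),
                   "MAP": params.linear_effects.get("MAP", 0.0005)},
        "area_effects": {1: 0.0, 2: 0.0, 3: params.linear_effects.get("Area3", 0.0123), 4: 0.0},
        "smooth": smooth,
        "intercept": params.intercept,
        "noise_sd": params.noise_sd,
    }


class _CenteredShape:
    """Scaled, centred smooth component; picklable and reusable on grids."""

    def __init__(self, fn, scale: float, center: float):
        self._fn = fn
        self.scale = scale
        self.center = center

    def __call__(self, x):
        return self._fn(np.asarray(x, dtype=float)) * self.scale - self.center


def generate_cohort(params: CohortParams | None = None, **overrides) -> SyntheticCohort:
    """Draw one synthetic cohort; deterministic given params.seed."""
    if params is None:
        params = CohortParams()
    if overrides:
        params = replace(params, **overrides)
    n = int(params.n)
    rng = np.random.default_rng(params.seed)

    R = _latent_correlation_matrix(params)
    chol = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, len(_VARS))) @ chol.T

    cols = {}
    for j, name in enumerate(_VARS):
        mean, sd = params.marginals[name]
        if name in _SKEWED:
            s = _lognormal_sigma(mean, sd)
            mu = math.log(mean) - s * s / 2.0
            cols[name] = np.exp(mu + s * Z[:, j])
        else:
            cols[name] = mean + sd * Z[:, j]

    gender = np.where(rng.random(n) < params.female_fraction, "female", "male")
    area = rng.integers(1, 5, size=n)
    noise = rng.normal(0.0, params.noise_sd, size=n)

    model = default_structural_model(params)
    components = {
        "Age": model["linear"]["Age"] * cols["Age"],
        "MAP": model["linear"]["MAP"] * cols["MAP"],
        "Area": np.array([model["area_effects"][a] for a in area]),
    }
    for name, fn in model["smooth"].items():
        components[name] = fn(cols[name])

    raw = params.intercept + sum(components.values()) + noise
    clipped = (raw <= 0.0) | (raw >= 1.0)
    aov = np.clip(raw, 1e-9, 1.0 - 1e-9)

    table = pd.DataFrame(cols)
    table["Gender"] = gender
    table["Area"] = area
    table["AOV"] = aov

    truth = {
        "intercept": params.intercept,
        "components": components,
        "coefficients": {
            "Age": model["linear"]["Age"],
            "MAP": model["linear"]["MAP"],
            "Area3": model["area_effects"][3],
        },
        "smooth_functions": model["smooth"],
        "noise": noise,
        "clipped": clipped,
        "raw_outcome": raw,
    }
    return SyntheticCohort(table=table, truth=truth, params=params)


def study_terms() -> list[TermSpec]:
    """The study's final semiparametric composition.

    Age, HTN_Dur, GFR, S_cr and MAP enter linearly; BMI, UPE, A1C and BUN
    as tilted smooth terms; Gender and Area as categorical factors.
    """
    return [
        TermSpec("Age", "linear"),
        TermSpec("HTN_Dur", "linear"),
        TermSpec("GFR", "linear"),
        TermSpec("S_cr", "linear"),
        TermSpec("MAP", "linear"),
        TermSpec("Gender", "categorical"),
        TermSpec("Area", "categorical"),
        TermSpec("BMI", "smooth"),
        TermSpec("UPE", "smooth"),
        TermSpec("A1C", "smooth"),
        TermSpec("BUN", "smooth"),
    ]
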