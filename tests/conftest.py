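import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tiltam as tm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_data(rng):
    """n=200 noisy sine: the workhorse one-dimensional smoothing example."""
    x = np.sort(rng.uniform(0.0, 1.0, 200))
    f = np.sin(2.0 * np.pi * x)
    y = f + rng.normal(0.0, 0.3, 200)
    return x, y, f


@pytest.fixture
def two_term_data(rng):
    """Smooth + linear additive truth: y = 1 + sin(2 pi x1) + 2 x2 + eps."""
    n = 500
    x1 = rng.uniform(0.0, 1.0, n)
    x2 = rng.standard_normal(n)
    f1 = np.sin(2.0 * np.pi * x1)
    y = 1.0 + f1 + 2.0 * x2 + rng.normal(0.0, 0.2, n)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    terms = [tm.TermSpec("x1", "smooth"), tm.TermSpec("x2", "linear")]
    return X, y, f1, terms


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic cohort at the study's sample size."""
    return tm.generate_cohort(n=300, seed=7)
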