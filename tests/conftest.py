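import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

import sasmodelfit as sm


@pytest.fixture
def gold_curve():
    """One gold-like synthetic curve (seed 0) with its truth record."""
    return sm.generate(sm.gold_like_spec(seed=0))


@pytest.fixture
def random_curve_factory():
    """Seeded random curves with positive sigma, for reduction tests."""

    def make(seed, n=200):
        rng = np.random.default_rng(seed)
        q = np.sort(rng.uniform(0.05, 3.0, n))
        I = np.abs(rng.lognormal(0.0, 1.0, n)) + 0.1
        sigma = rng.uniform(0.01, 0.5, n) * I
        return sm.SASCurve(q, I, sigma)

    return make
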