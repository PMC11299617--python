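import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sasbayes as sb
from sasbayes.synthetic import Scenario, generate_curve

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def priors():
    return sb.PriorSet()


@pytest.fixture(scope="session")
def small_curve():
    """A short noisy two-sphere curve for cheap sampler tests (N = 60)."""
    sc = Scenario(R1=2, S1=250, R2=10, S2=100, B=0.01, T=1.0, N=60)
    return generate_curve(sc, seed=0)


@pytest.fixture(scope="session")
def default_scenario():
    """Equal-scale two-sphere scenario (r_S = 1) at T = 1."""
    return Scenario(R1=2, S1=250, R2=10, S2=250, B=0.01, T=1.0)


@pytest.fixture(scope="session")
def small_chain(small_curve, priors):
    """A short converged-ish K=2 chain reused by estimation/chi2 tests."""
    ladder = sb.geometric_ladder(8, N=small_curve.N)
    return sb.run_remc(
        small_curve, 2, priors, ladder, n_burn=500, n_samples=1000, rng_seed=42
    )
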