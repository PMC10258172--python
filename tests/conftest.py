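import numpy as np
import pytest
from hypothesis import settings

import ijpseudo as ij

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scenario1_sample():
    """One Scenario-1-style cohort: p_Z=.5, b0=b1=eta=.2, p_oc=.2, n=1000."""
    return ij.simulate_cohort(
        ij.ScenarioConfig(p_Z=0.5, beta0=0.2, beta1=0.2, eta=0.2,
                          p_oc=0.2, n=1000), seed=20230508)


@pytest.fixture(scope="session")
def censored_sample():
    """Medium censored cohort without truncation."""
    return ij.simulate_cohort(ij.ScenarioConfig(p_oc=0.3, n=300), seed=7)


@pytest.fixture(scope="session")
def truncated_sample():
    """Left-truncated cohort (entry mass 0.2 at zero, else uniform)."""
    return ij.simulate_truncated_cohort(
        ij.ScenarioConfig(p_oc=0.2, n=400, truncation=True), seed=11)


@pytest.fixture
def tie_sample():
    """Hand-built sample with tied event and censoring times."""
    time = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0])
    status = np.array([1, 0, 2, 1, 1, 0, 2, 0])
    z = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
    return ij.make_sample(time, status, covariates=z[:, None], d=2)


def random_tied_sample(rng, n=50, d=2):
    """Random small sample on a coarse grid so ties are guaranteed."""
    time = rng.integers(1, 8, n) / 2.0
    status = rng.integers(0, d + 1, n)
    if not (status >= 1).any():
        status[0] = 1
    z = rng.random(n)
    return ij.make_sample(time, status, covariates=z[:, None], d=d)
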