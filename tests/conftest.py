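import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fundusindex import CohortConfig, simulate_cohort

settings.register_profile(
    "fundusindex",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fundusindex")


@pytest.fixture(scope="session")
def cohort400():
    """A medium synthetic cohort with default (calibrated) sex effects."""
    config = CohortConfig(n_subjects=400, seed=11)
    records, covariates, features = simulate_cohort(config)
    return config, records, covariates, features


@pytest.fixture()
def rng():
    return np.random.default_rng(20050501)
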