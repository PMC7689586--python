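import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famprs import SimulationConfig, derive_cohort, generate_synthetic_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort_20k():
    """One moderately sized cohort at the default study conditions."""
    cfg = SimulationConfig(n=20_000, seed=11)
    return derive_cohort(generate_synthetic_cohort(cfg))


@pytest.fixture(scope="session")
def cohort_small():
    cfg = SimulationConfig(n=4_000, seed=7)
    return derive_cohort(generate_synthetic_cohort(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
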