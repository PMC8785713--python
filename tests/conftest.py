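import pytest
from hypothesis import HealthCheck, settings

from taigrade.cohort import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """400 simulated patients, enough for model fits in unit tests."""
    return generate_cohort(CohortConfig(n_patients=400, seed=3))


@pytest.fixture(scope="session")
def ref_cohort():
    """10,000 simulated patients at default calibration."""
    return generate_cohort(CohortConfig(n_patients=10_000, seed=11))
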