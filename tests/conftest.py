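import pytest
from hypothesis import HealthCheck, settings

import erythroplan as ep

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    return ep.load_reference_cohort()


@pytest.fixture(scope="session")
def subject01(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def subject02(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def subject20(cohort):
    return cohort[19]


@pytest.fixture(scope="session")
def patient20(subject20):
    """Subject 20 with its second published PV fraction."""
    return subject20.params(subject20.lambdas[1])


@pytest.fixture(scope="session")
def bounds20(subject20):
    return ep.SafetyBounds.default_for(subject20.B)


@pytest.fixture(scope="session")
def insilico_cohort(cohort):
    """Full rejection-sampled cohort (shared across tests; ~30 s once)."""
    return ep.generate_insilico_cohort(cohort, seed=0)
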