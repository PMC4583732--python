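import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey_records():
    """One default synthetic survey, shared across tests."""
    from mtoburden.synthetic_survey import generate

    return generate(seed=1)


@pytest.fixture(scope="session")
def large_survey_records():
    """A 20 000-record draw for Monte-Carlo calibration checks."""
    from mtoburden.synthetic_survey import generate

    return generate(seed=7, n_subsidized=10_000, n_private=10_000)
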