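import pytest
from hypothesis import HealthCheck, settings

from obpi_cea import default_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_case():
    """Packaged base-case configuration and coverage table."""
    return default_config()


@pytest.fixture(scope="session")
def base_config(base_case):
    return base_case[0]


@pytest.fixture(scope="session")
def base_coverage(base_case):
    return base_case[1]
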