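import pytest
from hypothesis import HealthCheck, settings

from srnasig import make_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small():
    """60 features x 20 samples (5 per group), fixed seed."""
    return make_fixture("small")


@pytest.fixture(scope="session")
def medium():
    """600 features x 200 samples (50 per group), the study's design size."""
    return make_fixture("medium")
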