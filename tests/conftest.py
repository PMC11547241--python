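import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dropscreen.assay import build_erbb2_assays  # noqa: E402
from dropscreen.workflows import control_chamber, default_gates, screening_limits  # noqa: E402


@pytest.fixture(scope="session")
def designs():
    return build_erbb2_assays()


@pytest.fixture(scope="session")
def screening(designs):
    return designs[0]


@pytest.fixture(scope="session")
def duplexes(designs):
    return designs[1]


@pytest.fixture(scope="session")
def control(screening):
    return control_chamber(screening, seed=0)


@pytest.fixture(scope="session")
def screen_gates(screening):
    return default_gates(screening, seed=0)


@pytest.fixture(scope="session")
def screen_limits(screening):
    return screening_limits(seed=0, design=screening)
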