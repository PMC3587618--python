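import pytest
from hypothesis import HealthCheck, settings

import envburden as eb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundled():
    return eb.load_bundled()


@pytest.fixture(scope="session")
def bundled_result(bundled):
    """One full national run shared by engine and acceptance tests."""
    mc = eb.MCConfig(iterations=1000, seed=1)
    return eb.run_scenario(bundled, mc)
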