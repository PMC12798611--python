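import pytest
from hypothesis import HealthCheck, settings

from gadsim import default_parameters

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()
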