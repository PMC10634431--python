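import pytest
from hypothesis import HealthCheck, settings

from tcrnorm import reference

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def human():
    return reference.load_reference("homosapiens")


@pytest.fixture(scope="session")
def mouse():
    return reference.load_reference("musmusculus")


@pytest.fixture(scope="session", params=["homosapiens", "musmusculus"])
def species(request):
    return request.param
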