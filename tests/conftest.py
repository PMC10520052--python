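import pytest
from hypothesis import HealthCheck, settings

from ecigrisk.concentrations import load_packaged_summaries
from ecigrisk.exposure import ExposureScenario
from ecigrisk.registry import load_packaged_references

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refs():
    return load_packaged_references()


@pytest.fixture(scope="session")
def summaries():
    return load_packaged_summaries()


@pytest.fixture(scope="session")
def scenario():
    return ExposureScenario.paper_default()
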