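import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    from hkalpha.cluster import build_synthetic_reference

    return build_synthetic_reference(seed=0)


@pytest.fixture(scope="session")
def alleles(ref):
    from hkalpha.cluster import build_allele_library

    return build_allele_library(ref, include_anti37=True)


@pytest.fixture(scope="session")
def panel(ref):
    from hkalpha.pcr import PCRPanel

    return PCRPanel(ref)


@pytest.fixture(scope="session")
def caller(panel):
    from hkalpha.calling import ReflexCaller

    return ReflexCaller(panel)
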