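import pytest
from hypothesis import HealthCheck, settings

from costream import CONCEPT_IDS, evaluate, load_concept

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def concepts():
    return {cid: load_concept(cid) for cid in CONCEPT_IDS}


@pytest.fixture(scope="session")
def statements(concepts):
    return {cid: evaluate(sc) for cid, sc in concepts.items()}
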