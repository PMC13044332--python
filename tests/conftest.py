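import pytest
from hypothesis import HealthCheck, settings

from partitherm.anthropometry import assemble_body
from partitherm.environment import Environment
from partitherm.thermoregulation import HumanSpec

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_human():
    return HumanSpec()


@pytest.fixture(scope="session")
def nude_human():
    return HumanSpec.nude()


@pytest.fixture(scope="session")
def default_parts():
    h = HumanSpec()
    return assemble_body(h.mass, h.total_area, h.height)


@pytest.fixture(scope="session")
def trunk_geometry(default_parts):
    return next(p for p in default_parts if p.part_id == "trunk")


@pytest.fixture
def indoor_env():
    return Environment(TA=21.0, VEL=0.1, RH=50.0)
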