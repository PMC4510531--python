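import datetime

import pytest

import lactodose as ld
from lactodose.registry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def lactating_model(registry):
    return ld.build_lactating_adult_model(registry)


@pytest.fixture(scope="session")
def vapour_acute_30d():
    """Unit acute vapour intake, 30-day trajectory at reference solver settings."""
    return ld.unit_acute_trajectory("vapour_inhalation", 30.0)


@pytest.fixture(scope="session")
def particulate_acute_30d():
    return ld.unit_acute_trajectory("particulate_inhalation", 30.0)


@pytest.fixture(scope="session")
def synthetic_bundle():
    return ld.default_synthetic_bundle(seed=20110311)


@pytest.fixture(scope="session")
def default_scenario():
    return ld.ScenarioConfig(
        origin=datetime.date(2011, 3, 11), end=datetime.date(2011, 4, 30)
    )


@pytest.fixture
def simple_two_compartment():
    """A -> B chain with decay; B accumulates."""
    return ld.CompartmentModel(
        ["A", "B"], {("A", "B"): 0.5}, decay_constant=ld.I131_DECAY_CONSTANT, sinks=["B"]
    )
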