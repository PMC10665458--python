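import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pulseflow import ClimateModel, EmissionInventory, TimeGrid, load_config

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model() -> ClimateModel:
    return ClimateModel(load_config())


@pytest.fixture(scope="session")
def grid100() -> TimeGrid:
    return TimeGrid(horizon_years=100)


@pytest.fixture(scope="session")
def grid500() -> TimeGrid:
    return TimeGrid(horizon_years=500)


def make_inventory(rows) -> EmissionInventory:
    return EmissionInventory.from_frame(
        pd.DataFrame(rows, columns=["region", "species", "gas", "tonnes_per_year"])
    )


@pytest.fixture
def global_inventory() -> EmissionInventory:
    """Published global ruminant totals as a single-region inventory."""
    return make_inventory(
        [
            ("World", "cattle", "CH4", 110e6),
            ("World", "cattle", "N2O", 2.4e6),
        ]
    )
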