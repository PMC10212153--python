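from datetime import date

import pytest

from dielshift import SimulationConfig, SolarContext, simulate_dataset


@pytest.fixture(scope="session")
def study_ctx() -> SolarContext:
    """Solar context at the study area's reference point."""
    return SolarContext(49.4, -122.5, -8.0)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: 12 stations over 6 months, two species."""
    return SimulationConfig(
        n_stations=12,
        extent_m=9_000.0,
        study_start=date(2019, 3, 1),
        study_end=date(2019, 9, 1),
        species_event_means={"coyote": 12.0, "black_bear": 10.0},
        species_intercepts={"coyote": 7.27, "black_bear": 4.70},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_dataset(small_config)
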