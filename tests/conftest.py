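import numpy as np
import pandas as pd
import pytest

from steppedwedge import ScenarioConfig, default_schedule, simulate_dataset


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def small_config(schedule):
    """Default study conditions scaled to 50 respondents per cell."""
    return ScenarioConfig(schedule=schedule, n_per_cell=50, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def full_config(schedule):
    """The reference study conditions: 9 x 12 x 1000."""
    return ScenarioConfig(schedule=schedule, seed=20160)


@pytest.fixture(scope="session")
def full_dataset(full_config):
    return simulate_dataset(full_config)
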