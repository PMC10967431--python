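import numpy as np
import pytest

from pigemit.scenario import ls_preset, ss_preset
from pigemit.weather import weather_fixture


@pytest.fixture(scope="session")
def fixture_weather():
    """One deterministic synthetic year (plus calendar overhang)."""
    return weather_fixture(1234, n_days=380)


@pytest.fixture(scope="session")
def ls_scenario():
    return ls_preset()


@pytest.fixture(scope="session")
def ss_scenario():
    return ss_preset()


@pytest.fixture
def rng():
    return np.random.default_rng(7)
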