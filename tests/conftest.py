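import pytest

from bibvent import PlantParams
from bibvent.verify import (ARDS_TEST_LUNG, DECREASING_PRESSURE_SETTINGS,
                            run_step_response, run_to_steady)


@pytest.fixture(scope="session")
def plant():
    return PlantParams()


@pytest.fixture(scope="session")
def ards_lung():
    return ARDS_TEST_LUNG


@pytest.fixture(scope="session")
def step_response(plant):
    """One 400->600 mL VT step on the ARDS test lung (shared: it is the
    most expensive closed-loop run in the suite)."""
    return run_step_response(plant)


@pytest.fixture(scope="session")
def nominal_supply_result(plant, ards_lung):
    """10 settled cycles at the nominal 4.0 bar, VT=600, RR=25, I:E=1:2."""
    return run_to_steady(DECREASING_PRESSURE_SETTINGS, plant, ards_lung)
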