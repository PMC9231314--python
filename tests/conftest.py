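import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsfvirome.eve_caller import call_eves
from bsfvirome.synthetic_data import default_eve_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def scenario():
    """The canonical three-assembly synthetic world (fixed seed)."""
    return default_eve_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario_calls(scenario):
    """EVE calls of the full pipeline on the canonical world."""
    return call_eves(
        scenario.assemblies, scenario.viral_proteome, scenario.host_proteome
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
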