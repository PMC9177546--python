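import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ifascal import (
    CompositeMeasurements,
    EffluentEvaluator,
    PlantConfig,
    default_registry,
    fractionate_influent,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def calibration_composites():
    return CompositeMeasurements(cod=626.0, bod=306.0, tss=384.0,
                                 nh3=33.7, tkn=44.2, tn=46.7)


@pytest.fixture(scope="session")
def influent(calibration_composites):
    state, _ = fractionate_influent(calibration_composites)
    return state


@pytest.fixture(scope="session")
def plant_config():
    return PlantConfig()


@pytest.fixture(scope="session")
def evaluator(influent, plant_config, registry):
    """Session-wide warm evaluator over the bundled calibration regime."""
    return EffluentEvaluator(influent, plant_config, registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
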