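import numpy as np
import pytest

from aerompc import PlantParameters, PlantState
from aerompc.model import InfluentRecord


@pytest.fixture(scope="session")
def params() -> PlantParameters:
    return PlantParameters()


@pytest.fixture
def nominal_state() -> PlantState:
    """A loaded reactor state used by the worked hand-evaluated examples."""
    return PlantState(X_COD=100.0, S_O=2.0, S_NH=20.0, S_NO=5.0,
                      X_BH=2000.0, X_BA=100.0)


@pytest.fixture
def nominal_influent() -> InfluentRecord:
    return InfluentRecord(t=0.0, Qin=7500.0, XCOD_in=500.0, SNH_in=35.0,
                          XBH_in=30.0)


def random_admissible_state(rng: np.random.Generator) -> np.ndarray:
    """Random nonnegative state spanning realistic operating magnitudes."""
    scale = np.array([500.0, 8.0, 50.0, 30.0, 6000.0, 500.0])
    return rng.uniform(0.0, 1.0, 6) * scale


def random_influent(rng: np.random.Generator, t: float = 0.0) -> InfluentRecord:
    return InfluentRecord(
        t=t, Qin=rng.uniform(3000.0, 12000.0),
        XCOD_in=rng.uniform(400.0, 650.0),
        SNH_in=rng.uniform(25.0, 50.0),
        XBH_in=rng.uniform(0.0, 60.0))
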