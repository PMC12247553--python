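import numpy as np
import pytest

from qmtsim.mt_core import SystemPars, TissuePars, default_r2sl_grid
from qmtsim.sequence_engine import PulseTrain, default_train


@pytest.fixture(scope="session")
def grid():
    """Warm the process-wide R2s,l lookup grid once."""
    return default_r2sl_grid()


@pytest.fixture(scope="session")
def wm():
    """Healthy white-matter ROI means (rates from the tabulated times)."""
    return TissuePars(m0s=0.212, R1f=1 / 1.84, R2f=1 / 0.0769, Rx=13.6,
                      R1s=1 / 0.34, T2s=12.5e-6)


@pytest.fixture(scope="session")
def gm():
    return TissuePars(m0s=0.098, R1f=1 / 2.46, R2f=1 / 0.083, Rx=14.0,
                      R1s=1 / 0.42, T2s=14.4e-6)


@pytest.fixture(scope="session")
def sys0():
    return SystemPars()


@pytest.fixture(scope="session")
def sys_off():
    """Off-resonance + transmit-scale + complex-M0 system."""
    return SystemPars(omega_z=30.0, b1=1.05, M0=0.9 + 0.3j)


@pytest.fixture(scope="session")
def train200():
    return default_train(n_pulses=200)


@pytest.fixture(scope="session")
def train100():
    return default_train(n_pulses=100)


@pytest.fixture(scope="session")
def train_tiny():
    return default_train(n_pulses=40)
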