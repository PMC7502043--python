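import numpy as np
import pytest

from mtprep import (
    ImagingModule,
    MTPreparation,
    SimulationProtocol,
    TissueParameters,
    make_sinc_pulse,
)

MYO = TissueParameters(t1_free=1.1, t2_free=0.055, psr=0.15, exchange_rate=50.0)


@pytest.fixture(scope="session")
def myocardium():
    return MYO


@pytest.fixture(scope="session")
def human_prep():
    """Human-study saturation train: 20 x 800 deg Sinc at 3 kHz off-resonance."""
    pulse = make_sinc_pulse(800.0, 20.48e-3, 270.0, 50e-6, 3000.0)
    return MTPreparation(pulse=pulse, n_pulses=20)


@pytest.fixture(scope="session")
def animal_prep():
    """Animal-study saturation train: 10 x 720 deg Sinc at 1.5 kHz."""
    pulse = make_sinc_pulse(720.0, 20.48e-3, 270.0, 50e-6, 1500.0)
    return MTPreparation(pulse=pulse, n_pulses=10)


@pytest.fixture(scope="session")
def spgr():
    return ImagingModule("spgr", tr=3.8e-3, te=1.6e-3, flip_deg=15.0)


@pytest.fixture(scope="session")
def bssfp():
    return ImagingModule("bssfp", tr=3.2e-3, te=1.4e-3, flip_deg=70.0)


@pytest.fixture(scope="session")
def protocol():
    return SimulationProtocol(heart_rate=65.0, n_heartbeats=5, measure_beat=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
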