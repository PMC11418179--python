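import numpy as np
import pytest

from strikescape import (
    CalibrationRecord,
    SimulationDesign,
    StrikeKinParams,
    calibrate,
    simulate_strike_track,
)


@pytest.fixture
def default_kin():
    """A physically typical strike: 5 mm gape, 7 mm protrusion, 120 deg,
    10 ms TTPG, 0.2 m/s ram."""
    return StrikeKinParams(5.0, 7.0, 120.0, 10.0, 0.2)


@pytest.fixture
def clean_track(default_kin):
    """Noiseless calibrated track with its ground truth."""
    track, truth = simulate_strike_track(default_kin, noise_sd_mm=0.0, seed=0)
    return calibrate(track, CalibrationRecord("s0", 40.0)), truth


@pytest.fixture
def design():
    return SimulationDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
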