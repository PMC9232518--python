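import numpy as np
import pytest

from bsfc import AcquisitionConfig, NoiseModel
from bsfc.config import CHANNELS

ZERO_PER_CHANNEL = {c: 0.0 for c in CHANNELS}


@pytest.fixture
def acq10s() -> AcquisitionConfig:
    """Short (10 s) acquisition used throughout the suite; full-length
    90 s segments behave identically but dominate runtime."""
    return AcquisitionConfig(segment_duration_s=10.0)


@pytest.fixture
def silent_noise() -> NoiseModel:
    """No baseline, drift or white noise: pulses only."""
    return NoiseModel(
        baseline=dict(ZERO_PER_CHANNEL),
        drift_amplitude=0.0,
        white_sigma=dict(ZERO_PER_CHANNEL),
        blood_background_scale=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
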