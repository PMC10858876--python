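import warnings

import numpy as np
import pytest

from periseizure import SimulationConfig


@pytest.fixture(autouse=True)
def _silence_clip_warnings():
    """Synthetic defaults use a 360-s session, exactly the analysis window;
    tests that deliberately shorten records assert their own warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def noise_free_cfg() -> SimulationConfig:
    """All stochastic and artifact sources off; latents pinned by the test."""
    return SimulationConfig(
        noise_sd_eeg=0.0,
        motion_sd=0.0,
        calcium_noise_sd=0.0,
        noise_sd_photometry=0.0,
        ad_gain_jitter_sd=0.0,
        bleach_slope=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_tone(freq_hz: float, amplitude: float, fs: float, duration_s: float):
    t = np.arange(int(round(duration_s * fs))) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t)
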