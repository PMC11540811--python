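import numpy as np
import pytest

from pulseflux import SimConfig, generate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """Short noiseless recording with exact ground truth (session-cached)."""
    cfg = SimConfig(
        duration_s=60.0,
        fs=250.0,
        heart_rate_bpm=65.0,
        measurement_noise_sd=0.0,
        feature_noise_sd=0.0,
        envelope_phase=0.0,
        seed=11,
    )
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def noisy_recording():
    """Short recording under the default noise model (session-cached)."""
    cfg = SimConfig(duration_s=60.0, fs=250.0, envelope_phase=0.0, seed=7)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
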