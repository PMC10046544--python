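import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neuroage as na

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_eeg():
    """Signal config with background, line noise and artifacts switched off."""
    return dataclasses.replace(
        na.EEGConfig(),
        duration_s=30.0,
        pink_noise_amp_uv=0.0,
        line_noise_amp_uv=0.0,
        artifact_rate_per_min=0.0,
        feature_noise_sd_hz=0.0,
    )


@pytest.fixture
def tone_recording():
    """Pure 10 Hz unit-amplitude sinusoid on all 19 channels, 30 s at 256 Hz."""
    fs = 256.0
    t = np.arange(int(30 * fs)) / fs
    x = np.sin(2 * np.pi * 10.0 * t)
    return na.Recording(
        data=np.tile(x, (19, 1)), channel_labels=na.STANDARD_1020, fs_hz=fs, subject_id="tone"
    )


def small_arm(**overrides):
    """A compact arm configuration for fast generator tests."""
    base = dict(
        name="arm",
        n_subjects=12,
        ca_mean=50.0,
        ca_sd=8.0,
        female_fraction=0.5,
        baseline_gap_mean=-5.0,
        baseline_gap_sd=8.0,
        effect_mean_older_stratum=-4.0,
        effect_mean_younger_stratum=-1.0,
        effect_sd=1.0,
        followup_mean_months=13.0,
        followup_sd_months=1.0,
    )
    base.update(overrides)
    return na.ArmConfig(**base)
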