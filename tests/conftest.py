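import numpy as np
import pandas as pd
import pytest

from laterotrace import LateralizationProfile, RecordingSession, SimConfig


@pytest.fixture
def flat_profile():
    """Constant right-bias profile over a 21-day exposure."""
    def make(g: float = 1.0, condition: str = "test") -> LateralizationProfile:
        return LateralizationProfile(condition, (((0, 20), g),))
    return make


@pytest.fixture
def small_config():
    """Economical generator settings for fast tests."""
    def make(**overrides) -> SimConfig:
        defaults = dict(
            seed=0, sample_rate=2000.0, n_channels_per_hemisphere=2,
            n_stimuli=2, n_presentations=25, stimulus_duration=0.3,
            isi=1.0, baseline_noise_rms=5e-6, evoked_amplitude=2e-5,
            adaptation_fraction=0.1, non_adapting_site_fraction=0.0,
        )
        defaults.update(overrides)
        return SimConfig(**defaults)
    return make


@pytest.fixture
def handmade_session():
    """Tiny hand-built session: 2 channels, 2 trials, known evoked RMS.

    Trial window 1.0 s at 1 kHz; onset 0.6 s, duration 0.2 s, so the
    stimulus window is [0.6, 0.9) and the baseline window [0.1, 0.6).
    The stimulus window carries a constant level per (trial, channel).
    """
    fs = 1000.0
    n_samples = 1000
    levels = np.array([[2.0, 3.0], [4.0, 6.0]])  # (trial, channel)
    traces = np.zeros((2, 2, n_samples))
    traces[:, :, 600:900] = levels[:, :, None]
    channels = pd.DataFrame(
        {"channel": ["ch00", "ch01"], "hemisphere": ["L", "R"], "depth_um": [1500.0, 1500.0]}
    )
    events = pd.DataFrame(
        {
            "trial": [0, 1],
            "stimulus": ["s0", "s0"],
            "presentation": [1, 2],
            "onset": [0.6, 0.6],
            "duration": [0.2, 0.2],
            "time": [0.6, 2.6],
        }
    )
    meta = {"subject": "b0", "day": 0, "condition": "test", "modality": "MUA"}
    return RecordingSession(traces, fs, channels, events, meta), levels
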