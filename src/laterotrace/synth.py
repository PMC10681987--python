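"""Synthetic bilateral auditory recordings, ERP sessions, stimuli and operant logs.

The generator produces data with the statistical structure the analysis
stages assume, so the whole pipeline is testable without animal recordings:

* **Depth (MUA-like) sessions** — per-trial background Gaussian noise of RMS
  sigma_b plus, during the stimulus-on window, a per-stimulus noise token
  whose RMS is ``A * h(c) * (1 - k_c)**(t - 1)`` for presentation t: geometric
  stimulus-specific adaptation with per-repetition decrement k, and a
  hemispheric gain ``h(c) = g`` on right-hemisphere channels (g from the
  exposure-condition profile) and 1 on the left.
* **Epidural (ERP-like) sessions** — a deterministic damped-oscillation
  template confined to the stimulus window, scaled per channel, plus
  independent per-trial noise; 8 pins in four left/right x caudal/rostral
  quadrants with caudal pins carrying a higher evoked gain.
* **Operant logs** — Bernoulli correct/incorrect trials following a
  saturating per-day learning curve, with Go/NoGo types exactly balanced
  25/25 within each 50-trial block.

All randomness flows from ``SimConfig.seed`` through per-session
``numpy.random.SeedSequence`` streams keyed by (seed, modality tag, day), so
any session is independently reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .config import BehaviorSimConfig, LateralizationProfile, SimConfig
from .session import RecordingSession

_DAY_OFFSET = 4096  # SeedSequence entries must be non-negative
_TAG_MUA, _TAG_ERP, _TAG_BEHAVIOR, _TAG_STIMULUS = 0, 1, 2, 3


def _session_rng(seed: int, tag: int, day: int, extra: int = 0) -> np.random.Generator:
    if day + _DAY_OFFSET < 0:
        raise ValueError(f"day {day} below supported range (-{_DAY_OFFSET})")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), tag, day + _DAY_OFFSET, extra])
    )


def _stimulus_token(seed: int, stimulus: int, n_samples: int) -> np.ndarray:
    """Frozen per-stimulus noise token, unit RMS — the 'song' waveform."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _TAG_STIMULUS, stimulus]))
    token = rng.standard_normal(n_samples)
    return token / np.sqrt(np.mean(token**2))


def _erp_template(n_samples: int, sample_rate: float) -> np.ndarray:
    """Damped oscillation spanning the stimulus window, unit RMS.

    The analysis must not depend on the exact shape; any waveform with its
    energy confined to the stimulus window would do.
    """
    t = np.arange(n_samples) / sample_rate
    dur = n_samples / sample_rate
    wave = np.sin(2 * np.pi * 20.0 * t) * np.exp(-t / (dur / 3.0))
    return wave / np.sqrt(np.mean(wave**2))


def _shuffled_events(
    rng: np.random.Generator,
    n_stimuli: int,
    n_presentations: int,
    onset: float,
    duration: float,
    trial_period: float,
) -> pd.DataFrame:
    """Event table for a shuffled presentation order.

    The presentation index counts occurrences of each stimulus in trial
    order (1-based, contiguous).
    """
    stim_seq = np.repeat(np.arange(n_stimuli), n_presentations)
    rng.shuffle(stim_seq)
    presentation = np.zeros_like(stim_seq)
    counts = np.zeros(n_stimuli, dtype=int)
    for i, s in enumerate(stim_seq):
        counts[s] += 1
        presentation[i] = counts[s]
    n = len(stim_seq)
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "stimulus": [f"stim{s:02d}" for s in stim_seq],
            "presentation": presentation,
            "onset": np.full(n, onset),
            "duration": np.full(n, duration),
            "time": np.arange(n) * trial_period + onset,
        }
    )


def generate_session(
    config: SimConfig,
    profile: LateralizationProfile,
    day: int,
    subject: str = "bird00",
) -> RecordingSession:
    """Simulate one bilateral depth-recording session.

    For presentation t (1-based) of stimulus s on channel c, the stimulus-on
    window of the trace carries an added token of RMS
    ``A * h(c) * (1 - k_c)**(t - 1)`` on top of background noise of RMS
    sigma_b, where ``h(c)`` is the profile gain g for right-hemisphere
    channels and 1 for left, and ``k_c`` is the per-channel adaptation
    decrement (0 for the configured fraction of non-adapting sites).

    Raises
    ------
    ValueError
        If ``day`` lies outside the profile span (baseline days < 0 are
        allowed and unbiased) or the config is invalid.
    """
    config.validate()
    g = profile.gain(day)  # raises with the span for invalid days

    fs = config.sample_rate
    window = config.pre_onset + config.stimulus_duration + 0.1 + config.post_offset
    n_samples = int(round(window * fs))
    i0 = int(np.floor(config.pre_onset * fs + 1e-9))
    i1 = int(np.floor((config.pre_onset + config.stimulus_duration + 0.1) * fs + 1e-9))

    rng = _session_rng(config.seed, _TAG_MUA, day)
    n_ch = 2 * config.n_channels_per_hemisphere
    hemis = np.array(["L"] * config.n_channels_per_hemisphere + ["R"] * config.n_channels_per_hemisphere)
    # electrodes advanced in 300 um steps within NCM
    depths = 1500 + 300 * (np.arange(n_ch) % 4)
    non_adapting = rng.random(n_ch) < config.non_adapting_site_fraction
    k = np.where(non_adapting, 0.0, config.adaptation_fraction)
    h = np.where(hemis == "R", g, 1.0)

    channels = pd.DataFrame(
        {
            "channel": [f"ch{i:02d}" for i in range(n_ch)],
            "hemisphere": hemis,
            "depth_um": depths.astype(float),
            "adapting": ~non_adapting,
        }
    )
    events = _shuffled_events(
        rng, config.n_stimuli, config.n_presentations,
        onset=config.pre_onset, duration=config.stimulus_duration,
        trial_period=window + config.isi,
    )

    n_trials = len(events)
    if config.baseline_noise_rms > 0:
        traces = rng.normal(0.0, config.baseline_noise_rms, (n_trials, n_ch, n_samples))
    else:
        traces = np.zeros((n_trials, n_ch, n_samples))

    tokens = {
        f"stim{s:02d}": _stimulus_token(config.seed, s, i1 - i0)
        for s in range(config.n_stimuli)
    }
    amp_base = config.evoked_amplitude * h  # (n_ch,)
    for row in events.itertuples(index=False):
        decay = (1.0 - k) ** (row.presentation - 1)
        traces[row.trial, :, i0:i1] += np.outer(amp_base * decay, tokens[row.stimulus])

    meta = {
        "subject": subject,
        "day": int(day),
        "condition": profile.condition,
        "modality": "MUA",
        "seed": int(config.seed),
        "gain_ratio": float(g),
    }
    return RecordingSession(traces, fs, channels, events, meta)


def generate_erp_session(
    config: SimConfig,
    profile: LateralizationProfile,
    day: int,
    subject: str = "bird00",
) -> RecordingSession:
    """Simulate one epidural ERP session on the 8-pin array.

    Each trial is the deterministic ERP template scaled by
    ``A * h(c) * region(c)`` plus independent Gaussian noise, where
    ``region(c)`` is ``erp_caudal_gain`` for caudal pins and 1 for rostral
    (the auditory lobule lies under the caudal pins). Default design: 3 call
    stimuli x 100 presentations.
    """
    config.validate()
    g = profile.gain(day)

    fs = config.sample_rate
    window = config.pre_onset + config.stimulus_duration + 0.1 + config.post_offset
    n_samples = int(round(window * fs))
    i0 = int(np.floor(config.pre_onset * fs + 1e-9))
    i1 = int(np.floor((config.pre_onset + config.stimulus_duration + 0.1) * fs + 1e-9))

    rng = _session_rng(config.seed, _TAG_ERP, day)
    # 2 pins per quadrant: hemisphere x caudal/rostral
    hemis = np.array(["L", "L", "L", "L", "R", "R", "R", "R"])
    positions = np.array(["caudal", "caudal", "rostral", "rostral"] * 2)
    n_ch = 8
    channels = pd.DataFrame(
        {
            "channel": [f"pin{i}" for i in range(n_ch)],
            "hemisphere": hemis,
            "position": positions,
        }
    )
    events = _shuffled_events(
        rng, config.n_stimuli, config.n_presentations,
        onset=config.pre_onset, duration=config.stimulus_duration,
        trial_period=window + config.isi,
    )

    n_trials = len(events)
    if config.baseline_noise_rms > 0:
        traces = rng.normal(0.0, config.baseline_noise_rms, (n_trials, n_ch, n_samples))
    else:
        traces = np.zeros((n_trials, n_ch, n_samples))

    template = _erp_template(i1 - i0, fs)
    h = np.where(hemis == "R", g, 1.0)
    region = np.where(positions == "caudal", config.erp_caudal_gain, 1.0)
    amp = config.evoked_amplitude * h * region
    traces[:, :, i0:i1] += np.einsum("c,s->cs", amp, template)[None, :, :]

    meta = {
        "subject": subject,
        "day": int(day),
        "condition": profile.condition,
        "modality": "ERP",
        "seed": int(config.seed),
        "gain_ratio": float(g),
    }
    return RecordingSession(traces, fs, channels, events, meta)


def generate_behavior_log(
    config: BehaviorSimConfig, n_days: int, subject: str = "bird00"
) -> pd.DataFrame:
    """Simulate a Go/NoGo operant log.

    Returns a DataFrame with columns ``subject, day, trial, type, responded,
    correct``; ``trial`` is the within-day 0-based index. P(correct) follows
    the configured learning curve per day; Go/NoGo types are exactly balanced
    within each consecutive ``block_size``-trial block (the i.i.d. 50/50 mode
    is available via ``iid_assignment``).
    """
    config.validate()
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _TAG_BEHAVIOR]))

    n_total = n_days * config.n_trials_per_day
    if config.iid_assignment:
        is_go = rng.random(n_total) < config.go_probability
    else:
        is_go = np.empty(n_total, dtype=bool)
        for start in range(0, n_total, config.block_size):
            size = min(config.block_size, n_total - start)
            n_go = int(round(size * config.go_probability))
            block = np.array([True] * n_go + [False] * (size - n_go))
            rng.shuffle(block)
            is_go[start : start + size] = block

    day = np.repeat(np.arange(n_days), config.n_trials_per_day)
    p = np.array([config.p_correct(d) for d in range(n_days)])[day]
    correct = rng.random(n_total) < p
    responded = is_go == correct  # Go: correct iff responded; NoGo: correct iff withheld

    return pd.DataFrame(
        {
            "subject": subject,
            "day": day,
            "trial": np.tile(np.arange(config.n_trials_per_day), n_days),
            "type": np.where(is_go, "Go", "NoGo"),
            "responded": responded,
            "correct": correct,
        }
    )


def amplitude_envelope(audio: np.ndarray, smoothing_points: int = 500) -> np.ndarray:
    """Smoothed positive amplitude envelope of a sound waveform.

    Local maxima of the signal are detected, interpolated onto the full
    sample grid with a cubic spline, then smoothed with a centered moving
    average of ``smoothing_points`` samples; negative spline excursions are
    clipped to zero. Output length equals input length.

    Raises
    ------
    ValueError
        If fewer than 4 local maxima are found (cubic spline
        underdetermined), or ``smoothing_points`` is out of range.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.ndim != 1 or audio.size == 0:
        raise ValueError("audio must be a non-empty 1-D array")
    peaks, _ = find_peaks(audio)
    if len(peaks) < 4:
        raise ValueError(
            f"found {len(peaks)} local maxima; at least 4 are needed for the cubic spline"
        )
    if not 1 <= smoothing_points <= len(audio):
        raise ValueError(
            f"smoothing_points must be in [1, {len(audio)}], got {smoothing_points}"
        )
    spline = CubicSpline(peaks, audio[peaks], extrapolate=True)
    env = spline(np.arange(len(audio)))
    # centered moving average with proper edge normalization
    kernel = np.ones(smoothing_points)
    smoothed = np.convolve(env, kernel, mode="same") / np.convolve(
        np.ones_like(env), kernel, mode="same"
    )
    return np.clip(smoothed, 0.0, None)
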