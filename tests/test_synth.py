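"""Generator contracts: design counts, reproducibility, hemispheric gain,
event-table consistency, the operant log, and the amplitude envelope."""

import numpy as np
import pandas as pd
import pytest

from laterotrace import (
    BehaviorSimConfig,
    LateralizationProfile,
    SimConfig,
    amplitude_envelope,
    generate_behavior_log,
    generate_erp_session,
    generate_session,
)
from laterotrace.metrics import window_slice


def evoked_rms(session, channel_idx):
    """Direct oracle: windowed RMS of the stimulus segment of each trial."""
    fs = session.sample_rate
    out = []
    for ev in session.events.itertuples(index=False):
        sl = window_slice(ev.onset, ev.onset + ev.duration + 0.1, fs)
        seg = session.traces[ev.trial, channel_idx, sl]
        out.append(np.sqrt(np.mean(seg**2)))
    return np.array(out)


class TestGenerateSession:
    def test_design_counts(self, small_config, flat_profile):
        # emulated design: 10 songs x 25 shuffled repetitions
        cfg = small_config(n_stimuli=10, n_presentations=25, n_channels_per_hemisphere=1)
        session = generate_session(cfg, flat_profile(), day=0)
        assert len(session.events) == 250
        assert session.events["stimulus"].nunique() == 10
        session.validate_events()  # onsets increasing, presentations contiguous

    def test_zero_amplitude_is_pure_noise(self, small_config, flat_profile):
        cfg = small_config(evoked_amplitude=0.0, adaptation_fraction=0.0)
        session = generate_session(cfg, flat_profile(), day=0)
        rms = np.sqrt(np.mean(session.traces**2))
        assert rms == pytest.approx(cfg.baseline_noise_rms, rel=0.01)

    def test_hemispheric_gain_ratio_noiseless(self, small_config, flat_profile):
        cfg = small_config(seed=7, baseline_noise_rms=0.0, adaptation_fraction=0.08)
        session = generate_session(cfg, flat_profile(g=1.5), day=0)
        left = evoked_rms(session, 0)
        right = evoked_rms(session, 2)  # first right-hemisphere channel
        np.testing.assert_allclose(right / left, 1.5, rtol=1e-2)

    def test_adaptation_decay_matches_law(self, small_config, flat_profile):
        k = 0.1
        cfg = small_config(baseline_noise_rms=0.0, adaptation_fraction=k,
                           n_stimuli=1, n_channels_per_hemisphere=1)
        session = generate_session(cfg, flat_profile(), day=0)
        rms = evoked_rms(session, 0)
        pres = session.events["presentation"].to_numpy()
        order = np.argsort(pres)
        expected = cfg.evoked_amplitude * (1 - k) ** (pres[order] - 1)
        np.testing.assert_allclose(rms[order], expected, rtol=1e-2)

    def test_reproducibility_bit_for_bit(self, small_config, flat_profile):
        cfg = small_config(seed=11)
        a = generate_session(cfg, flat_profile(1.2), day=3)
        b = generate_session(cfg, flat_profile(1.2), day=3)
        assert a.equals(b)
        c = generate_session(cfg, flat_profile(1.2), day=4)
        assert not np.array_equal(a.traces, c.traces)

    def test_invalid_day_names_span(self, small_config, flat_profile):
        with pytest.raises(ValueError, match=r"span \(0, 20\)"):
            generate_session(small_config(), flat_profile(), day=25)

    def test_baseline_day_is_unbiased(self, small_config, flat_profile):
        cfg = small_config(baseline_noise_rms=0.0)
        session = generate_session(cfg, flat_profile(g=2.0), day=-2)
        assert session.metadata["gain_ratio"] == 1.0

    def test_invalid_config_rejected(self, flat_profile):
        with pytest.raises(ValueError):
            SimConfig(sample_rate=-1).validate()
        with pytest.raises(ValueError):
            SimConfig(adaptation_fraction=1.5).validate()


class TestGenerateErpSession:
    def test_event_count_and_quadrants(self, small_config, flat_profile):
        # emulated design: 3 calls x 100 presentations = 300 events
        cfg = small_config(n_stimuli=3, n_presentations=100, stimulus_duration=0.25)
        session = generate_erp_session(cfg, flat_profile(), day=0)
        assert len(session.events) == 300
        assert session.traces.shape[1] == 8
        counts = session.channels.groupby(["hemisphere", "position"]).size()
        assert (counts == 2).all()

    def test_noiseless_symmetry_across_hemispheres(self, small_config, flat_profile):
        cfg = small_config(baseline_noise_rms=0.0, n_stimuli=1, n_presentations=5)
        session = generate_erp_session(cfg, flat_profile(g=1.0), day=0)
        avg = session.traces.mean(axis=0)
        np.testing.assert_array_equal(avg[0], avg[4])  # caudal L vs caudal R

    def test_caudal_exceeds_rostral(self, small_config, flat_profile):
        cfg = small_config(baseline_noise_rms=0.0, n_stimuli=1, n_presentations=3,
                           erp_caudal_gain=2.0)
        session = generate_erp_session(cfg, flat_profile(), day=0)
        caudal = np.sqrt(np.mean(session.traces[:, 0] ** 2))
        rostral = np.sqrt(np.mean(session.traces[:, 2] ** 2))
        assert caudal > rostral
        assert caudal / rostral == pytest.approx(2.0, rel=1e-6)


class TestBehaviorLog:
    def test_perfect_learner_all_correct(self):
        cfg = BehaviorSimConfig(seed=0, p_correct_initial=1.0, asymptote=1.0)
        log = generate_behavior_log(cfg, 2)
        assert log["correct"].all()

    def test_balanced_blocks(self):
        cfg = BehaviorSimConfig(seed=5)
        log = generate_behavior_log(cfg, 3)
        for start in range(0, len(log), 50):
            block = log.iloc[start : start + 50]
            assert (block["type"] == "Go").sum() == 25

    def test_response_coding_invariant(self):
        # Go: correct iff responded; NoGo: correct iff withheld
        log = generate_behavior_log(BehaviorSimConfig(seed=2), 2)
        go = log[log["type"] == "Go"]
        nogo = log[log["type"] == "NoGo"]
        assert (go["correct"] == go["responded"]).all()
        assert (nogo["correct"] == ~nogo["responded"]).all()

    def test_chance_learner_near_half(self):
        cfg = BehaviorSimConfig(seed=9, p_correct_initial=0.5, asymptote=0.5)
        log = generate_behavior_log(cfg, 21)
        assert abs(log["correct"].mean() - 0.5) < 0.03

    def test_iid_mode_not_exactly_balanced(self):
        cfg = BehaviorSimConfig(seed=1, iid_assignment=True)
        log = generate_behavior_log(cfg, 5)
        counts = [
            (log.iloc[s : s + 50]["type"] == "Go").sum() for s in range(0, len(log), 50)
        ]
        assert any(c != 25 for c in counts)


class TestAmplitudeEnvelope:
    def test_constant_sinusoid(self):
        t = np.arange(20000) / 20000
        audio = 0.7 * np.sin(2 * np.pi * 200 * t)
        env = amplitude_envelope(audio, smoothing_points=50)
        interior = env[2000:-2000]
        np.testing.assert_allclose(interior, 0.7, rtol=0.02)
        assert len(env) == len(audio)

    def test_linear_ramp(self):
        t = np.arange(40000) / 40000
        ramp = t  # amplitude 0 -> 1
        audio = ramp * np.sin(2 * np.pi * 400 * t)
        env = amplitude_envelope(audio, smoothing_points=100)
        interior = slice(4000, -4000)
        assert np.max(np.abs(env[interior] - ramp[interior])) < 0.02

    def test_nonnegative_output(self):
        rng = np.random.default_rng(0)
        env = amplitude_envelope(rng.standard_normal(5000), smoothing_points=11)
        assert (env >= 0).all()

    def test_too_few_extrema_errors(self):
        with pytest.raises(ValueError, match="local maxima"):
            amplitude_envelope(np.linspace(0, 1, 100))

    def test_idempotent_on_smooth_envelope(self):
        # a slowly varying positive envelope barely changes under re-smoothing
        t = np.arange(20000) / 20000
        audio = (1.5 + np.sin(2 * np.pi * 2 * t)) * np.sin(2 * np.pi * 300 * t)
        env = amplitude_envelope(audio, smoothing_points=50)
        # re-smooth the envelope directly (it is already smooth and positive)
        kernel = np.ones(50)
        resmoothed = np.convolve(env, kernel, "same") / np.convolve(
            np.ones_like(env), kernel, "same"
        )
        interior = slice(1000, -1000)
        np.testing.assert_allclose(resmoothed[interior], env[interior], rtol=0.02)
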