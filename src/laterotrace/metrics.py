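"""Windowed RMS response magnitudes: per-trial ARM and trial-averaged eARM.

The absolute response magnitude (ARM) of one stimulus presentation is the
RMS of the trace over the stimulus-on window (stimulus duration plus 100 ms)
minus the RMS over the 500 ms control period immediately before onset. For
epidural potentials the analogous eARM is computed *after* averaging the
first 25 presentations of a stimulus sample-wise — the order matters on
noisy data, because averaging first cancels noise that per-trial RMS would
rectify.

Window discretization is half-open on the sample grid:
``[floor(start * fs), floor(end * fs))``, so the onset sample is never
counted in both the baseline and the stimulus window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .session import BASELINE_WINDOW_S, STIMULUS_OFFSET_S, RecordingSession

_META_KEYS = ("subject", "day", "condition")


def window_slice(start_s: float, end_s: float, sample_rate: float) -> slice:
    """Half-open sample window ``[floor(start*fs), floor(end*fs))``.

    A small epsilon guards against float representation of exact products
    (e.g. ``0.7 * 10000`` evaluating just below 7000).
    """
    i0 = int(np.floor(start_s * sample_rate + 1e-9))
    i1 = int(np.floor(end_s * sample_rate + 1e-9))
    if i1 <= i0:
        raise ValueError(
            f"window [{start_s}, {end_s}) s is empty at {sample_rate} Hz"
        )
    return slice(i0, i1)


def windowed_rms(trace: np.ndarray, window: tuple[float, float], sample_rate: float) -> float:
    """Root-mean-square of ``trace`` over the half-open time window (seconds)."""
    trace = np.asarray(trace, dtype=np.float64)
    sl = window_slice(window[0], window[1], sample_rate)
    if sl.start < 0 or sl.stop > trace.shape[-1]:
        raise ValueError(
            f"window [{window[0]}, {window[1]}) s outside trace of "
            f"{trace.shape[-1] / sample_rate} s"
        )
    seg = trace[..., sl]
    return float(np.sqrt(np.mean(seg**2)))


def _meta_columns(session: RecordingSession) -> dict:
    return {k: session.metadata.get(k) for k in _META_KEYS}


def compute_arm(session: RecordingSession) -> pd.DataFrame:
    """Per-trial absolute response magnitudes for every channel and event.

    Returns one row per (channel, stimulus, presentation) with columns
    ``rms_stim`` (stimulus-on window: onset to onset + duration + 0.1 s),
    ``rms_base`` (0.5 s control period before onset) and
    ``arm = rms_stim - rms_base``, joined with channel metadata and session
    identifiers.

    Raises
    ------
    ValueError
        If any event's analysis windows fall outside the trial window (the
        offending event is named).
    """
    session.validate_events()
    fs = session.sample_rate
    rows: list[pd.DataFrame] = []
    traces = session.traces
    for ev in session.events.itertuples(index=False):
        stim_sl = window_slice(ev.onset, ev.onset + ev.duration + STIMULUS_OFFSET_S, fs)
        base_sl = window_slice(ev.onset - BASELINE_WINDOW_S, ev.onset, fs)
        seg = traces[ev.trial]  # (channels, samples)
        rms_stim = np.sqrt(np.mean(seg[:, stim_sl] ** 2, axis=1))
        rms_base = np.sqrt(np.mean(seg[:, base_sl] ** 2, axis=1))
        block = session.channels.copy()
        block["stimulus"] = ev.stimulus
        block["presentation"] = ev.presentation
        block["rms_stim"] = rms_stim
        block["rms_base"] = rms_base
        block["arm"] = rms_stim - rms_base
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    for key, val in _meta_columns(session).items():
        out[key] = val
    return out


def mean_arm_early(
    responses: pd.DataFrame, trials: tuple[int, int] = (2, 6)
) -> pd.DataFrame:
    """Mean ARM over presentations 2-6 per (channel, stimulus).

    Groups missing any presentation in the window are emitted with
    ``complete = False`` rather than silently dropped; their mean uses the
    presentations that are available.
    """
    lo, hi = trials
    wanted = set(range(lo, hi + 1))
    sub = responses[responses["presentation"].between(lo, hi)]
    keys = [c for c in ("subject", "day", "condition", "channel", "hemisphere",
                        "position", "depth_um", "stimulus") if c in responses.columns]
    grouped = sub.groupby(keys, dropna=False, sort=True)
    out = grouped.agg(
        mean_arm=("arm", "mean"),
        n_trials=("presentation", "nunique"),
    ).reset_index()
    out["complete"] = out["n_trials"] == len(wanted)
    # groups present in the input but with no presentations in the window at all
    all_groups = responses[keys].drop_duplicates()
    out = all_groups.merge(out, on=keys, how="left")
    missing = out["mean_arm"].isna()
    out.loc[missing, "n_trials"] = 0
    out.loc[missing, "complete"] = False
    out["n_trials"] = out["n_trials"].astype(int)
    out["complete"] = out["complete"].astype(bool)
    return out


def compute_earm(session: RecordingSession, max_trials: int = 25) -> pd.DataFrame:
    """ERP response magnitudes from trial-averaged waveforms.

    For each (channel, stimulus): average the first ``min(max_trials,
    available)`` presentations sample-wise, then compute
    ``earm = rms(stimulus window) - rms(baseline window)`` on the averaged
    waveform. Fewer than ``max_trials`` presentations is not an error; the
    count actually averaged is recorded in ``n_trials_averaged``.
    """
    session.validate_events()
    fs = session.sample_rate
    rows = []
    for stim, grp in session.events.groupby("stimulus", sort=True):
        grp = grp.sort_values("presentation")
        onsets = grp["onset"].unique()
        durs = grp["duration"].unique()
        if len(onsets) > 1 or len(durs) > 1:
            raise ValueError(
                f"stimulus {stim}: trial-aligned averaging requires a common "
                "onset and duration across presentations"
            )
        onset, dur = float(onsets[0]), float(durs[0])
        take = grp.head(max_trials)
        avg = session.traces[take["trial"].to_numpy()].mean(axis=0)  # (channels, samples)
        stim_sl = window_slice(onset, onset + dur + STIMULUS_OFFSET_S, fs)
        base_sl = window_slice(onset - BASELINE_WINDOW_S, onset, fs)
        rms_stim = np.sqrt(np.mean(avg[:, stim_sl] ** 2, axis=1))
        rms_base = np.sqrt(np.mean(avg[:, base_sl] ** 2, axis=1))
        block = session.channels.copy()
        block["stimulus"] = stim
        block["n_trials_averaged"] = len(take)
        block["rms_stim"] = rms_stim
        block["rms_base"] = rms_base
        block["earm"] = rms_stim - rms_base
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    for key, val in _meta_columns(session).items():
        out[key] = val
    return out
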