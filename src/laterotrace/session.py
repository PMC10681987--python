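"""Trial-aligned recording container shared by the simulator and the analysis stages.

A :class:`RecordingSession` holds everything needed to quantify auditory
responses for one subject on one day: the voltage traces (trials x channels x
samples, volts), the per-channel metadata (hemisphere, and either an epidural
pin position or a microelectrode depth), and the trial-event table.

Conventions
-----------
* Units are volts and seconds throughout; microvolts appear only in displays.
* Every trial window is stimulus-aligned: the event table's ``onset`` column
  gives the stimulus onset in seconds *within* the trial window, and ``time``
  gives the absolute onset within the session (strictly increasing).
* Presentation indices are 1-based per stimulus and contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: columns required in the channel table
CHANNEL_COLUMNS = ("channel", "hemisphere")
#: columns required in the event table
EVENT_COLUMNS = ("trial", "stimulus", "presentation", "onset", "duration", "time")

# analysis windows relative to stimulus onset (seconds)
BASELINE_WINDOW_S = 0.5    # control period before onset
STIMULUS_OFFSET_S = 0.1    # response window extends this far past stimulus offset


@dataclass
class RecordingSession:
    """One subject/day recording: traces, channel metadata and events.

    Parameters
    ----------
    traces
        Array of shape ``(n_trials, n_channels, n_samples)`` in volts.
    sample_rate
        Sampling rate in Hz.
    channels
        DataFrame with at least ``channel`` (string id) and ``hemisphere``
        (``"L"`` or ``"R"``); optionally ``position`` (``caudal``/``rostral``)
        for epidural arrays or ``depth_um`` for depth microelectrodes.
    events
        DataFrame with one row per stimulus presentation; see
        :data:`EVENT_COLUMNS`.
    metadata
        Free-form session metadata; the pipeline uses keys ``subject``,
        ``day`` (relative to exposure onset, baseline days negative),
        ``condition`` and ``modality`` (``"MUA"`` or ``"ERP"``).
    """

    traces: np.ndarray
    sample_rate: float
    channels: pd.DataFrame
    events: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if self.traces.ndim != 3:
            raise ValueError(
                f"traces must be (trials, channels, samples); got shape {self.traces.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        for col in CHANNEL_COLUMNS:
            if col not in self.channels.columns:
                raise ValueError(f"channel table missing column {col!r}")
        for col in EVENT_COLUMNS:
            if col not in self.events.columns:
                raise ValueError(f"event table missing column {col!r}")
        if len(self.channels) != self.traces.shape[1]:
            raise ValueError(
                f"channel table has {len(self.channels)} rows but traces have "
                f"{self.traces.shape[1]} channels"
            )

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def n_channels(self) -> int:
        return self.traces.shape[1]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[2]

    @property
    def trial_duration(self) -> float:
        """Length of one trial window in seconds."""
        return self.n_samples / self.sample_rate

    def validate_events(self) -> None:
        """Check that every analysis window fits inside the trial window.

        For each event, the interval ``[onset - 0.5 s, onset + duration + 0.1 s]``
        must lie inside the recorded trial; presentation indices per stimulus
        must be 1..n with no gaps; absolute onset times must strictly increase.

        Raises
        ------
        ValueError
            Naming the first offending event.
        """
        ev = self.events
        t_max = self.trial_duration
        bad = ev[(ev["onset"] - BASELINE_WINDOW_S < -1e-9)
                 | (ev["onset"] + ev["duration"] + STIMULUS_OFFSET_S > t_max + 1e-9)]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                "event window outside trial: trial "
                f"{row['trial']}, stimulus {row['stimulus']}, onset {row['onset']} s, "
                f"duration {row['duration']} s with trial window {t_max} s"
            )
        if not np.all(np.diff(ev["time"].to_numpy()) > 0):
            raise ValueError("event times are not strictly increasing")
        for stim, grp in ev.groupby("stimulus"):
            pres = np.sort(grp["presentation"].to_numpy())
            if not np.array_equal(pres, np.arange(1, len(pres) + 1)):
                raise ValueError(
                    f"presentation indices for stimulus {stim} are not contiguous from 1"
                )

    def equals(self, other: "RecordingSession") -> bool:
        """Exact equality of traces, metadata and tables (used by round-trip tests)."""
        return (
            np.array_equal(self.traces, other.traces)
            and self.sample_rate == other.sample_rate
            and self.channels.reset_index(drop=True).equals(other.channels.reset_index(drop=True))
            and self.events.reset_index(drop=True).equals(other.events.reset_index(drop=True))
            and self.metadata == other.metadata
        )
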