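"""Hemispheric aggregation, the Lateralization Index, baseline correction
and exposure-time binning.

The Lateralization Index of a session is

    LI = (R - L) / ((R + L) / 2)

where R and L are the hemisphere-averaged response magnitudes. LI is
dimensionless and bounded in [-2, 2] for non-negative magnitudes; positive
values indicate right-biased activity, negative left-biased. Although the
index is sometimes described via the "absolute difference", the sign
convention (LI < 0 = left bias) requires the signed difference, which is
what is implemented.

To compare subjects with different idiosyncratic baselines, each subject's
mean LI over its silent-baseline sessions (days < 0) is subtracted from all
of its LI values. Exposure days are then grouped into 3-day bins
(0-2, 3-5, ..., 18-20 for a 21-day exposure).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def lateralization_index(R: float, L: float) -> float:
    """Signed lateralization index ``(R - L) / ((R + L) / 2)``.

    Raises
    ------
    ValueError
        If ``R + L == 0`` (the index is undefined) or either magnitude is
        negative.
    """
    if R < 0 or L < 0:
        raise ValueError(f"magnitudes must be non-negative, got R={R}, L={L}")
    if R + L == 0:
        raise ValueError("LI undefined: R + L = 0")
    return (R - L) / ((R + L) / 2.0)


def hemisphere_average(
    values: pd.DataFrame,
    value_col: str,
    channel_selection: str = "all",
) -> tuple[float, float]:
    """Hemisphere-averaged magnitudes (R, L) from a per-channel table.

    Per-stimulus magnitudes are first averaged within each channel (equal
    stimulus weighting regardless of trial counts), then channel means are
    averaged within each hemisphere. ``channel_selection="caudal_only"``
    drops rostral channels first (the caudal pins overlie the auditory
    lobule).

    Raises
    ------
    ValueError
        If a hemisphere ends up with no channels (LI would be undefined).
    """
    if channel_selection not in ("all", "caudal_only"):
        raise ValueError(f"unknown channel_selection {channel_selection!r}")
    df = values
    if channel_selection == "caudal_only":
        if "position" not in df.columns:
            raise ValueError("caudal_only selection requires a 'position' column")
        df = df[df["position"] == "caudal"]
    per_channel = df.groupby(["hemisphere", "channel"])[value_col].mean()
    hemi = per_channel.groupby("hemisphere").mean()
    for side in ("L", "R"):
        if side not in hemi.index:
            raise ValueError(f"no channels for hemisphere {side!r}; LI undefined")
    return float(hemi["R"]), float(hemi["L"])


def session_li(
    values: pd.DataFrame,
    value_col: str,
    channel_selection: str = "all",
) -> dict:
    """One LateralizationRecord-shaped dict from a single session's table."""
    R, L = hemisphere_average(values, value_col, channel_selection)
    rec = {
        "subject": values["subject"].iloc[0] if "subject" in values else None,
        "day": int(values["day"].iloc[0]) if "day" in values else None,
        "condition": values["condition"].iloc[0] if "condition" in values else None,
        "R": R,
        "L": L,
        "li_raw": lateralization_index(R, L),
    }
    return rec


def baseline_correct(records: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject's own mean baseline LI from all its LI values.

    Baseline sessions are those with ``day < 0``; they also receive
    ``li_corrected`` (their per-subject mean is 0 by construction).

    Raises
    ------
    ValueError
        Naming any subject that has no baseline session.
    """
    out = records.copy()
    baseline_mean = (
        out[out["day"] < 0].groupby("subject")["li_raw"].mean()
    )
    missing = sorted(set(out["subject"]) - set(baseline_mean.index))
    if missing:
        raise ValueError(f"no baseline sessions (day < 0) for subjects: {missing}")
    out["li_corrected"] = out["li_raw"] - out["subject"].map(baseline_mean)
    return out


def bin_days(records: pd.DataFrame, bin_width: int = 3) -> pd.DataFrame:
    """Label each session with its exposure-time bin.

    Exposure day d >= 0 maps to the bin ``[w*floor(d/w), w*floor(d/w)+w-1]``
    labelled e.g. ``"6-8"``; baseline days (d < 0) are labelled
    ``"baseline"``. The bins partition the exposure span.
    """
    out = records.copy()
    day = out["day"].to_numpy()
    lo = bin_width * np.floor_divide(day, bin_width)
    labels = np.where(
        day < 0,
        "baseline",
        [f"{int(a)}-{int(a) + bin_width - 1}" for a in lo],
    )
    out["bin_label"] = labels
    return out


def mua_li_summary(
    arm_means: pd.DataFrame,
    value_col: str = "mean_arm",
    channel_selection: str = "all",
) -> pd.DataFrame:
    """Per subject/day/condition lateralization records from MUA ARM means.

    ``arm_means`` should contain post-filter sites only (one row per
    channel/stimulus with a mean-ARM column); hemisphere averaging and the
    LI are applied per (subject, day, condition) group, enabling the
    cross-condition summary of depth-recording lateralization.
    """
    rows = []
    for (subject, day, condition), grp in arm_means.groupby(
        ["subject", "day", "condition"], sort=True
    ):
        R, L = hemisphere_average(grp, value_col, channel_selection)
        rows.append(
            {
                "subject": subject,
                "day": int(day),
                "condition": condition,
                "R": R,
                "L": L,
                "li_raw": lateralization_index(R, L),
            }
        )
    return pd.DataFrame(rows)
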