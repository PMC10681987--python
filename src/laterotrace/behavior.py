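"""Go/NoGo operant log scoring: block performance, criterion detection and
group summaries.

Training is scored in consecutive, non-overlapping 50-trial blocks (blocks
are defined purely by trial count and may span days). A subject reaches
criterion at the first pair of consecutive full blocks both at >= 80%
correct; training is capped at 21 days. Final performance is the proportion
correct over all trials on the day criterion was reached (or on the last
training day for subjects that never reach it).
"""

from __future__ import annotations

import pandas as pd


def score_blocks(log: pd.DataFrame, block_size: int = 50) -> pd.DataFrame:
    """Partition each subject's trials into consecutive blocks and score them.

    Trials are ordered by (day, trial) within subject. Each full block
    contributes ``p_correct = n_correct / block_size``; a trailing partial
    block is emitted with ``full = False`` and must be excluded from
    criterion logic.

    Raises
    ------
    ValueError
        On duplicated (day, trial) records within a subject.
    """
    rows = []
    for subject, grp in log.groupby("subject", sort=True):
        if grp.duplicated(subset=["day", "trial"]).any():
            raise ValueError(f"duplicated (day, trial) records for subject {subject!r}")
        grp = grp.sort_values(["day", "trial"], kind="stable").reset_index(drop=True)
        for b, start in enumerate(range(0, len(grp), block_size)):
            chunk = grp.iloc[start : start + block_size]
            rows.append(
                {
                    "subject": subject,
                    "block": b,
                    "day_start": int(chunk["day"].iloc[0]),
                    "day_end": int(chunk["day"].iloc[-1]),
                    "n_trials": len(chunk),
                    "n_correct": int(chunk["correct"].sum()),
                    "p_correct": chunk["correct"].mean(),
                    "full": len(chunk) == block_size,
                }
            )
    return pd.DataFrame(rows)


def detect_criterion(
    blocks: pd.DataFrame,
    log: pd.DataFrame,
    threshold: float = 0.8,
    consecutive: int = 2,
    max_days: int = 21,
) -> pd.DataFrame:
    """Per-subject criterion attainment from scored blocks.

    A subject reaches criterion at the first run of ``consecutive`` full
    blocks all with ``p_correct >= threshold`` (within the first
    ``max_days`` training days). ``day_reached`` is the day containing the
    last trial of the qualifying run; ``final_performance`` is the
    proportion correct over all of that day's trials. Subjects that never
    qualify report ``reached = False`` and the final training day's
    performance.
    """
    rows = []
    for subject, sub_blocks in blocks.groupby("subject", sort=True):
        sub_blocks = sub_blocks.sort_values("block").reset_index(drop=True)
        sub_log = log[(log["subject"] == subject) & (log["day"] < max_days)]
        eligible = sub_blocks[(sub_blocks["full"]) & (sub_blocks["day_end"] < max_days)]
        eligible = eligible.reset_index(drop=True)
        reached = False
        day_reached: int | None = None
        ok = (eligible["p_correct"] >= threshold).to_numpy()
        for i in range(len(eligible) - consecutive + 1):
            if ok[i : i + consecutive].all():
                reached = True
                day_reached = int(eligible["day_end"].iloc[i + consecutive - 1])
                break
        perf_day = day_reached if reached else int(sub_log["day"].max())
        day_trials = sub_log[sub_log["day"] == perf_day]
        rows.append(
            {
                "subject": subject,
                "reached": reached,
                "day_reached": day_reached,
                "days_to_criterion": day_reached + 1 if reached else None,
                "final_performance": float(day_trials["correct"].mean()),
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(
    per_subject: pd.DataFrame, groups: pd.DataFrame
) -> pd.DataFrame:
    """Group-level criterion summary.

    ``groups`` maps ``subject`` to ``condition`` and ``exposure_days``.
    For each (condition, exposure_days) cell: the count of subjects
    reaching criterion, the mean days-to-criterion among reachers only,
    and the mean final performance over all subjects.
    """
    merged = per_subject.merge(groups, on="subject", how="inner", validate="1:1")
    rows = []
    for (condition, exposure), grp in merged.groupby(
        ["condition", "exposure_days"], sort=True
    ):
        reachers = grp[grp["reached"]]
        rows.append(
            {
                "condition": condition,
                "exposure_days": exposure,
                "n_total": len(grp),
                "n_reached": len(reachers),
                "mean_days_to_criterion": (
                    reachers["days_to_criterion"].astype(float).mean()
                    if len(reachers)
                    else None
                ),
                "mean_final_performance": grp["final_performance"].mean(),
            }
        )
    return pd.DataFrame(rows)
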