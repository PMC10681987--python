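"""Normalized stimulus-specific adaptation rates and the site-inclusion filter.

The adaptation rate (AdR) of one site/stimulus pair is the ordinary
least-squares slope of ARM against presentation index over presentations
6-25, divided by the mean ARM over those same presentations. The
normalization makes AdR the fractional drop in response per repetition,
independent of absolute response strength. Strongly adapting sites
(AdR < -0.05, strict) are characteristic of the higher-order auditory
region; sites failing the criterion (primary-field-like, non-adapting) are
excluded from lateralization analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_CRITERION = -0.05
DEFAULT_TRIALS = (6, 25)

_GROUP_KEYS = ("subject", "day", "condition", "channel", "hemisphere",
               "position", "depth_um", "stimulus")


def compute_adr(
    responses: pd.DataFrame,
    trials: tuple[int, int] = DEFAULT_TRIALS,
    criterion: float = DEFAULT_CRITERION,
) -> pd.DataFrame:
    """Per (channel, stimulus) adaptation rates from a long ARM table.

    For each group with the full presentation range ``trials`` (inclusive)
    available: ``slope`` is the OLS slope of arm on presentation index,
    ``mean_arm`` the mean over the same presentations, and
    ``adr = slope / mean_arm``. Groups with missing presentations, or with
    ``mean_arm <= 0`` (non-responsive site: the normalization is
    meaningless), are emitted with ``defined = False`` and never imputed.
    ``included`` is ``defined and adr < criterion`` (strict).
    """
    lo, hi = trials
    n_expected = hi - lo + 1
    keys = [c for c in _GROUP_KEYS if c in responses.columns]
    rows = []
    for group_vals, grp in responses.groupby(keys, dropna=False, sort=True):
        sub = grp[grp["presentation"].between(lo, hi)]
        rec = dict(zip(keys, group_vals if isinstance(group_vals, tuple) else (group_vals,)))
        if sub["presentation"].nunique() < n_expected:
            rec.update(slope=np.nan, mean_arm=np.nan, adr=np.nan,
                       defined=False, included=False, reason="missing_presentations")
        else:
            x = sub["presentation"].to_numpy(dtype=float)
            y = sub["arm"].to_numpy(dtype=float)
            slope = float(np.polyfit(x, y, 1)[0])
            mean_arm = float(y.mean())
            if mean_arm <= 0:
                rec.update(slope=slope, mean_arm=mean_arm, adr=np.nan,
                           defined=False, included=False, reason="nonpositive_mean_arm")
            else:
                adr = slope / mean_arm
                rec.update(slope=slope, mean_arm=mean_arm, adr=adr,
                           defined=True, included=adr < criterion, reason="")
        rows.append(rec)
    return pd.DataFrame(rows)


def filter_sites(
    results: pd.DataFrame,
    per_site_rule: str = "mean",
    criterion: float = DEFAULT_CRITERION,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Apply the adaptation criterion per recording site.

    Aggregates the defined AdR values of each channel across stimuli
    (``mean``, ``median``, or ``any`` = keep if any stimulus meets the
    criterion) and keeps the channel iff the aggregate is below
    ``criterion`` (strict). Channels with no defined AdR are excluded with
    reason ``no_defined_adr``.

    Returns
    -------
    kept, excluded, exclusion_fraction
        Per-channel tables (``excluded`` carries a ``reason`` column) and
        the fraction of channels excluded.
    """
    if per_site_rule not in ("mean", "median", "any"):
        raise ValueError(f"unknown per_site_rule {per_site_rule!r}")
    site_keys = [c for c in _GROUP_KEYS if c != "stimulus" and c in results.columns]
    kept_rows, excl_rows = [], []
    for group_vals, grp in results.groupby(site_keys, dropna=False, sort=True):
        rec = dict(zip(site_keys, group_vals if isinstance(group_vals, tuple) else (group_vals,)))
        defined = grp.loc[grp["defined"], "adr"]
        if defined.empty:
            rec.update(site_adr=np.nan, reason="no_defined_adr")
            excl_rows.append(rec)
            continue
        if per_site_rule == "mean":
            agg = float(defined.mean())
            meets = agg < criterion
        elif per_site_rule == "median":
            agg = float(defined.median())
            meets = agg < criterion
        else:  # any
            agg = float(defined.min())
            meets = bool((defined < criterion).any())
        rec["site_adr"] = agg
        if meets:
            kept_rows.append(rec)
        else:
            rec["reason"] = "adr_above_criterion"
            excl_rows.append(rec)
    kept = pd.DataFrame(kept_rows, columns=site_keys + ["site_adr"])
    excluded = pd.DataFrame(excl_rows, columns=site_keys + ["site_adr", "reason"])
    total = len(kept) + len(excluded)
    fraction = len(excluded) / total if total else 0.0
    return kept, excluded, fraction
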