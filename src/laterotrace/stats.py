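"""Statistical stage: factorial ANOVA, Bonferroni-corrected pairwise t-tests,
a repeated-measures ANCOVA, and the Kruskal-Wallis H test.

These wrap standard linear-model machinery (statsmodels OLS with Type III
sums of squares under sum-to-zero factor coding, scipy test statistics)
behind small result objects. The repeated-measures ANCOVA uses the classic
split-plot decomposition for a two-level within-unit factor (e.g. stimulus
category): between-unit effects and the covariate are tested on per-unit
means, the within factor and its interactions on per-unit differences.
All tests are deterministic given the input table; alpha defaults to 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

ALPHA = 0.05


@dataclass
class TestResult:
    """One effect's test statistic.

    ``statistic`` is F, t or H according to ``stat_name``; ``df`` is the
    numerator df (or the single df for t/H) and ``df_resid`` the denominator
    df where applicable. ``p_adjusted`` is set only for post-hoc tests.
    """

    effect: str
    stat_name: str
    statistic: float
    df: float
    df_resid: float | None
    p: float
    p_adjusted: float | None = None
    note: str = ""

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p
        return p < ALPHA

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "stat": self.stat_name,
            "statistic": self.statistic,
            "df": self.df,
            "df_resid": self.df_resid,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
            "note": self.note,
        }


def results_table(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _anova_terms(data: pd.DataFrame, response: str, rhs: str, ss_type: int) -> pd.DataFrame:
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    if model.df_resid <= 0:
        raise ValueError("design has no residual degrees of freedom")
    rank = np.linalg.matrix_rank(model.model.exog)
    if rank < model.model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design for '{rhs}': aliased terms present "
            f"(rank {rank} < {model.model.exog.shape[1]} columns)"
        )
    return sm.stats.anova_lm(model, typ=ss_type)


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    ss_type: int = 3,
) -> list[TestResult]:
    """Fixed-factor factorial ANOVA (main effects and all interactions).

    Factors are coded sum-to-zero and tested with Type III sums of squares
    by default (Type II via ``ss_type=2``), which handles unbalanced data.

    Raises
    ------
    ValueError
        If any factor has fewer than 2 levels, or the design is
        rank-deficient (aliased terms are named).
    """
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    rhs = "*".join(f"C({f}, Sum)" for f in factors)
    table = _anova_terms(data, response, rhs, ss_type)
    out = []
    df_resid = float(table.loc["Residual", "df"])
    for term, row in table.iterrows():
        if term in ("Residual", "Intercept"):
            continue
        name = term.replace("C(", "").replace(", Sum)", "")
        out.append(
            TestResult(
                effect=name,
                stat_name="F",
                statistic=float(row["F"]),
                df=float(row["df"]),
                df_resid=df_resid,
                p=float(row["PR(>F)"]),
            )
        )
    return out


def posthoc_pairwise(
    data: pd.DataFrame,
    response: str,
    group_col: str,
    level_col: str,
    pairs: list[tuple[str, str, object]],
    correction: str = "bonferroni",
) -> list[TestResult]:
    """Two-sided independent-samples t-tests between groups at given levels.

    Each pair is ``(group_a, group_b, level)``: the two groups are compared
    on the rows where ``level_col == level`` using a pooled-variance t-test.
    Bonferroni adjustment multiplies each p by the number of pairs (capped
    at 1). If both groups have zero variance and equal means the comparison
    is degenerate: t = 0, p = 1, flagged in ``note``.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    n_pairs = len(pairs)
    out = []
    for a, b, level in pairs:
        sub = data[data[level_col] == level]
        xa = sub.loc[sub[group_col] == a, response].to_numpy(dtype=float)
        xb = sub.loc[sub[group_col] == b, response].to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(
                f"pair ({a}, {b}) at {level_col}={level!r} needs >= 2 observations per group"
            )
        note = ""
        if xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean():
            t, p = 0.0, 1.0
            note = "degenerate: zero variance in both groups with equal means"
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=True)
        out.append(
            TestResult(
                effect=f"{a} vs {b} @ {level_col}={level}",
                stat_name="t",
                statistic=float(t),
                df=float(len(xa) + len(xb) - 2),
                df_resid=None,
                p=float(p),
                p_adjusted=min(1.0, float(p) * n_pairs),
                note=note,
            )
        )
    return out


def rm_ancova(
    data: pd.DataFrame,
    response: str,
    unit: str,
    within: str,
    between: list[str],
    covariate: str | None = None,
    ss_type: int = 3,
) -> list[TestResult]:
    """Repeated-measures ANCOVA with a two-level within-unit factor.

    Split-plot decomposition: units (recording sites) are the repetition
    blocks. Between-unit effects and the covariate are tested on the
    per-unit mean across the two within levels; the within main effect and
    within x between interactions are tested on the per-unit difference
    (level2 - level1). Units missing either within level are dropped and
    reported in the ``note`` of every result.

    Raises
    ------
    ValueError
        If the within factor does not have exactly 2 levels.
    """
    levels = sorted(data[within].unique())
    if len(levels) != 2:
        raise ValueError(
            f"within factor {within!r} must have exactly 2 levels, got {levels}"
        )
    wide = data.pivot_table(
        index=[unit] + between + ([covariate] if covariate else []),
        columns=within,
        values=response,
        aggfunc="mean",
    ).reset_index()
    complete = wide.dropna(subset=levels)
    n_dropped = len(wide) - len(complete)
    note = f"{n_dropped} unit(s) dropped for missing within-levels" if n_dropped else ""
    complete = complete.copy()
    complete["unit_mean"] = complete[levels].mean(axis=1)
    complete["unit_diff"] = complete[levels[1]] - complete[levels[0]]

    out: list[TestResult] = []
    between_rhs = "*".join(f"C({b}, Sum)" for b in between)

    if covariate is not None and complete[covariate].nunique() < 2:
        note = (note + "; " if note else "") + f"covariate {covariate!r} constant, dropped"
        covariate = None

    rhs_between = (f"{covariate} + " if covariate else "") + between_rhs
    table_b = _anova_terms(complete, "unit_mean", rhs_between, ss_type)
    df_resid_b = float(table_b.loc["Residual", "df"])
    for term, row in table_b.iterrows():
        if term in ("Residual", "Intercept"):
            continue
        name = term.replace("C(", "").replace(", Sum)", "")
        out.append(
            TestResult(name, "F", float(row["F"]), float(row["df"]),
                       df_resid_b, float(row["PR(>F)"]), note=note)
        )

    # within stratum: intercept of the difference model = within main effect
    if np.allclose(complete["unit_diff"], 0.0):
        # both within levels identical on every unit: all within-stratum
        # effects are exactly null (0/0 F is reported as 0 by convention)
        w_note = (note + "; " if note else "") + "degenerate: no within-unit variation"
        out.append(TestResult(within, "F", 0.0, 1.0, float(len(complete) - 1), 1.0, note=w_note))
        return out
    table_w = _anova_terms(complete, "unit_diff", between_rhs, ss_type)
    df_resid_w = float(table_w.loc["Residual", "df"])
    for term, row in table_w.iterrows():
        if term == "Residual":
            continue
        if term == "Intercept":
            name = within
        else:
            name = f"{within}:" + term.replace("C(", "").replace(", Sum)", "")
        out.append(
            TestResult(name, "F", float(row["F"]), float(row["df"]),
                       df_resid_w, float(row["PR(>F)"]), note=note)
        )
    return out


def kruskal_wallis(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p value).

    With all observations identical the statistic is defined as H = 0,
    p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == lab] for lab in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least 1 observation")
    if np.all(values == values[0]):
        return TestResult("groups", "H", 0.0, float(len(labels) - 1), None, 1.0,
                          note="all values identical")
    h, p = sps.kruskal(*samples)
    return TestResult("groups", "H", float(h), float(len(labels) - 1), None, float(p))
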