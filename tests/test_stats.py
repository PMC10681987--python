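"""Statistical stage against hand computations, closed-form balanced-design
F statistics and an independent normal-equations oracle."""

import numpy as np
import pandas as pd
import pytest

from laterotrace import factorial_anova, kruskal_wallis, posthoc_pairwise, rm_ancova


def balanced_2x2(means, n, sigma, rng):
    """Long table for a 2x2 design with given cell means."""
    rows = []
    for i, a in enumerate(("a0", "a1")):
        for j, b in enumerate(("b0", "b1")):
            for _ in range(n):
                rows.append({"A": a, "B": b, "y": means[i][j] + sigma * rng.normal()})
    return pd.DataFrame(rows)


def normal_equations_f(data, response, full_terms, reduced_terms):
    """Independent F via explicit normal equations on dummy-coded designs."""
    def design(terms):
        cols = [np.ones(len(data))]
        for t in terms:
            if ":" in t:
                f1, f2 = t.split(":")
                cols.append(
                    ((data[f1] == data[f1].unique()[1]).astype(float) - 0.5)
                    * ((data[f2] == data[f2].unique()[1]).astype(float) - 0.5)
                )
            else:
                cols.append((data[t] == data[t].unique()[1]).astype(float) - 0.5)
        return np.column_stack(cols)

    y = data[response].to_numpy(dtype=float)

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    rss_full, p_full = rss(design(full_terms))
    rss_red, p_red = rss(design(reduced_terms))
    df1 = p_full - p_red
    df2 = len(y) - p_full
    return ((rss_red - rss_full) / df1) / (rss_full / df2), df1, df2


class TestFactorialAnova:
    def test_identical_cell_means_f_zero(self):
        # every cell holds {1, 3}: identical cell means, nonzero residual
        rows = [
            {"A": a, "B": b, "y": y}
            for a in ("a0", "a1") for b in ("b0", "b1") for y in (1.0, 3.0)
        ]
        results = factorial_anova(pd.DataFrame(rows), "y", ["A", "B"])
        for r in results:
            assert r.statistic == pytest.approx(0.0, abs=1e-12)
            assert r.p == pytest.approx(1.0)

    def test_pure_main_effect_matches_closed_form(self):
        # balanced 2x2, known residual variance: F_A = n_total * delta^2 / (4 sigma_hat^2)
        rng = np.random.default_rng(1)
        delta = 2.0
        data = balanced_2x2([[0.0, 0.0], [delta, delta]], n=8, sigma=1.0, rng=rng)
        results = {r.effect: r for r in factorial_anova(data, "y", ["A", "B"])}
        # closed form from cell means on this realized sample
        cell = data.groupby(["A", "B"])["y"].mean().unstack()
        n = 8
        grand = data["y"].mean()
        a_means = data.groupby("A")["y"].mean()
        ss_a = 2 * n * ((a_means - grand) ** 2).sum()
        resid = data["y"] - data.merge(
            data.groupby(["A", "B"], as_index=False)["y"].mean(),
            on=["A", "B"], suffixes=("", "_cell"),
        )["y_cell"]
        ms_e = (resid**2).sum() / (len(data) - 4)
        assert results["A"].statistic == pytest.approx(ss_a / ms_e, rel=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        data = balanced_2x2([[0.3, -0.1], [0.5, 0.2]], n=6, sigma=1.0, rng=rng)
        results = {r.effect: r for r in factorial_anova(data, "y", ["A", "B"])}
        # balanced design: Type III F for the interaction equals the
        # model-comparison F from explicit normal equations
        f, df1, df2 = normal_equations_f(
            data, "y", ["A", "B", "A:B"], ["A", "B"]
        )
        assert results["A:B"].statistic == pytest.approx(f, rel=1e-8)
        assert results["A:B"].df == df1
        assert results["A:B"].df_resid == df2

    def test_single_level_factor_rejected(self):
        data = pd.DataFrame({"A": ["a"] * 4, "B": ["x", "y"] * 2, "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            factorial_anova(data, "y", ["A", "B"])


class TestPosthocPairwise:
    def test_identical_groups_null(self):
        data = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "lv": 0,
                             "y": [1.0, 2, 3, 1, 2, 3]})
        r = posthoc_pairwise(data, "y", "g", "lv", [("a", "b", 0)])[0]
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # {1,2,3} vs {4,5,6}: pooled sd 1, se sqrt(2/3), t = -3/se
        data = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "lv": 0,
                             "y": [1.0, 2, 3, 4, 5, 6]})
        r = posthoc_pairwise(data, "y", "g", "lv", [("a", "b", 0)])[0]
        assert r.statistic == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-9)
        assert r.df == 4

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20,
                             "lv": list(range(4)) * 10,
                             "y": rng.normal(size=40)})
        pairs = [("a", "b", lv) for lv in range(4)]
        results = posthoc_pairwise(data, "y", "g", "lv", pairs)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 4))
            assert r.p_adjusted >= r.p

    def test_degenerate_zero_variance_flagged(self):
        data = pd.DataFrame({"g": ["a"] * 2 + ["b"] * 2, "lv": 0, "y": [1.0, 1, 1, 1]})
        r = posthoc_pairwise(data, "y", "g", "lv", [("a", "b", 0)])[0]
        assert r.p == 1.0 and "degenerate" in r.note


class TestRmAncova:
    def make_data(self, rng, n_units=24, hemi_env_effect=0.0, stim_effect=0.0,
                  depth_effect=0.0):
        units = pd.DataFrame(
            {"site": np.arange(n_units),
             "env": np.repeat(["con", "het"], n_units // 2),
             "hemi": np.tile(np.repeat(["L", "R"], n_units // 4), 2),
             "depth": rng.normal(1500, 300, n_units)}
        )
        sign = ((units["env"] == "het") & (units["hemi"] == "R")).astype(float)
        base = rng.normal(0, 1, n_units) + hemi_env_effect * sign \
            + depth_effect * (units["depth"] - 1500) / 300
        frames = []
        for s, shift in (("zfstim", 0.0), ("canstim", stim_effect)):
            frames.append(units.assign(stim=s, y=base + shift + rng.normal(0, 0.5, n_units)))
        return pd.concat(frames, ignore_index=True)

    def test_null_repeated_factor_f_near_zero(self):
        rng = np.random.default_rng(3)
        data = self.make_data(rng)
        data_dup = data.copy()
        # identical values in both stimulus categories
        wide = data[data["stim"] == "zfstim"]
        data_dup = pd.concat(
            [wide, wide.assign(stim="canstim")], ignore_index=True
        )
        results = {r.effect: r for r in rm_ancova(
            data_dup, "y", "site", "stim", ["env", "hemi"], covariate="depth"
        )}
        assert results["stim"].statistic == pytest.approx(0.0, abs=1e-18)

    def test_strong_interaction_detected(self):
        rng = np.random.default_rng(4)
        data = self.make_data(rng, n_units=40, hemi_env_effect=2.5)
        results = {r.effect: r for r in rm_ancova(
            data, "y", "site", "stim", ["env", "hemi"], covariate="depth"
        )}
        assert results["env:hemi"].p < 0.01

    def test_depth_covariate_recovered(self):
        rng = np.random.default_rng(5)
        data = self.make_data(rng, n_units=60, depth_effect=2.0)
        results = {r.effect: r for r in rm_ancova(
            data, "y", "site", "stim", ["env", "hemi"], covariate="depth"
        )}
        assert results["depth"].p < 0.01

    def test_constant_covariate_dropped_with_note(self):
        rng = np.random.default_rng(6)
        data = self.make_data(rng)
        data["depth"] = 1500.0
        results = rm_ancova(data, "y", "site", "stim", ["env", "hemi"], covariate="depth")
        assert all("constant" in r.note for r in results)
        assert not any(r.effect == "depth" for r in results)

    def test_incomplete_units_dropped_and_reported(self):
        rng = np.random.default_rng(7)
        data = self.make_data(rng)
        data = data.drop(data[(data["site"] == 0) & (data["stim"] == "canstim")].index)
        results = rm_ancova(data, "y", "site", "stim", ["env", "hemi"])
        assert all("1 unit(s) dropped" in r.note for r in results)

    def test_non_two_level_within_rejected(self):
        rng = np.random.default_rng(8)
        data = self.make_data(rng)
        data.loc[data.index[:5], "stim"] = "third"
        with pytest.raises(ValueError, match="exactly 2 levels"):
            rm_ancova(data, "y", "site", "stim", ["env", "hemi"])


class TestKruskalWallis:
    def test_identical_groups_near_zero(self):
        r = kruskal_wallis([1.0, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_no_ties(self):
        # ranks 1..6, R1=6, R2=15 -> H = 12/42*(12+75) - 21 = 27/7
        r = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert r.statistic == pytest.approx(27 / 7, rel=1e-9)

    def test_all_identical_convention(self):
        r = kruskal_wallis([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])
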