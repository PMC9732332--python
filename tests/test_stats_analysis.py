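"""Presence split, Type III between ANOVA, and the mixed factorial ANOVA."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy.stats import ttest_rel

from contextmem.stats_analysis import (
    between_anova_2x2,
    presence_split,
    rm_anova_factorial,
    summarize_cells,
)


def _by_effect(results):
    return {r.effect: r for r in results}


class TestPresenceSplit:
    def test_example(self):
        split = presence_split(pd.Series([1, 2, 3, 4, 5], index=list("abcde")))
        assert split.threshold == 3.0
        assert [split.assignment[k] for k in "abcde"] == ["low"] * 3 + ["high"] * 2

    def test_all_equal_goes_low(self):
        split = presence_split(pd.Series([2.0, 2.0, 2.0]))
        assert set(split.assignment.values()) == {"low"}

    def test_two_participants(self):
        split = presence_split(pd.Series({"a": 1.0, "b": 5.0}))
        assert split.assignment == {"a": "low", "b": "high"}

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            presence_split(pd.Series([3.0]))


class TestBetweenAnova:
    def test_hand_computed_ss_on_balanced_table(self):
        """Balanced 2x2 with 2 integer values per cell against a direct
        sums-of-squares decomposition."""
        cells = {("d", "hi"): [8, 6], ("d", "lo"): [4, 2],
                 ("s", "hi"): [3, 1], ("s", "lo"): [5, 3]}
        rows = [{"g": g, "p": p, "y": y} for (g, p), ys in cells.items() for y in ys]
        df = pd.DataFrame(rows)
        res = _by_effect(between_anova_2x2(df.y, df.g, df.p))

        grand = df.y.mean()
        m = {k: np.mean(v) for k, v in cells.items()}
        mg = {g: np.mean([m[(g, "hi")], m[(g, "lo")]]) for g in ("d", "s")}
        mp = {p: np.mean([m[("d", p)], m[("s", p)]]) for p in ("hi", "lo")}
        ss_g = 4 * sum((v - grand) ** 2 for v in mg.values())
        ss_p = 4 * sum((v - grand) ** 2 for v in mp.values())
        ss_gp = 2 * sum(
            (m[(g, p)] - mg[g] - mp[p] + grand) ** 2 for g, p in m
        )
        ss_err = sum((y - m[(g, p)]) ** 2 for (g, p), ys in cells.items() for y in ys)
        assert res["group"].F == pytest.approx(ss_g / (ss_err / 4))
        assert res["presence"].F == pytest.approx(ss_p / (ss_err / 4))
        assert res["group x presence"].F == pytest.approx(ss_gp / (ss_err / 4))
        assert res["group"].partial_eta_sq == pytest.approx(ss_g / (ss_g + ss_err))

    def test_ss_additivity_balanced(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"g": np.repeat(["a", "b"], 10),
                           "p": np.tile(np.repeat(["x", "y"], 5), 2),
                           "y": rng.normal(size=20)})
        res = between_anova_2x2(df.y, df.g, df.p)
        main = [r for r in res if "within" not in r.effect]
        ss_total = ((df.y - df.y.mean()) ** 2).sum()
        assert sum(r.ss for r in main) + main[0].ss_error == pytest.approx(ss_total)

    def test_matches_pingouin_type3_unbalanced(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"g": rng.choice(["a", "b"], 37),
                           "p": rng.choice(["x", "y"], 37),
                           "y": rng.normal(size=37)})
        res = _by_effect(between_anova_2x2(df.y, df.g, df.p))
        ref = pg.anova(data=df, dv="y", between=["g", "p"], ss_type=3).set_index("Source")
        for ours, theirs in (("group", "g"), ("presence", "p"), ("group x presence", "g * p")):
            assert res[ours].F == pytest.approx(ref.loc[theirs, "F"], rel=1e-6)
            assert res[ours].p == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-6)
            assert res[ours].partial_eta_sq == pytest.approx(ref.loc[theirs, "np2"], rel=1e-6)

    def test_simple_effect_direction_and_pooled_error(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"g": np.repeat(["dual", "single"], 12),
                           "p": np.tile(np.repeat(["high", "low"], 6), 2),
                           "y": rng.normal(0, 0.1, 24)})
        df.loc[(df.g == "dual") & (df.p == "high"), "y"] += 2.0
        res = _by_effect(between_anova_2x2(df.y, df.g, df.p))
        assert res["group within presence=high"].p < 0.001
        assert res["group within presence=low"].p > 0.05
        assert res["group within presence=high"].df_den == 20

    def test_empty_cell_rejected(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"], "p": ["x", "x", "x", "y"],
                           "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            between_anova_2x2(df.y, df.g, df.p)


class TestRmAnova:
    def test_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        n = 9
        d = pd.DataFrame({"subject": np.repeat(range(n), 2),
                          "cond": ["a", "b"] * n,
                          "y": rng.normal(size=2 * n) + np.tile([0.0, 0.6], n)})
        res = _by_effect(rm_anova_factorial(d, "y", "subject", ["cond"]))
        wide = d.pivot(index="subject", columns="cond", values="y")
        t = ttest_rel(wide["a"], wide["b"])
        assert res["cond"].F == pytest.approx(t.statistic**2)
        assert res["cond"].p == pytest.approx(t.pvalue)
        assert res["cond"].df_den == n - 1

    def test_identical_within_values_give_zero_f(self):
        d = pd.DataFrame({"subject": np.repeat(range(4), 2),
                          "cond": ["a", "b"] * 4,
                          "y": np.repeat([1.0, 2.0, 3.0, 4.0], 2)})
        res = _by_effect(rm_anova_factorial(d, "y", "subject", ["cond"]))
        assert res["cond"].F == pytest.approx(0.0)

    def test_two_within_factors_match_pingouin(self):
        rng = np.random.default_rng(4)
        n = 12
        rows = []
        for s in range(n):
            base = rng.normal()
            for t in ("t4", "t5"):
                for f in ("hi", "lo"):
                    rows.append({"subject": s, "time": t, "fid": f,
                                 "y": base + rng.normal() + (0.5 if f == "hi" else 0)})
        d = pd.DataFrame(rows)
        res = _by_effect(rm_anova_factorial(d, "y", "subject", ["time", "fid"]))
        ref = pg.rm_anova(data=d, dv="y", within=["time", "fid"], subject="subject",
                          detailed=True).set_index("Source")
        for ours, theirs in (("time", "time"), ("fid", "fid"),
                             ("time x fid", "time * fid")):
            assert res[ours].F == pytest.approx(ref.loc[theirs, "F"], rel=1e-6)
            assert res[ours].p == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-6)

    def test_mixed_design_matches_pingouin(self):
        # balanced groups: every sums-of-squares convention coincides there
        rng = np.random.default_rng(5)
        n = 16
        grp = np.repeat(["g1", "g2"], n // 2)
        rows = []
        for s in range(n):
            for c in ("a", "b"):
                rows.append({"subject": s, "cond": c, "grp": grp[s],
                             "y": rng.normal() + (0.8 if (c == "b" and grp[s] == "g1") else 0)})
        d = pd.DataFrame(rows)
        res = _by_effect(rm_anova_factorial(d, "y", "subject", ["cond"], ["grp"]))
        ref = pg.mixed_anova(data=d, dv="y", within="cond", subject="subject",
                             between="grp").set_index("Source")
        assert res["grp"].F == pytest.approx(ref.loc["grp", "F"], rel=1e-6)
        assert res["cond"].F == pytest.approx(ref.loc["cond", "F"], rel=1e-6)
        assert res["cond x grp"].F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)
        assert res["cond"].partial_eta_sq == pytest.approx(ref.loc["cond", "np2"], rel=1e-6)

    def test_incomplete_subject_dropped_with_warning(self):
        d = pd.DataFrame({"subject": [0, 0, 1, 1, 2],
                          "cond": ["a", "b", "a", "b", "a"],
                          "y": [1.0, 2.0, 2.0, 4.0, 9.0]})
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova_factorial(d, "y", "subject", ["cond"])
        assert _by_effect(res)["cond"].df_den == 1

    def test_too_few_subjects_rejected(self):
        d = pd.DataFrame({"subject": [0, 0], "cond": ["a", "b"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            rm_anova_factorial(d, "y", "subject", ["cond"])


class TestSummarizeCells:
    def test_n_partitions_cohort(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"group": rng.choice(["dual", "single"], 30),
                           "presence": rng.choice(["high", "low"], 30),
                           "retention": rng.random(30)})
        out = summarize_cells(df, ["group", "presence"], ["retention"])
        assert out["n"].sum() == 30

    def test_empty_cell_flagged(self):
        df = pd.DataFrame({"group": ["dual", "dual", "single"],
                           "presence": ["high", "low", "high"],
                           "retention": [0.9, 0.8, 0.7]})
        out = summarize_cells(df, ["group", "presence"], ["retention"])
        missing = out[out["missing"]]
        assert len(missing) == 1
        assert missing.iloc[0]["group"] == "single" and missing.iloc[0]["presence"] == "low"

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            summarize_cells(pd.DataFrame(), ["g"], ["y"])
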