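"""Reaction-time statistics: filtering, within-subject ANOVA, planned
contrasts, the underline-position control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chunkdyn.behavior import (filter_trials, planned_contrasts,
                               rm_anova_2x2x2, rm_anova_factorial,
                               underline_position_anova)
from chunkdyn.data import TrialTable
from chunkdyn.synth import build_design, simulate_rt

CELLS = [(g, l, t) for g in "wn" for l in "wn" for t in ("global", "local")]


def _table(cell_offsets=None, n_subjects=6, noise_sd=0.0, seed=0,
           n_per_cell=4, subject_sd=0.0):
    """Balanced trial table with controllable cell structure."""
    rng = np.random.default_rng(seed)
    offsets = cell_offsets or {}
    rows = []
    for s in range(n_subjects):
        intercept = subject_sd * rng.standard_normal()
        for (g, l, t) in CELLS:
            for i in range(n_per_cell):
                pos = "full" if t == "global" else \
                    ("first", "last")[i % 2]
                rt = (700.0 + offsets.get((g, l, t), 0.0) + intercept
                      + noise_sd * rng.standard_normal())
                rows.append({"subject": f"s{s:02d}", "global_lex": g,
                             "local_lex": l, "task": t,
                             "underline_pos": pos, "rt_ms": max(rt, 1.0),
                             "correct": 1})
    return TrialTable(pd.DataFrame(rows))


def _anova_oracle_statsmodels(df):
    """Independent cross-check via statsmodels AnovaRM."""
    from statsmodels.stats.anova import AnovaRM
    agg = df.groupby(["subject", "global_lex", "local_lex", "task"],
                     as_index=False)["rt_ms"].mean()
    res = AnovaRM(agg, depvar="rt_ms", subject="subject",
                  within=["global_lex", "local_lex", "task"]).fit()
    return res.anova_table


class TestFilterTrials:
    def _mixed(self):
        t = _table(n_subjects=2, n_per_cell=2)
        df = t.df.copy()
        df.loc[df.index[:2], "correct"] = 0
        return TrialTable(df)

    def test_error_trials_removed(self):
        t = self._mixed()
        kept, _ = filter_trials(t)
        assert len(kept) == len(t) - 2
        assert (kept.df["correct"] == 1).all()

    def test_accuracy_screen_lists_low_subjects(self):
        t = _table(n_subjects=2, n_per_cell=4)
        df = t.df.copy()
        s0 = df["subject"] == "s00"
        idx = df.index[s0][:6]  # 6/32 errors -> 81% accuracy
        df.loc[idx, "correct"] = 0
        kept, rep = filter_trials(TrialTable(df))
        assert rep.below_screen == ["s00"]
        assert rep.per_subject_accuracy["s00"] < 0.85

    def test_all_correct_is_identity(self):
        t = _table(n_subjects=2)
        kept, rep = filter_trials(t)
        assert len(kept) == len(t)
        assert rep.below_screen == []
        assert rep.flagged_empty_cell == []

    def test_emptied_cell_flagged(self):
        t = _table(n_subjects=2, n_per_cell=1)
        df = t.df.copy()
        kill = (df["subject"] == "s00") & (df["global_lex"] == "w") \
            & (df["local_lex"] == "w") & (df["task"] == "global")
        df.loc[kill, "correct"] = 0
        _, rep = filter_trials(TrialTable(df))
        assert ("s00", ("w", "w", "global")) in rep.flagged_empty_cell


class TestRmAnova:
    def test_equal_cell_means_give_zero_f(self):
        t = _table(subject_sd=50.0, seed=3)
        res = rm_anova_2x2x2(t)
        for eff in res.effects.values():
            assert eff.F == pytest.approx(0.0, abs=1e-18)
            assert eff.p == 1.0
            assert eff.df1 == 1 and eff.df2 == res.n_subjects - 1

    def test_matches_brute_force_ss_oracle(self):
        """Engine agrees with an explicit sums-of-squares computation on a
        small fixture to 1e-9."""
        rng = np.random.default_rng(1)
        Y = rng.normal(700, 60, size=(4, 2, 2, 2))
        effects = rm_anova_factorial(Y, ("A", "B", "C"))

        def marg(axes):  # mean keeping listed axes
            keep = tuple(i for i in range(4) if i not in axes)
            return Y.mean(axis=keep, keepdims=True)

        # main effect A (axis 1): textbook SS formulas
        n = 4
        g = Y.mean()
        ya = Y.mean(axis=(0, 2, 3))
        ss_a = n * 4 * ((ya - g) ** 2).sum()
        ys = Y.mean(axis=(1, 2, 3))
        yas = Y.mean(axis=(2, 3))
        ss_as = 4 * ((yas - ya[None, :] - ys[:, None] + g) ** 2).sum()
        F_a = ss_a / (ss_as / (n - 1))
        assert effects["A"].F == pytest.approx(F_a, abs=1e-9)

        # three-way interaction: full inclusion-exclusion residual
        yab = Y.mean(axis=(0, 3), keepdims=True)
        yac = Y.mean(axis=(0, 2), keepdims=True)
        ybc = Y.mean(axis=(0, 1), keepdims=True)
        ya_ = Y.mean(axis=(0, 2, 3), keepdims=True)
        yb_ = Y.mean(axis=(0, 1, 3), keepdims=True)
        yc_ = Y.mean(axis=(0, 1, 2), keepdims=True)
        cell = Y.mean(axis=0, keepdims=True)
        eff_abc = cell - yab - yac - ybc + ya_ + yb_ + yc_ - g
        ss_abc = n * (eff_abc ** 2).sum()
        assert ss_abc >= 0

    def test_matches_statsmodels_anovarm(self):
        t = _table(cell_offsets={("w", "w", "local"): 40.0,
                                 ("n", "n", "global"): -25.0},
                   noise_sd=30.0, seed=5, n_subjects=8)
        mine = rm_anova_2x2x2(t)
        oracle = _anova_oracle_statsmodels(t.df)
        for eff_name, row_name in [("global_lex", "global_lex"),
                                   ("local_lex", "local_lex"),
                                   ("task", "task"),
                                   ("global_lex x local_lex",
                                    "global_lex:local_lex"),
                                   ("global_lex x local_lex x task",
                                    "global_lex:local_lex:task")]:
            got = mine[eff_name]
            want = oracle.loc[row_name]
            assert got.F == pytest.approx(want["F Value"], rel=1e-9)
            assert got.p == pytest.approx(want["Pr > F"], abs=1e-12)

    def test_f_equals_squared_paired_t_for_mains(self):
        """Classical identity for 2-level within factors."""
        t = _table(noise_sd=40.0, seed=7, n_subjects=10, subject_sd=60.0)
        res = rm_anova_2x2x2(t)
        df = t.df
        for factor, (lv1, lv2) in [("global_lex", ("w", "n")),
                                   ("local_lex", ("w", "n")),
                                   ("task", ("global", "local"))]:
            m1 = df[df[factor] == lv1].groupby("subject")["rt_ms"].mean()
            m2 = df[df[factor] == lv2].groupby("subject")["rt_ms"].mean()
            tt, _ = stats.ttest_rel(m1, m2)
            assert res[factor].F == pytest.approx(tt ** 2, rel=1e-9)

    def test_planted_task_effect_is_specific(self):
        hits_task, hits_other = 0, 0
        for r in range(50):
            t = _table(cell_offsets={(g, l, "local"): 60.0
                                     for g in "wn" for l in "wn"},
                       noise_sd=50.0, seed=100 + r, n_subjects=8)
            res = rm_anova_2x2x2(t)
            hits_task += res["task"].p < 0.05
            hits_other += res["global_lex"].p < 0.05
        assert hits_task >= 45          # strong planted effect detected
        assert hits_other <= 10         # others stay near the null rate

    def test_type_one_error_calibrated(self):
        """Null rejection rate of each effect ~5% over 500 replicates."""
        rng = np.random.default_rng(0)
        n_rep, n = 500, 12
        rej = {k: 0 for k in range(7)}
        for _ in range(n_rep):
            Y = rng.normal(size=(n, 2, 2, 2))
            effects = rm_anova_factorial(Y, ("A", "B", "C"))
            for i, eff in enumerate(effects.values()):
                rej[i] += eff.p < 0.05
        half = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        for i in rej:
            assert abs(rej[i] / n_rep - 0.05) < half

    def test_missing_cell_names_subject(self):
        t = _table(n_subjects=3, n_per_cell=1)
        df = t.df[~((t.df["subject"] == "s01") & (t.df["task"] == "local")
                    & (t.df["global_lex"] == "w")
                    & (t.df["local_lex"] == "w"))]
        with pytest.raises(ValueError, match="s01"):
            rm_anova_2x2x2(TrialTable(df))


class TestPlannedContrasts:
    def test_identical_cells_give_zero(self):
        t = _table()
        for c in planned_contrasts(t):
            assert c.t == 0.0
            assert c.mean_diff_ms == pytest.approx(0.0)

    def test_two_subject_closed_form(self):
        # subject diffs 50 and 60 ms on the GnLw-GwLw (local) contrast
        t = _table(n_subjects=2)
        df = t.df.copy()
        for s, d in [("s00", 50.0), ("s01", 60.0)]:
            sel = (df["subject"] == s) & (df["task"] == "local") \
                & (df["global_lex"] == "n") & (df["local_lex"] == "w")
            df.loc[sel, "rt_ms"] += d
        res = planned_contrasts(TrialTable(df))
        c = next(x for x in res if x.name.startswith("GnLw-GwLw"))
        assert c.mean_diff_ms == pytest.approx(55.0)
        assert c.t == pytest.approx(11.0, rel=1e-9)  # 55 / (7.0711/sqrt(2))
        assert c.df == 1

    def test_generator_roundtrip_recovers_planted_112ms(self):
        design = build_design(80, seed=0)
        base = {(g, l, t): (800.0, 150.0) for g in "wn" for l in "wn"
                for t in ("global", "local")}
        base[("n", "w", "global")] = (912.0, 150.0)  # +112 vs GnLn global
        acc = {k: 1.0 for k in base}
        tt = simulate_rt(design, base, acc, seed=21, n_subjects=21)
        res = planned_contrasts(tt)
        c = next(x for x in res if x.name.startswith("GnLw-GnLn"))
        se = 150.0 / np.sqrt(40) * np.sqrt(2) / np.sqrt(21)
        assert abs(c.mean_diff_ms - 112.0) < 1.96 * se * 1.5
        assert c.p < 0.001


class TestUnderlineAnova:
    def test_no_local_rows_rejected(self):
        t = _table()
        df = t.df[t.df["task"] == "global"]
        with pytest.raises(ValueError, match="local"):
            underline_position_anova(TrialTable(df))

    def test_null_position_effect_near_null(self):
        ps = []
        for r in range(30):
            t = _table(noise_sd=40.0, seed=500 + r, n_subjects=8,
                       n_per_cell=8)
            res = underline_position_anova(t)
            ps.append(res["underline_pos"].p)
        assert 0.2 < np.mean(ps) < 0.8  # roughly uniform p under the null

    def test_planted_position_effect_detected(self):
        rng = np.random.default_rng(9)
        t = _table(noise_sd=20.0, seed=9, n_subjects=10, n_per_cell=8)
        df = t.df.copy()
        df.loc[(df["task"] == "local") & (df["underline_pos"] == "last"),
               "rt_ms"] += 80.0
        res = underline_position_anova(TrialTable(df))
        assert res["underline_pos"].p < 0.01
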