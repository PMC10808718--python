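import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from faceloop.inference import test_habituation as habituation_ttests
from faceloop.inference import (
    BalancedMixedLM,
    compare_connectivity,
    fit_condition_lmm,
    fit_psychometric_lmm,
    holm_adjust,
    two_sample_t_from_summary,
)


def make_run_data(rng, n_per_group=16, n_runs=4, sigma_e=0.6, sigma_u=0.5,
                  effect=None):
    """Balanced two-group repeated-measures data; ``effect[(group, run)]``
    adds a fixed shift."""
    rows = []
    for gname in ("congruent", "incongruent"):
        for i in range(n_per_group):
            sid = f"{gname[:3]}{i:02d}"
            u = rng.normal(0, sigma_u)
            for r in range(1, n_runs + 1):
                mu = (effect or {}).get((gname, r), 0.0)
                rows.append(
                    {"participant_id": sid, "congruency": gname, "run": r,
                     "beta": u + mu + rng.normal(0, sigma_e)}
                )
    return pd.DataFrame(rows)


class TestBalancedMixedLM:
    def test_exact_recovery_under_zero_noise(self, rng):
        effect = {("congruent", 3): -0.4, ("congruent", 4): -0.7}
        df = make_run_data(rng, n_per_group=4, sigma_e=0.0, sigma_u=0.0, effect=effect)
        res = BalancedMixedLM(
            df, "beta", "participant_id", "run", "congruency",
            within_ref=1, group_ref="congruent",
        ).fit()
        fe = res.fixed_effects.set_index("term")["estimate"]
        assert fe["run[3]"] == pytest.approx(-0.4, abs=1e-6)
        assert fe["run[4]"] == pytest.approx(-0.7, abs=1e-6)
        assert fe["run[3]:congruency[incongruent]"] == pytest.approx(0.4, abs=1e-6)

    def test_satterthwaite_df_closed_form_balanced(self, rng):
        df = make_run_data(rng)
        res = BalancedMixedLM(
            df, "beta", "participant_id", "run", "congruency",
            within_ref=1, group_ref="congruent",
        ).fit()
        fe = res.fixed_effects.set_index("term")
        # within-stratum df = (32 subjects)(4-1 runs) - 6 = 90
        assert fe.loc["run[2]", "df"] == 90
        assert fe.loc["run[4]:congruency[incongruent]", "df"] == 90
        an = res.anova.set_index("effect")
        assert an.loc["run", "df_den"] == 90
        assert an.loc["congruency", "df_den"] == 30

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        df = make_run_data(rng, effect={("congruent", 4): -0.5})
        res = BalancedMixedLM(
            df, "beta", "participant_id", "run", "congruency",
            within_ref=1, group_ref="congruent",
        ).fit()
        m = smf.mixedlm(
            "beta ~ C(run, Treatment(1)) * C(congruency, Treatment('congruent'))",
            df, groups=df["participant_id"],
        ).fit(reml=True)
        fe = res.fixed_effects.set_index("term")
        assert fe.loc["run[4]", "estimate"] == pytest.approx(
            m.params["C(run, Treatment(1))[T.4]"], abs=1e-6
        )
        assert fe.loc["run[4]", "se"] == pytest.approx(
            m.bse["C(run, Treatment(1))[T.4]"], rel=1e-4
        )
        assert fe.loc["(Intercept)", "estimate"] == pytest.approx(
            m.params["Intercept"], abs=1e-6
        )

    def test_matches_lmertest_satterthwaite(self, rng, tmp_path):
        """Estimates, SEs, df and type-III F values should reproduce
        lme4/lmerTest (REML, Satterthwaite) on balanced data."""
        df = make_run_data(rng, effect={("incongruent", 3): 0.5})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages({{library(lme4); library(lmerTest)}})
            d <- read.csv("{csv}")
            d$run <- factor(d$run)
            d$congruency <- relevel(factor(d$congruency), "congruent")
            m <- lmer(beta ~ run*congruency + (1|participant_id), data=d, REML=TRUE)
            co <- coef(summary(m))
            a <- anova(m, type=3)
            cat(co["run3","Estimate"], co["run3","Std. Error"], co["run3","df"],
                co["congruencyincongruent","Std. Error"],
                co["congruencyincongruent","df"],
                a["run","F value"], a["run:congruency","F value"], sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_run3, r_se3, r_df3, r_seg, r_dfg, r_Frun, r_Fint = map(
            float, out.stdout.split()
        )
        res = BalancedMixedLM(
            df, "beta", "participant_id", "run", "congruency",
            within_ref=1, group_ref="congruent",
        ).fit()
        fe = res.fixed_effects.set_index("term")
        an = res.anova.set_index("effect")
        assert fe.loc["run[3]", "estimate"] == pytest.approx(r_run3, abs=1e-6)
        assert fe.loc["run[3]", "se"] == pytest.approx(r_se3, abs=1e-6)
        assert fe.loc["run[3]", "df"] == pytest.approx(r_df3, abs=1e-3)
        assert fe.loc["congruency[incongruent]", "se"] == pytest.approx(r_seg, abs=1e-6)
        assert fe.loc["congruency[incongruent]", "df"] == pytest.approx(r_dfg, abs=0.01)
        assert an.loc["run", "F"] == pytest.approx(r_Frun, abs=1e-5)
        assert an.loc["run:congruency", "F"] == pytest.approx(r_Fint, abs=1e-5)

    def test_unbalanced_falls_back_with_warning(self, rng):
        df = make_run_data(rng, n_per_group=6).iloc[:-2]  # drop 2 rows
        model = BalancedMixedLM(
            df, "beta", "participant_id", "run", "congruency",
            within_ref=1, group_ref="congruent",
        )
        with pytest.warns(UserWarning, match="unbalanced"):
            res = model.fit()
        assert "mixedlm" in res.method

    def test_too_few_levels_rejected(self, rng):
        df = make_run_data(rng, n_per_group=2)
        with pytest.raises(ValueError):
            BalancedMixedLM(
                df[df.run == 1], "beta", "participant_id", "run", "congruency"
            )


class TestConditionLmm:
    def test_runs_on_block_beta_table(self, small_cohort):
        from faceloop.glm import block_beta_table

        betas = block_beta_table(small_cohort)
        res = fit_condition_lmm(betas, "fear")
        assert set(res.anova["effect"]) == {"run", "congruency", "run:congruency"}
        assert (res.fixed_effects["se"].dropna() > 0).all()

    def test_unknown_condition_rejected(self, small_cohort):
        from faceloop.glm import block_beta_table

        with pytest.raises(ValueError):
            fit_condition_lmm(block_beta_table(small_cohort), "angry")


class TestHabituationTests:
    def test_zero_slopes_give_null_result(self):
        df = pd.DataFrame(
            {"participant_id": [f"s{i}" for i in range(16)],
             "group": "fear-down", "run": 1, "slope": 0.0}
        )
        res = habituation_ttests(df)
        assert res.loc[0, "t"] == 0.0 and res.loc[0, "p"] == 1.0
        assert res.loc[0, "df"] == 15

    def test_constant_nonzero_slopes_flagged_degenerate(self):
        df = pd.DataFrame(
            {"participant_id": [f"s{i}" for i in range(16)],
             "group": "fear-down", "run": 4, "slope": -0.5}
        )
        res = habituation_ttests(df)
        assert bool(res.loc[0, "degenerate"])
        assert np.isnan(res.loc[0, "t"])

    def test_t_statistic_magnitude_regime(self, rng):
        """Slopes drawn as -0.8 + N(0, 0.85) at n=16 give a mean t near the
        analytic -0.8/(0.85/4) = -3.76 over replicates."""
        ts = []
        for _ in range(1000):
            df = pd.DataFrame(
                {"participant_id": [f"s{i}" for i in range(16)],
                 "group": "g", "run": 4,
                 "slope": -0.8 + rng.normal(0, 0.85, 16)}
            )
            ts.append(habituation_ttests(df).loc[0, "t"])
        assert np.mean(ts) == pytest.approx(-3.76, abs=0.4)

    def test_single_slope_rejected(self):
        df = pd.DataFrame(
            {"participant_id": ["s0"], "group": "g", "run": 1, "slope": [0.1]}
        )
        with pytest.raises(ValueError):
            habituation_ttests(df)


class TestPsychometricLmm:
    @staticmethod
    def scores_frame(shift, noise, rng, n=8):
        rows = []
        for gname, cong in (("happy-up", True), ("happy-down", False)):
            for i in range(n):
                pid = f"{gname}{i}"
                pre = 30 + rng.normal(0, 3)
                for time, val in (("pre", pre), ("post", pre + shift + rng.normal(0, noise))):
                    rows.append(
                        {"participant_id": pid, "group": gname, "congruent": cong,
                         "scale": "panas_pos", "time": time, "score": val}
                    )
        return pd.DataFrame(rows)

    def test_identical_pre_post_zero_time_effect(self, rng):
        df = self.scores_frame(0.0, 0.0, rng)
        res = fit_psychometric_lmm(df, "happy", "panas_pos")
        fe = res.fixed_effects.set_index("term")
        assert fe.loc["time[post]", "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_uniform_shift_recovered_exactly(self, rng):
        df = self.scores_frame(5.0, 0.0, rng)
        res = fit_psychometric_lmm(df, "happy", "panas_pos")
        fe = res.fixed_effects.set_index("term")
        assert fe.loc["time[post]", "estimate"] == pytest.approx(5.0, abs=1e-6)

    def test_missing_timepoint_dropped_with_warning(self, rng):
        df = self.scores_frame(1.0, 1.0, rng).iloc[:-1]
        with pytest.warns(UserWarning, match="missing a timepoint"):
            fit_psychometric_lmm(df, "happy", "panas_pos")

    def test_interaction_type_one_error_calibrated(self, rng):
        """Under the null, the time x group test should reject at ~alpha."""
        n_rep, alpha = 400, 0.05
        rejections = 0
        for _ in range(n_rep):
            df = self.scores_frame(0.0, 2.0, rng)
            res = fit_psychometric_lmm(df, "happy", "panas_pos")
            an = res.anova.set_index("effect")
            rejections += an.loc["time:congruency", "p"] < alpha
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09


class TestConnectivityComparisons:
    @staticmethod
    def conn_frame(rng, vals_by_group_run):
        rows = []
        for (g, r), vals in vals_by_group_run.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"participant_id": f"{g}{i:02d}", "group": g, "run": r,
                     "value": float(v)}
                )
        return pd.DataFrame(rows)

    def test_identical_runs_give_zero_paired_t(self, rng):
        v = rng.normal(0.5, 0.1, 16)
        df = self.conn_frame(rng, {("happy-up", 1): v, ("happy-up", 4): v})
        res = compare_connectivity(df)
        paired = res[res.kind == "paired"].iloc[0]
        assert paired["t"] == 0.0 and paired["df"] == 15

    def test_summary_statistic_oracle_regime(self):
        """Group summaries 0.83 +/- 0.21 vs 0.19 +/- 0.23 at n=16 give a
        two-sample t within 20% of 8.30 (printed-group-difference regime)."""
        t, df = two_sample_t_from_summary(0.83, 0.21, 16, 0.19, 0.23, 16)
        assert abs(t) == pytest.approx(8.30, rel=0.20)
        assert 25 <= df <= 30

    def test_df_bookkeeping_tiny_groups(self, rng):
        df = self.conn_frame(
            rng,
            {("a", 1): [0.1, 0.2], ("a", 4): [0.3, 0.1],
             ("b", 1): [0.0, 0.4], ("b", 4): [0.2, 0.5]},
        )
        res = compare_connectivity(df)
        assert (res[res.kind == "paired"]["df"] == 1).all()
        assert (res[res.kind == "paired-style"]["df"] == 1).all()

    def test_unbalanced_pairs_rejected(self, rng):
        df = self.conn_frame(rng, {("a", 1): [0.1, 0.2], ("a", 4): [0.3]})
        with pytest.raises(ValueError, match="unbalanced"):
            compare_connectivity(df)


def test_holm_adjustment_monotone():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = holm_adjust(p)
    assert np.all(adj >= p)
    assert adj.max() <= 1.0
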