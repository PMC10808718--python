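"""Group-level inference: mixed models, habituation tests, comparisons.

The central model is a linear mixed model with a random intercept per
participant and categorical fixed effects (a within-participant factor such
as run or time, a between-participant group factor, and their interaction),
fitted by REML. For the balanced designs this package simulates, REML has a
closed form through the classical between/within stratum decomposition:

* within stratum — participant-demeaned data; estimates and tests of the
  within factor and the interaction, error df = n_subj*(r-1) - p_within;
* between stratum — participant means; estimates and tests of the group
  effect, error df = n_subj - n_groups.

On balanced data these stratum df are exactly what the Satterthwaite
approximation returns (e.g. 2 groups x 16 participants x 4 runs gives
t(90) for run contrasts and t(30) for the group contrast). Unbalanced data
fall back to ``statsmodels`` MixedLM with residual df, flagged in the
result's ``method`` tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MixedLMResultsLite:
    """Fixed-effect table, variance components and omnibus F tests."""

    fixed_effects: pd.DataFrame  # term, estimate, se, df, t, p
    anova: pd.DataFrame          # effect, F, df_num, df_den, p
    var_subject: float
    var_residual: float
    method: str

    def summary(self) -> str:
        lines = [
            f"Linear mixed model ({self.method})",
            f"variance components: subject {self.var_subject:.4f}, "
            f"residual {self.var_residual:.4f}",
            "",
            self.fixed_effects.to_string(
                index=False, float_format=lambda v: f"{v:8.4f}"
            ),
            "",
            self.anova.to_string(index=False, float_format=lambda v: f"{v:8.4f}"),
        ]
        return "\n".join(lines)


class BalancedMixedLM:
    """Random-intercept LMM for a two-group, r-level repeated design.

    Parameters
    ----------
    data : DataFrame
        Long format with one row per participant x within level.
    outcome, subject, within, group : str
        Column names. ``within`` and ``group`` are treated as categorical
        with treatment coding.
    within_ref, group_ref :
        Reference levels (default: the first sorted level).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        subject: str,
        within: str,
        group: str,
        within_ref=None,
        group_ref=None,
    ):
        self.data = data.copy()
        self.outcome, self.subject = outcome, subject
        self.within, self.group = within, group
        self.within_levels = sorted(data[within].unique())
        self.group_levels = sorted(data[group].unique())
        if within_ref is not None:
            self.within_levels.insert(
                0, self.within_levels.pop(self.within_levels.index(within_ref))
            )
        if group_ref is not None:
            self.group_levels.insert(
                0, self.group_levels.pop(self.group_levels.index(group_ref))
            )
        if len(self.within_levels) < 2:
            raise ValueError("need at least 2 within-factor levels")
        if data[subject].nunique() < 2:
            raise ValueError("need at least 2 participants")

    # -------------------------------------------------------------- balance
    def _is_balanced(self) -> bool:
        counts = self.data.groupby([self.subject, self.within]).size()
        if (counts != 1).any():
            return False
        per_subj = self.data.groupby(self.subject)[self.within].nunique()
        return (per_subj == len(self.within_levels)).all()

    # ------------------------------------------------------------------ fit
    def fit(self) -> MixedLMResultsLite:
        if self._is_balanced():
            return self._fit_balanced()
        warnings.warn(
            "unbalanced design: delegating to statsmodels MixedLM "
            "with residual-df inference", stacklevel=2
        )
        return self._fit_mixedlm()

    def _design(self, df: pd.DataFrame):
        """Treatment-coded design columns and term labels."""
        w, g = self.within, self.group
        terms, cols = ["(Intercept)"], [np.ones(len(df))]
        for lev in self.within_levels[1:]:
            terms.append(f"{w}[{lev}]")
            cols.append((df[w] == lev).to_numpy(float))
        for lev in self.group_levels[1:]:
            terms.append(f"{g}[{lev}]")
            cols.append((df[g] == lev).to_numpy(float))
        for wl in self.within_levels[1:]:
            for gl in self.group_levels[1:]:
                terms.append(f"{w}[{wl}]:{g}[{gl}]")
                cols.append(
                    ((df[w] == wl) & (df[g] == gl)).to_numpy(float)
                )
        return np.column_stack(cols), terms

    def _fit_balanced(self) -> MixedLMResultsLite:
        df = self.data.sort_values([self.subject, self.within])
        y = df[self.outcome].to_numpy(float)
        X, terms = self._design(df)
        n_subj = df[self.subject].nunique()
        r = len(self.within_levels)
        g = len(self.group_levels)

        subj_codes, _ = pd.factorize(df[self.subject])
        # ---- within stratum: participant-demeaned data
        def demean(M):
            M = np.atleast_2d(M.T).T
            means = np.zeros_like(M)
            for j in range(M.shape[1]):
                mean_per = np.bincount(subj_codes, M[:, j]) / np.bincount(subj_codes)
                means[:, j] = mean_per[subj_codes]
            return M - means

        is_within = [
            i for i, t in enumerate(terms)
            if (self.within in t and "(Intercept)" not in t)
        ]
        is_between = [i for i in range(len(terms)) if i not in is_within]

        Xw = demean(X[:, is_within])
        yw = demean(y[:, None])[:, 0]
        beta_w, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss_w = float(np.sum((yw - Xw @ beta_w) ** 2))
        df_within = n_subj * (r - 1) - len(is_within)
        sigma_e2 = rss_w / df_within if df_within > 0 else np.nan
        cov_w = sigma_e2 * np.linalg.inv(Xw.T @ Xw)

        # ---- between stratum: participant means on the between design
        subj_mean_y = np.bincount(subj_codes, y) / np.bincount(subj_codes)
        # between design: intercept + group dummies (the subject means of the
        # within columns are constants/multiples of these and fold into them)
        first_row = np.full(n_subj, -1)
        for row_i, s in enumerate(subj_codes):
            if first_row[s] < 0:
                first_row[s] = row_i
        Xb = X[np.ix_(first_row, is_between)]  # constant per subject
        gamma, *_ = np.linalg.lstsq(Xb, subj_mean_y, rcond=None)
        rss_b = float(np.sum((subj_mean_y - Xb @ gamma) ** 2))
        df_between = n_subj - g
        # estimates sigma_a^2 + sigma_e^2 / r; undefined with one
        # participant per group
        ms_b = rss_b / df_between if df_between > 0 else np.nan
        sigma_a2 = max(0.0, ms_b - sigma_e2 / r)
        cov_gamma = ms_b * np.linalg.inv(Xb.T @ Xb)

        # recover the treatment-coded between coefficients: the subject mean
        # absorbs 1/r of every within effect, so
        #   gamma_0 = b0 + (1/r) sum_k run_k
        #   gamma_j = g_j + (1/r) sum_k int_{k,j}
        w_names = [terms[c] for c in is_within]
        main_w = [j for j, t in enumerate(w_names) if ":" not in t]
        inter_by_group = {
            gl: [j for j, t in enumerate(w_names) if f":{self.group}[{gl}]" in t]
            for gl in self.group_levels[1:]
        }
        beta_b = np.empty(len(is_between))
        var_b = np.empty(len(is_between))
        df_b = np.empty(len(is_between))
        for jj, col in enumerate(is_between):
            name = terms[col]
            if name == "(Intercept)":
                corr_idx = main_w
            else:
                gl = name[name.index("[") + 1 : name.index("]")]
                corr_idx = inter_by_group.get(gl, [])
            c = np.zeros(len(is_within))
            c[corr_idx] = 1.0 / r
            v_between = cov_gamma[jj, jj]
            v_within = float(c @ cov_w @ c)
            beta_b[jj] = gamma[jj] - float(c @ beta_w)
            var_b[jj] = v_between + v_within
            # Satterthwaite combination of the two independent strata
            denom = v_between**2 / df_between + (
                v_within**2 / df_within if v_within > 0 else 0.0
            )
            df_b[jj] = var_b[jj] ** 2 / denom if denom > 0 else df_between

        # ---- assemble the fixed-effect table
        rows = []
        for jj, col in enumerate(is_within):
            est, se = beta_w[jj], np.sqrt(cov_w[jj, jj])
            t = est / se if se > 0 else np.nan
            rows.append((terms[col], est, se, df_within, t,
                         2 * stats.t.sf(abs(t), df_within)))
        for jj, col in enumerate(is_between):
            est, se = beta_b[jj], np.sqrt(var_b[jj])
            t = est / se if se > 0 else np.nan
            rows.append((terms[col], est, se, df_b[jj], t,
                         2 * stats.t.sf(abs(t), df_b[jj])))
        order = {t: i for i, t in enumerate(terms)}
        fe = (
            pd.DataFrame(rows, columns=["term", "estimate", "se", "df", "t", "p"])
            .sort_values("term", key=lambda s: s.map(order))
            .reset_index(drop=True)
        )

        # ---- omnibus type-III F tests per effect (within stratum: the main
        # effect of the within factor is the average over groups, i.e. the
        # contrast run_k + (1/g) sum_j int_{k,j})
        anova_rows = []
        n_wl = len(self.within_levels) - 1
        L_main = np.zeros((n_wl, len(is_within)))
        L_inter = np.zeros((n_wl * (g - 1), len(is_within)))
        for k, wl in enumerate(self.within_levels[1:]):
            L_main[k, w_names.index(f"{self.within}[{wl}]")] = 1.0
            for jg, gl in enumerate(self.group_levels[1:]):
                jj = w_names.index(f"{self.within}[{wl}]:{self.group}[{gl}]")
                L_main[k, jj] = 1.0 / g
                L_inter[k * (g - 1) + jg, jj] = 1.0
        for label, L in (
            (self.within, L_main),
            (f"{self.within}:{self.group}", L_inter),
        ):
            if L.size == 0:
                continue
            b = L @ beta_w
            V = L @ cov_w @ L.T
            # pinv guards the zero-residual-variance degenerate case
            F = (
                float(b @ np.linalg.pinv(V) @ b) / L.shape[0]
                if np.all(np.isfinite(V))
                else np.nan
            )
            anova_rows.append(
                (label, F, L.shape[0], df_within,
                 stats.f.sf(F, L.shape[0], df_within))
            )
        g_terms = [t for t in terms if self.group in t and ":" not in t]
        if g_terms:
            # the group main effect lives in the between stratum; averaging
            # over the within levels removes the interaction correction
            idx = [[terms[c] for c in is_between].index(t) for t in g_terms]
            b = gamma[idx]
            V = cov_gamma[np.ix_(idx, idx)]
            F = (
                float(b @ np.linalg.pinv(V) @ b) / len(idx)
                if np.all(np.isfinite(V))
                else np.nan
            )
            anova_rows.insert(
                1, (self.group, F, len(idx), df_between,
                    stats.f.sf(F, len(idx), df_between))
            )
        anova = pd.DataFrame(
            anova_rows, columns=["effect", "F", "df_num", "df_den", "p"]
        )
        return MixedLMResultsLite(
            fixed_effects=fe,
            anova=anova,
            var_subject=sigma_a2,
            var_residual=sigma_e2,
            method="reml-balanced-stratum (Satterthwaite-exact df)",
        )

    def _fit_mixedlm(self) -> MixedLMResultsLite:
        import statsmodels.api as sm

        df = self.data.copy()
        X, terms = self._design(df)
        exog = pd.DataFrame(X, columns=terms, index=df.index)
        model = sm.MixedLM(df[self.outcome], exog, groups=df[self.subject])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        n = len(df)
        df_resid = n - df[self.subject].nunique() - (len(terms) - 1)
        fe_params = res.params[terms]
        se = res.bse[terms]
        t = fe_params / se
        p = 2 * stats.t.sf(np.abs(t), df_resid)
        fe = pd.DataFrame(
            {
                "term": terms,
                "estimate": fe_params.to_numpy(),
                "se": se.to_numpy(),
                "df": df_resid,
                "t": t.to_numpy(),
                "p": p,
            }
        )
        return MixedLMResultsLite(
            fixed_effects=fe,
            anova=pd.DataFrame(columns=["effect", "F", "df_num", "df_den", "p"]),
            var_subject=float(res.cov_re.iloc[0, 0]),
            var_residual=float(res.scale),
            method="statsmodels-mixedlm (residual df)",
        )


# ------------------------------------------------------------ entry points


def fit_condition_lmm(
    betas: pd.DataFrame, condition: str
) -> MixedLMResultsLite:
    """Run x group mixed model for one emotion condition.

    The outcome per participant x run is the mean of the four block betas;
    fixed effects are run (reference run 1), group congruency (reference
    congruent) and their interaction, with a random intercept per
    participant, REML estimation and stratum-exact Satterthwaite df.
    """
    sub = betas[betas["group"].str.startswith(condition)]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    per_run = (
        sub.groupby(["participant_id", "group", "congruent", "run"])["beta"]
        .mean()
        .reset_index()
    )
    per_run["congruency"] = np.where(per_run["congruent"], "congruent", "incongruent")
    model = BalancedMixedLM(
        per_run,
        outcome="beta",
        subject="participant_id",
        within="run",
        group="congruency",
        within_ref=1,
        group_ref="congruent",
    )
    return model.fit()


def test_habituation(slopes: pd.DataFrame) -> pd.DataFrame:
    """Per group x run one-sample t-test of habituation slopes against 0.

    Returns rows (group, run, n, mean slope, sd, t, df = n-1, p); a
    degenerate cell (sd = 0, mean != 0) is flagged with t = NaN.
    """
    rows = []
    for (group, run), sub in slopes.groupby(["group", "run"], sort=True):
        vals = sub["slope"].to_numpy(float)
        n = vals.size
        if n < 2:
            raise ValueError(f"group {group} run {run}: need >= 2 slopes")
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0.0:
            t = 0.0 if mean == 0.0 else np.nan
            p = 1.0 if mean == 0.0 else np.nan
            degenerate = mean != 0.0
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
            t, p, degenerate = float(t), float(p), False
        rows.append(
            {
                "group": group, "run": run, "n": n, "beta": mean, "sd": sd,
                "t": t, "df": n - 1, "p": p, "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def fit_psychometric_lmm(
    scores: pd.DataFrame, condition: str, scale: str
) -> MixedLMResultsLite:
    """Pre/post x group mixed model for one questionnaire scale.

    ``scores`` is long format with columns participant_id, group,
    congruent, scale, time ('pre'/'post'), score. Participants missing a
    timepoint are dropped with a warning.
    """
    sub = scores[
        scores["group"].str.startswith(condition) & (scores["scale"] == scale)
    ].copy()
    counts = sub.groupby("participant_id")["time"].nunique()
    incomplete = counts[counts < 2].index
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} participant(s) missing a timepoint",
            stacklevel=2,
        )
        sub = sub[~sub["participant_id"].isin(incomplete)]
    sub["congruency"] = np.where(sub["congruent"], "congruent", "incongruent")
    model = BalancedMixedLM(
        sub,
        outcome="score",
        subject="participant_id",
        within="time",
        group="congruency",
        within_ref="pre",
        group_ref="congruent",
    )
    return model.fit()


def scores_long(dataset) -> pd.DataFrame:
    """Long-format psychometric table from a simulated cohort."""
    rows = []
    for p in dataset.participants:
        for scale, (pre, post) in p.scores.items():
            for time, val in (("pre", pre), ("post", post)):
                rows.append(
                    {
                        "participant_id": p.id,
                        "group": p.group.name,
                        "congruent": p.group.congruent,
                        "scale": scale,
                        "time": time,
                        "score": val,
                    }
                )
    return pd.DataFrame(rows)


# ------------------------------------------------- connectivity comparisons


def two_sample_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch t and df from printed summary statistics."""
    se2 = sd1**2 / n1 + sd2**2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (
        (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
    )
    return float(t), float(df)


def compare_connectivity(values: pd.DataFrame) -> pd.DataFrame:
    """t-test table over per-participant connectivity summaries.

    ``values`` has columns participant_id, group, run, value. Emits

    * within-group run-1 vs run-4 paired t (df = n-1);
    * between-group comparisons of the run-4 values, both as Welch
      two-sample tests and as a pair-by-participant-index variant with
      df = n-1 (both reported because pairing across independent groups is
      a reporting convention, not a statistical pairing).
    """
    rows = []
    groups = sorted(values["group"].unique())
    runs_present = set(values["run"].unique())
    both_runs = {1, 4} <= runs_present
    target_run = 4 if 4 in runs_present else max(runs_present)
    for g in groups if both_runs else []:
        sub = values[values["group"] == g]
        r1 = sub[sub["run"] == 1].sort_values("participant_id")["value"].to_numpy()
        r4 = sub[sub["run"] == 4].sort_values("participant_id")["value"].to_numpy()
        if r1.size != r4.size:
            raise ValueError(f"group {g}: unbalanced run-1/run-4 pairs")
        if r1.size:
            d = r4 - r1
            if np.allclose(d.std(ddof=1), 0) and np.allclose(d.mean(), 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(r4, r1)
            rows.append(
                {
                    "comparison": f"{g}: run4 vs run1", "kind": "paired",
                    "t": float(t), "df": r1.size - 1, "p": float(p),
                }
            )
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            v1 = (
                values[(values["group"] == g1) & (values["run"] == target_run)]
                .sort_values("participant_id")["value"].to_numpy()
            )
            v2 = (
                values[(values["group"] == g2) & (values["run"] == target_run)]
                .sort_values("participant_id")["value"].to_numpy()
            )
            if not v1.size or not v2.size:
                continue
            t, p = stats.ttest_ind(v1, v2, equal_var=False)
            tw, dfw = two_sample_t_from_summary(
                v1.mean(), v1.std(ddof=1), v1.size, v2.mean(), v2.std(ddof=1), v2.size
            )
            rows.append(
                {
                    "comparison": f"{g1} vs {g2} (run {target_run})", "kind": "welch",
                    "t": float(t), "df": dfw, "p": float(p),
                }
            )
            if v1.size == v2.size:
                d = v1 - v2
                tp, pp = (
                    (0.0, 1.0)
                    if np.allclose(d.std(ddof=1), 0) and np.allclose(d.mean(), 0)
                    else stats.ttest_rel(v1, v2)
                )
                rows.append(
                    {
                        "comparison": f"{g1} vs {g2} (run {target_run})",
                        "kind": "paired-style",
                        "t": float(tp), "df": v1.size - 1, "p": float(pp),
                    }
                )
    return pd.DataFrame(rows)


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (opt-in column for result tables)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p, float), method="holm")[1]
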