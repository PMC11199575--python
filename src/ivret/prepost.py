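"""Pre/post inference for two response categories.

The centrepiece is the 2 (response category) x 2 (time) mixed
between-within ANOVA. For two within-subject levels the decomposition has
a convenient exact form in terms of per-subject means ``m_i`` and change
scores ``d_i = post - pre``:

* between-subjects: SS_group from group means of ``m_i`` (weighted by
  group size), error SS from subjects around their group mean;
* within-subjects: SS_time = N * dbar^2 / 2, SS_interaction =
  sum_g n_g (dbar_g - dbar)^2 / 2, error SS = sum (d_i - dbar_g)^2 / 2.

The interaction F is then algebraically identical to the squared
pooled-variance t statistic comparing change scores between groups — the
oracle the tests exploit. Sphericity is trivially satisfied with two
levels (Greenhouse-Geisser epsilon = 1). Effect sizes use generalized eta
squared (Olejnik-Algina): SS_effect over SS_effect plus *all* error sums
of squares, the convention appropriate to repeated-measures designs.

Also here: Bonferroni post-hoc contrasts, baseline-adjusted ANCOVA at
post, percent change, the within/between Cohen's d conventions, and the
distributional diagnostics (Shapiro-Wilk, Levene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .cohort import OutcomeSpec
from .classify import ClassificationResult, RESPONDER, NON_RESPONDER

__all__ = [
    "MixedAnovaResult",
    "Contrast",
    "mixed_anova",
    "bonferroni_posthoc",
    "ancova_post",
    "percent_change",
    "cohens_d_within",
    "cohens_d_between",
    "cohens_d_ci",
    "diagnostics",
    "group_ttests",
    "prepost_summary",
]

_GROUPS = (RESPONDER, NON_RESPONDER)


# ---------------------------------------------------------------------------
# effect sizes and simple summaries


def percent_change(mean_pre: float, mean_delta: float) -> float:
    """Percent change |mean_delta| / mean_pre * 100 (unrounded).

    The magnitude convention matches how intervention tables print
    "delta %" rows: the direction is carried by the delta itself.
    """
    if mean_pre == 0:
        raise ValueError("percent change undefined for a zero baseline mean")
    return abs(mean_delta) / mean_pre * 100.0


def cohens_d_within(mean_delta: float, sd_pre: float, sd_post: float) -> float:
    """Within-group effect size: |mean change| over the pooled pre/post SD.

    ESw = |mean_delta| / sqrt((sd_pre^2 + sd_post^2) / 2). This is the
    convention that reproduces printed within-group effect sizes from
    group summary rows; the alternative mean_delta / SD_delta is exposed
    via ``group_ttests``/``bonferroni_posthoc`` outputs instead.
    """
    if sd_pre <= 0 or sd_post <= 0:
        raise ValueError("pre/post SDs must be positive")
    return abs(mean_delta) / math.sqrt((sd_pre**2 + sd_post**2) / 2.0)


def cohens_d_between(
    mean_1: float,
    sd_1: float,
    mean_2: float,
    sd_2: float,
    *,
    n_1: int | None = None,
    n_2: int | None = None,
    weighting: str = "equal",
) -> float:
    """Between-group effect size |mean_1 - mean_2| / pooled SD.

    ``weighting="equal"`` (default) pools as sqrt((sd1^2 + sd2^2)/2);
    ``"sample-size"`` uses the n-weighted pooled SD and requires n_1, n_2.
    """
    if sd_1 <= 0 or sd_2 <= 0:
        raise ValueError("group SDs must be positive")
    if weighting == "equal":
        pooled = math.sqrt((sd_1**2 + sd_2**2) / 2.0)
    elif weighting == "sample-size":
        if not n_1 or not n_2:
            raise ValueError("sample-size weighting requires n_1 and n_2")
        pooled = math.sqrt(
            ((n_1 - 1) * sd_1**2 + (n_2 - 1) * sd_2**2) / (n_1 + n_2 - 2)
        )
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return abs(mean_1 - mean_2) / pooled


def cohens_d_ci(
    t_stat: float, df: float, scale: float, *, level: float = 0.95, method: str = "nct"
) -> tuple[float, float]:
    """CI for a Cohen's d obtained as ``d = t * scale``.

    ``method="nct"`` inverts the noncentral-t distribution for the
    noncentrality parameter (the standard d CI); ``"normal"`` is the
    large-sample Wald approximation.
    """
    alpha = 1.0 - level
    if method == "normal":
        se = scale * math.sqrt(1.0 + t_stat**2 / (2.0 * df))
        z = stats.norm.ppf(1 - alpha / 2)
        return (t_stat * scale - z * se, t_stat * scale + z * se)
    if method != "nct":
        raise ValueError(f"unknown method {method!r}")

    def _bound(q: float) -> float:
        # ncp such that P(T_{df,ncp} <= t_stat) == q
        f = lambda nc: stats.nct.cdf(t_stat, df, nc) - q
        lo, hi = t_stat - 50.0 - 10.0, t_stat + 50.0 + 10.0
        try:
            return optimize.brentq(f, lo, hi, xtol=1e-8)
        except ValueError:  # t so extreme the bracket failed
            return lo if f(lo) < 0 else hi

    return (_bound(1 - alpha / 2) * scale, _bound(alpha / 2) * scale)


# ---------------------------------------------------------------------------
# the 2x2 mixed between-within ANOVA


@dataclass(frozen=True)
class MixedAnovaResult:
    """ANOVA table plus cell summaries for a 2x2 mixed design."""

    outcome: str
    anova: pd.DataFrame  # effects x (SS, df1, df2, F, p, ges)
    cells: pd.DataFrame  # group x time: n, mean, sd, ci_low, ci_high
    deltas: pd.DataFrame  # per group: n, mean, sd, ci_low, ci_high, pct_change
    epsilon: float = 1.0  # Greenhouse-Geisser; identically 1 for 2 levels
    sphericity_note: str = "two within-subject levels: sphericity holds, epsilon = 1"

    def effect(self, name: str) -> pd.Series:
        return self.anova.loc[name]


def _split(table: pd.DataFrame, labels: ClassificationResult, outcome: OutcomeSpec):
    """Pre/post arrays per response group, in fixed (Rs, NRs) order."""
    lab = labels.label_series
    merged = table.set_index("subject_id")
    out = {}
    for g in _GROUPS:
        ids = lab.index[lab == g]
        sub = merged.loc[ids]
        out[g] = (
            sub[outcome.pre_col].to_numpy(float),
            sub[outcome.post_col].to_numpy(float),
        )
    return out


def _ci_mean(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = len(x)
    m = x.mean()
    half = stats.t.ppf(0.5 + level / 2, n - 1) * x.std(ddof=1) / math.sqrt(n)
    return m - half, m + half


def mixed_anova(
    table: pd.DataFrame, labels: ClassificationResult, outcome: OutcomeSpec
) -> MixedAnovaResult:
    """2 (response category) x 2 (time) mixed between-within ANOVA.

    Returns the three-effect ANOVA table (group, time, interaction) with
    F, degrees of freedom, p and generalized eta squared, plus per-cell
    and per-group change summaries.
    """
    data = _split(table, labels, outcome)
    for g, (pre, post) in data.items():
        if len(pre) < 2:
            raise ValueError(f"group {g!r} has {len(pre)} subject(s); need >= 2")

    pre1, post1 = data[RESPONDER]
    pre2, post2 = data[NON_RESPONDER]
    n1, n2 = len(pre1), len(pre2)
    n = n1 + n2

    m1, m2 = (pre1 + post1) / 2.0, (pre2 + post2) / 2.0
    d1, d2 = post1 - pre1, post2 - pre2
    m_all = np.concatenate([m1, m2])
    d_all = np.concatenate([d1, d2])
    grand_m = m_all.mean()
    dbar = d_all.mean()

    ss_group = 2.0 * (n1 * (m1.mean() - grand_m) ** 2 + n2 * (m2.mean() - grand_m) ** 2)
    ss_err_b = 2.0 * (((m1 - m1.mean()) ** 2).sum() + ((m2 - m2.mean()) ** 2).sum())
    ss_time = n * dbar**2 / 2.0
    ss_inter = (n1 * (d1.mean() - dbar) ** 2 + n2 * (d2.mean() - dbar) ** 2) / 2.0
    ss_err_w = (((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()) / 2.0

    df_err = n - 2
    ms_err_b = ss_err_b / df_err
    ms_err_w = ss_err_w / df_err
    if np.ptp(np.concatenate([pre1, post1, pre2, post2])) == 0:
        raise ValueError(
            f"outcome {outcome.name!r} is constant; the mixed ANOVA is undefined"
        )

    ss_err_total = ss_err_b + ss_err_w
    rows = []
    for name, ss, ms_err in (
        ("group", ss_group, ms_err_b),
        ("time", ss_time, ms_err_w),
        ("interaction", ss_inter, ms_err_w),
    ):
        if ms_err <= 0:
            # degenerate but consistent data (e.g. identical change scores in
            # every subject): a zero effect over zero error is no effect at
            # all; a non-zero effect over zero error is a deterministic one
            if ss <= 1e-12:
                f, p = 0.0, 1.0
            else:
                f, p = math.inf, 0.0
        else:
            f = ss / ms_err
            p = float(stats.f.sf(f, 1, df_err))
        rows.append(
            {
                "effect": name,
                "SS": ss,
                "df1": 1,
                "df2": df_err,
                "F": f,
                "p": p,
                "ges": ss / (ss + ss_err_total) if (ss + ss_err_total) > 0 else 0.0,
            }
        )
    anova = pd.DataFrame(rows).set_index("effect")

    cells = []
    for g, (pre, post) in data.items():
        for phase, x in (("pre", pre), ("post", post)):
            lo, hi = _ci_mean(x)
            cells.append(
                {
                    "group": g,
                    "time": phase,
                    "n": len(x),
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    deltas = []
    for g, (pre, post) in data.items():
        d = post - pre
        lo, hi = _ci_mean(d)
        deltas.append(
            {
                "group": g,
                "n": len(d),
                "mean": d.mean(),
                "sd": d.std(ddof=1),
                "ci_low": lo,
                "ci_high": hi,
                "pct_change": percent_change(pre.mean(), d.mean()),
            }
        )
    return MixedAnovaResult(
        outcome=outcome.name,
        anova=anova,
        cells=pd.DataFrame(cells),
        deltas=pd.DataFrame(deltas),
    )


# ---------------------------------------------------------------------------
# post-hoc contrasts


@dataclass(frozen=True)
class Contrast:
    name: str
    kind: str  # "paired" | "unpaired"
    estimate: float  # mean difference
    t: float
    df: float
    p_raw: float
    p_adj: float
    d: float
    d_ci: tuple[float, float]


def bonferroni_posthoc(
    table: pd.DataFrame,
    labels: ClassificationResult,
    outcome: OutcomeSpec,
    *,
    family_size: int = 4,
    d_ci_method: str = "nct",
) -> list[Contrast]:
    """The four pairwise contrasts with Bonferroni-adjusted p-values.

    Within each group pre vs post (paired t); between groups at pre and at
    post (unpaired Student t). ``p_adj = min(1, family_size * p_raw)``.
    Cohen's d uses the pooled pre/post SD within groups and equal-weight
    pooling between groups, with noncentral-t CIs by default.
    """
    data = _split(table, labels, outcome)
    contrasts: list[Contrast] = []

    for g, (pre, post) in data.items():
        n = len(pre)
        t, p = stats.ttest_rel(post, pre)
        d = cohens_d_within(post.mean() - pre.mean(), pre.std(ddof=1), post.std(ddof=1))
        # CI through the paired-t ncp, rescaled from the d_z metric to ESw
        dd = post - pre
        scale_z = 1.0 / math.sqrt(n)
        rescale = dd.std(ddof=1) / math.sqrt((pre.var(ddof=1) + post.var(ddof=1)) / 2.0)
        lo, hi = cohens_d_ci(float(t), n - 1, scale_z * rescale, method=d_ci_method)
        contrasts.append(
            Contrast(
                name=f"{g}: pre vs post",
                kind="paired",
                estimate=float(post.mean() - pre.mean()),
                t=float(t),
                df=n - 1,
                p_raw=float(p),
                p_adj=min(1.0, family_size * float(p)),
                d=d,
                d_ci=(lo, hi),
            )
        )

    for phase, idx in (("pre", 0), ("post", 1)):
        x1 = data[RESPONDER][idx]
        x2 = data[NON_RESPONDER][idx]
        n1, n2 = len(x1), len(x2)
        t, p = stats.ttest_ind(x1, x2, equal_var=True)
        d = cohens_d_between(x1.mean(), x1.std(ddof=1), x2.mean(), x2.std(ddof=1))
        scale = math.sqrt(1.0 / n1 + 1.0 / n2)
        lo, hi = cohens_d_ci(float(t), n1 + n2 - 2, scale, method=d_ci_method)
        contrasts.append(
            Contrast(
                name=f"{RESPONDER} vs {NON_RESPONDER} at {phase}",
                kind="unpaired",
                estimate=float(x1.mean() - x2.mean()),
                t=float(t),
                df=n1 + n2 - 2,
                p_raw=float(p),
                p_adj=min(1.0, family_size * float(p)),
                d=d,
                d_ci=(lo, hi),
            )
        )
    return contrasts


# ---------------------------------------------------------------------------
# ANCOVA, diagnostics, group tests


@dataclass(frozen=True)
class AncovaResult:
    adjusted_means: dict[str, float]
    group_effect: float  # Rs minus NRs, baseline-adjusted
    F: float
    p: float
    df: tuple[int, int]


def ancova_post(
    table: pd.DataFrame, labels: ClassificationResult, outcome: OutcomeSpec
) -> AncovaResult:
    """Post-intervention group comparison adjusted for baseline.

    Fits ``post ~ group + pre`` by OLS; the group effect is the adjusted
    Rs - NRs difference at the grand baseline mean. A globally constant
    baseline carries no information and the covariate is dropped (the
    comparison degenerates to the unadjusted t-test, F = t^2); a baseline
    collinear with the group indicator makes adjustment impossible and is
    an error.
    """
    data = _split(table, labels, outcome)
    pre = np.concatenate([data[g][0] for g in _GROUPS])
    post = np.concatenate([data[g][1] for g in _GROUPS])
    grp = np.concatenate(
        [np.full(len(data[g][0]), 1.0 if g == RESPONDER else 0.0) for g in _GROUPS]
    )
    if np.ptp(pre) == 0:
        # no covariate information at all: unadjusted comparison
        X0 = sm.add_constant(grp)
        fit0 = sm.OLS(post, X0).fit()
        mean_by = {
            RESPONDER: float(fit0.params[0] + fit0.params[1]),
            NON_RESPONDER: float(fit0.params[0]),
        }
        return AncovaResult(
            adjusted_means=mean_by,
            group_effect=float(fit0.params[1]),
            F=float(fit0.tvalues[1] ** 2),
            p=float(fit0.pvalues[1]),
            df=(1, int(fit0.df_resid)),
        )
    if all(np.ptp(data[g][0]) == 0 for g in _GROUPS):
        raise ValueError(
            "baseline is collinear with the group indicator (constant within "
            "each group); baseline adjustment is impossible"
        )
    X = sm.add_constant(np.column_stack([grp, pre]))
    fit = sm.OLS(post, X).fit()
    beta_g = fit.params[1]
    t_g = fit.tvalues[1]
    grand_pre = pre.mean()
    adj = {
        RESPONDER: float(fit.params[0] + beta_g + fit.params[2] * grand_pre),
        NON_RESPONDER: float(fit.params[0] + fit.params[2] * grand_pre),
    }
    return AncovaResult(
        adjusted_means=adj,
        group_effect=float(beta_g),
        F=float(t_g**2),
        p=float(fit.pvalues[1]),
        df=(1, int(fit.df_resid)),
    )


def diagnostics(
    table: pd.DataFrame, labels: ClassificationResult, outcome: OutcomeSpec
) -> pd.DataFrame:
    """Model-assumption checks for the 2x2 design.

    Shapiro-Wilk per cell (skipped with a reason for n < 3), Levene
    (centre = mean, i.e. on absolute deviations from group means) across
    groups at pre, at post and on change scores, and the sphericity note
    (epsilon = 1 with two within levels).
    """
    data = _split(table, labels, outcome)
    rows = []
    for g, (pre, post) in data.items():
        for phase, x in (("pre", pre), ("post", post)):
            if len(x) < 3:
                rows.append(
                    {
                        "test": "shapiro_wilk",
                        "where": f"{g}/{phase}",
                        "statistic": np.nan,
                        "p": np.nan,
                        "note": f"skipped: n={len(x)} < 3",
                    }
                )
            else:
                w, p = stats.shapiro(x)
                rows.append(
                    {
                        "test": "shapiro_wilk",
                        "where": f"{g}/{phase}",
                        "statistic": float(w),
                        "p": float(p),
                        "note": "",
                    }
                )
    for phase, idx in (("pre", 0), ("post", 1), ("delta", None)):
        if idx is None:
            xs = [data[g][1] - data[g][0] for g in _GROUPS]
        else:
            xs = [data[g][idx] for g in _GROUPS]
        w, p = stats.levene(*xs, center="mean")
        rows.append(
            {
                "test": "levene",
                "where": phase,
                "statistic": float(w),
                "p": float(p),
                "note": "absolute deviations from group means",
            }
        )
    rows.append(
        {
            "test": "mauchly",
            "where": "time",
            "statistic": np.nan,
            "p": np.nan,
            "note": "two within-subject levels: sphericity holds, epsilon = 1",
        }
    )
    return pd.DataFrame(rows)


def group_ttests(
    table: pd.DataFrame,
    labels: ClassificationResult,
    columns: list[str],
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Unpaired two-sample t-tests between response groups per column.

    Used both for baseline-characteristic comparisons and for the
    change-score (delta) comparison between categories, which for
    independent groups must be an independent-samples test. Student
    (pooled variance) by default; Welch by flag.
    """
    lab = labels.label_series
    merged = table.set_index("subject_id")
    ids1 = lab.index[lab == RESPONDER]
    ids2 = lab.index[lab == NON_RESPONDER]
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValueError(
            f"both groups need >= 2 subjects (Rs={len(ids1)}, NRs={len(ids2)})"
        )
    rows = []
    for col in columns:
        x1 = merged.loc[ids1, col].to_numpy(float)
        x2 = merged.loc[ids2, col].to_numpy(float)
        t, p = stats.ttest_ind(x1, x2, equal_var=not welch)
        df = (
            len(x1) + len(x2) - 2
            if not welch
            else _welch_df(x1, x2)
        )
        rows.append(
            {
                "column": col,
                "mean_Rs": x1.mean(),
                "sd_Rs": x1.std(ddof=1),
                "mean_NRs": x2.mean(),
                "sd_NRs": x2.std(ddof=1),
                "t": float(t),
                "df": df,
                "p": float(p),
                "d": cohens_d_between(
                    x1.mean(), x1.std(ddof=1), x2.mean(), x2.std(ddof=1)
                ),
            }
        )
    return pd.DataFrame(rows)


def _welch_df(x1: np.ndarray, x2: np.ndarray) -> float:
    v1, v2 = x1.var(ddof=1) / len(x1), x2.var(ddof=1) / len(x2)
    return (v1 + v2) ** 2 / (v1**2 / (len(x1) - 1) + v2**2 / (len(x2) - 1))


def prepost_summary(
    table: pd.DataFrame, labels: ClassificationResult, outcome: OutcomeSpec
) -> dict:
    """One-call bundle: ANOVA, post-hocs, ANCOVA, diagnostics, summaries."""
    res = mixed_anova(table, labels, outcome)
    return {
        "outcome": outcome.name,
        "anova": res.anova.reset_index().to_dict(orient="records"),
        "cells": res.cells.to_dict(orient="records"),
        "deltas": res.deltas.to_dict(orient="records"),
        "epsilon": res.epsilon,
        "sphericity_note": res.sphericity_note,
        "contrasts": [
            {
                "name": c.name,
                "kind": c.kind,
                "estimate": c.estimate,
                "t": c.t,
                "df": c.df,
                "p_raw": c.p_raw,
                "p_adj": c.p_adj,
                "d": c.d,
                "d_ci": list(c.d_ci),
            }
            for c in bonferroni_posthoc(table, labels, outcome)
        ],
        "ancova_post": ancova_post(table, labels, outcome).__dict__,
        "diagnostics": diagnostics(table, labels, outcome).to_dict(orient="records"),
    }
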