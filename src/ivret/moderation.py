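"""Baseline moderation: does pre-intervention body fat predict the change?

Per response group, an OLS line Delta_outcome = b0 + b1 * BFP_pre; then
the classical two-line comparison in a pooled model with a 0/1 group
indicator (NRs reference):

    Delta = beta0 + beta1*BFP + beta2*group + beta3*(BFP x group)

Testing is hierarchical: the slope difference (beta3, "test for slopes")
first; the vertical shift ("test for intercepts") is then read from the
parallel-slopes model Delta = beta0 + beta1*BFP + beta2*group, which is
the only model in which a single intercept difference is defined when the
interaction is retained. A joint-model shift estimate (beta2 with the
interaction kept) is also reported for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import OutcomeSpec, DEFAULT_OUTCOME_SPECS
from .classify import ClassificationResult, RESPONDER, NON_RESPONDER, deltas

__all__ = ["GroupLine", "TwoLineComparison", "fit_group_lines", "compare_lines"]


@dataclass(frozen=True)
class GroupLine:
    group: str
    n: int
    b0: float  # intercept, outcome-change units
    b1: float  # slope, outcome-change units per % BFP
    se_b0: float
    se_b1: float
    r_squared: float


@dataclass(frozen=True)
class TwoLineComparison:
    lines: dict[str, GroupLine]
    # slope (interaction) test, from the full model
    slope_diff: float
    slope_t: float
    slope_p: float
    # intercept (vertical shift) test, from the parallel-slopes model
    intercept_diff: float
    intercept_t: float
    intercept_p: float
    # beta2 with the interaction retained (off the default testing path)
    joint_intercept_diff: float
    joint_intercept_p: float


def _design(
    table: pd.DataFrame, labels: ClassificationResult, outcome: OutcomeSpec
) -> pd.DataFrame:
    lab = labels.label_series
    d = deltas(table, outcome)
    bfp = pd.Series(
        table.set_index("subject_id")[DEFAULT_OUTCOME_SPECS["BFP"].pre_col],
    )
    df = pd.DataFrame({"bfp_pre": bfp, "delta": d, "group": lab}).dropna()
    return df


def fit_group_lines(
    table: pd.DataFrame, labels: ClassificationResult, outcome: OutcomeSpec
) -> dict[str, GroupLine]:
    """Per-group OLS of outcome change on baseline BFP."""
    df = _design(table, labels, outcome)
    lines: dict[str, GroupLine] = {}
    for g in (RESPONDER, NON_RESPONDER):
        sub = df[df["group"] == g]
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has {len(sub)} subjects; need >= 3")
        x = sub["bfp_pre"].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"baseline BFP is constant within group {g!r}")
        X = sm.add_constant(x)
        fit = sm.OLS(sub["delta"].to_numpy(float), X).fit()
        lines[g] = GroupLine(
            group=g,
            n=len(sub),
            b0=float(fit.params[0]),
            b1=float(fit.params[1]),
            se_b0=float(fit.bse[0]),
            se_b1=float(fit.bse[1]),
            r_squared=float(fit.rsquared),
        )
    return lines


def compare_lines(
    table: pd.DataFrame, labels: ClassificationResult, outcome: OutcomeSpec
) -> TwoLineComparison:
    """Two-line comparison: slope interaction, then parallel-slopes shift."""
    lines = fit_group_lines(table, labels, outcome)
    df = _design(table, labels, outcome)
    x = df["bfp_pre"].to_numpy(float)
    y = df["delta"].to_numpy(float)
    g = (df["group"] == RESPONDER).to_numpy(float)  # NRs = 0 reference

    X_full = sm.add_constant(np.column_stack([x, g, x * g]))
    full = sm.OLS(y, X_full).fit()
    X_par = sm.add_constant(np.column_stack([x, g]))
    par = sm.OLS(y, X_par).fit()

    return TwoLineComparison(
        lines=lines,
        slope_diff=float(full.params[3]),
        slope_t=float(full.tvalues[3]),
        slope_p=float(full.pvalues[3]),
        intercept_diff=float(par.params[2]),
        intercept_t=float(par.tvalues[2]),
        intercept_p=float(par.pvalues[2]),
        joint_intercept_diff=float(full.params[2]),
        joint_intercept_p=float(full.pvalues[2]),
    )
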