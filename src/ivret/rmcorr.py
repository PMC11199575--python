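"""Repeated-measures correlation (rmcorr), written from first principles.

rmcorr estimates the common within-subject association between two
variables measured on the same subjects at multiple occasions, by fitting
y on x with one intercept per subject and a single shared slope (the
ANCOVA with subject as the factor and x as covariate). The correlation is

    r_rm = sign(b) * sqrt(SS_x / (SS_x + SS_residual))

where SS_x is the sum of squares absorbed by the covariate after the
subject effects. Centring x and y within subject makes this explicit:
with x~, y~ the within-subject-centred values,

    b = sum(x~ y~) / sum(x~^2),   r_rm = sum(x~ y~) / sqrt(sum x~^2 sum y~^2)

with degrees of freedom N_obs - k - 1 for k subjects (= k*(m-1) - 1 with
m occasions each; k - 1 for the paired pre/post case). The p-value is the
two-sided t test on r_rm with those df. Subject-level constants in either
variable are absorbed by the intercepts and cannot influence r_rm.

Written generically in the number of occasions; the pre/post pipeline
uses exactly two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OutcomeSpec

__all__ = ["RmcorrResult", "rmcorr", "rmcorr_prepost"]


@dataclass(frozen=True)
class RmcorrResult:
    r_rm: float
    df: int
    p_value: float
    common_slope: float
    #: per-subject intercepts of the parallel fit lines, subject -> a_i
    subject_intercepts: dict[str, float]
    n_subjects: int
    n_obs: int


def rmcorr(data: pd.DataFrame, x: str, y: str, subject: str = "subject_id") -> RmcorrResult:
    """Repeated-measures correlation of ``y`` on ``x``.

    ``data`` is long-format with one row per (subject, occasion); every
    subject must have at least two complete occasions. Raises when any
    subject has missing occasions/values or when there is no
    within-subject variation in x.
    """
    for col in (x, y, subject):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    bad = data.loc[data[x].isna() | data[y].isna(), subject].unique().tolist()
    if bad:
        raise ValueError(
            f"missing x/y value(s) for subject(s): {', '.join(map(str, bad))}"
        )
    counts = data.groupby(subject).size()
    few = counts[counts < 2].index.tolist()
    if few:
        raise ValueError(
            f"subject(s) with fewer than 2 occasions: {', '.join(map(str, few))}"
        )
    k = len(counts)
    if k < 3:
        raise ValueError(f"rmcorr needs >= 3 subjects, got {k}")

    g = data.groupby(subject)
    xt = data[x] - g[x].transform("mean")
    yt = data[y] - g[y].transform("mean")
    sxx = float((xt**2).sum())
    syy = float((yt**2).sum())
    sxy = float((xt * yt).sum())
    if sxx == 0:
        raise ValueError(
            "no within-subject variation in x: all subjects' x-changes are zero; "
            "r_rm is undefined"
        )
    n_obs = len(data)
    df = n_obs - k - 1
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    if syy == 0:
        # y constant within every subject: slope 0, correlation undefined -> 0
        r = 0.0
    else:
        r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    slope = sxy / sxx
    inter = (g[y].mean() - slope * g[x].mean()).to_dict()
    return RmcorrResult(
        r_rm=float(r),
        df=int(df),
        p_value=p,
        common_slope=float(slope),
        subject_intercepts={str(s): float(a) for s, a in inter.items()},
        n_subjects=k,
        n_obs=n_obs,
    )


def rmcorr_prepost(
    table: pd.DataFrame, x_outcome: OutcomeSpec, y_outcome: OutcomeSpec
) -> RmcorrResult:
    """rmcorr between two outcomes over the pre/post occasions of a cohort.

    Reshapes the wide cohort table to long (two occasions per subject) and
    correlates the x outcome (body fat, in the study's framing) with the
    y outcome within subject.
    """
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject_id": table["subject_id"],
                    "occasion": phase,
                    x_outcome.name: table[f"{x_outcome.name}_{phase}"],
                    y_outcome.name: table[f"{y_outcome.name}_{phase}"],
                }
            )
            for phase in ("pre", "post")
        ],
        ignore_index=True,
    )
    return rmcorr(long, x=x_outcome.name, y=y_outcome.name)
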