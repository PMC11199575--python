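"""Responder / non-responder classification by the typical-error criterion.

The typical error TE = SD_diff / sqrt(2), where SD_diff is the sample SD
(n-1 denominator) of the pre-to-post change scores, estimates the
measurement noise attached to a single occasion. A subject is a responder
(Rs) for an outcome when the *beneficial* change — the negated change for
outcomes where a decrease is the benefit — strictly exceeds twice the
typical error of their stratum; everyone else is a non-responder (NRs).
Ties at the cutoff are NRs (the criterion is "greater than two-fold TE").

The deltas feeding SD_diff are configurable (``te_source``): by default
the analysed subjects of each stratum supply their own TE ("within"); a
fixed externally supplied cutoff is also accepted, which is how
control-group-derived or published cutoffs are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OutcomeSpec, CohortError

__all__ = [
    "ClassificationResult",
    "deltas",
    "typical_error",
    "classify",
    "RESPONDER",
    "NON_RESPONDER",
]

RESPONDER = "Rs"
NON_RESPONDER = "NRs"
ADVERSE_RESPONDER = "ARs"


@dataclass(frozen=True)
class ClassificationResult:
    """Per-subject labels plus the stratum cutoffs that produced them.

    ``labels`` is a DataFrame with one row per subject: subject_id, outcome,
    delta (post - pre, sign preserved), benefit (delta on the benefit
    scale), stratum, TE, cutoff (= 2*TE), label (Rs/NRs).
    ``cutoffs`` maps stratum -> (TE, cutoff).
    """

    outcome: OutcomeSpec
    labels: pd.DataFrame
    cutoffs: dict[str, tuple[float, float]]

    @property
    def label_series(self) -> pd.Series:
        """Labels indexed by subject_id."""
        return self.labels.set_index("subject_id")["label"]

    def counts(self) -> dict[str, int]:
        c = self.labels["label"].value_counts()
        return {RESPONDER: int(c.get(RESPONDER, 0)), NON_RESPONDER: int(c.get(NON_RESPONDER, 0))}


def deltas(table: pd.DataFrame, outcome: OutcomeSpec) -> pd.Series:
    """Per-subject change post - pre for one outcome, indexed by subject_id.

    The sign is the raw arithmetic sign, *not* benefit-oriented.
    """
    for col in (outcome.pre_col, outcome.post_col):
        if col not in table.columns:
            raise CohortError(f"missing required column(s): {col}")
    pre = table[outcome.pre_col]
    post = table[outcome.post_col]
    bad = table.loc[pre.isna() | post.isna(), "subject_id"].tolist()
    if bad:
        raise CohortError(
            f"missing {outcome.name} value(s) for subject(s): {', '.join(map(str, bad))}"
        )
    d = post - pre
    d.index = pd.Index(table["subject_id"], name="subject_id")
    d.name = f"delta_{outcome.name}"
    return d


def typical_error(change_scores) -> float:
    """Typical error TE = SD_diff / sqrt(2) of a vector of change scores.

    Uses the sample SD (n-1 denominator); requires at least two scores.
    """
    x = np.asarray(change_scores, dtype=float)
    if x.size < 2:
        raise ValueError(f"typical error needs >= 2 change scores, got {x.size}")
    return float(np.std(x, ddof=1) / math.sqrt(2.0))


def classify(
    table: pd.DataFrame,
    outcome: OutcomeSpec,
    *,
    strata: str | None = None,
    te_source: str = "within",
    fixed_cutoffs: dict[str, float] | float | None = None,
    adverse_class: bool = False,
) -> ClassificationResult:
    """Assign Rs/NRs labels for one outcome.

    Parameters
    ----------
    table
        Cohort table with pre/post columns for ``outcome``.
    outcome
        The outcome spec; its ``benefit_direction`` orients the criterion.
    strata
        Optional grouping column (e.g. ``"sex"``): TE and cutoff are
        computed per stratum, mirroring sex-specific cutoffs.
    te_source
        ``"within"`` (default): each stratum's own deltas supply SD_diff.
        ``"fixed"``: use ``fixed_cutoffs`` (a scalar, or a mapping
        stratum -> cutoff) as the benefit cutoff directly; TE is reported
        as cutoff/2.
    fixed_cutoffs
        Required when ``te_source="fixed"``.
    adverse_class
        When true, subjects whose change exceeds the cutoff in the
        *harmful* direction are labelled ``ARs`` instead of ``NRs``
        (three-class variant; default off — binary Rs/NRs).
    """
    if te_source not in ("within", "fixed"):
        raise ValueError(f"unknown te_source {te_source!r}; use 'within' or 'fixed'")
    if strata is not None and strata not in table.columns:
        raise CohortError(f"missing required column(s): {strata}")

    d = deltas(table, outcome)
    stratum = (
        pd.Series("all", index=d.index)
        if strata is None
        else pd.Series(table[strata].values, index=d.index).astype(str)
    )

    cutoffs: dict[str, tuple[float, float]] = {}
    for name, idx in stratum.groupby(stratum).groups.items():
        if te_source == "within":
            if len(idx) < 2:
                raise ValueError(
                    f"stratum {name!r} has {len(idx)} subject(s); need >= 2 "
                    "to estimate a typical error"
                )
            te = typical_error(d.loc[idx])
            cutoffs[str(name)] = (te, 2.0 * te)
        else:
            if fixed_cutoffs is None:
                raise ValueError("te_source='fixed' requires fixed_cutoffs")
            cut = (
                float(fixed_cutoffs)
                if np.isscalar(fixed_cutoffs)
                else float(fixed_cutoffs[str(name)])
            )
            cutoffs[str(name)] = (cut / 2.0, cut)

    benefit = outcome.sign * d
    cut_per_subject = stratum.map(lambda s: cutoffs[str(s)][1])
    te_per_subject = stratum.map(lambda s: cutoffs[str(s)][0])
    label = np.where(benefit > cut_per_subject, RESPONDER, NON_RESPONDER)
    if adverse_class:
        label = np.where(benefit < -cut_per_subject, ADVERSE_RESPONDER, label)

    labels = pd.DataFrame(
        {
            "subject_id": d.index,
            "outcome": outcome.name,
            "delta": d.values,
            "benefit": benefit.values,
            "stratum": stratum.values,
            "TE": te_per_subject.values,
            "cutoff": cut_per_subject.values,
            "label": label,
        }
    ).reset_index(drop=True)
    return ClassificationResult(outcome=outcome, labels=labels, cutoffs=cutoffs)
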