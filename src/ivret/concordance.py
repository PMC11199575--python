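"""Cross-outcome concordance of response categories.

Given Rs/NRs labels on two outcomes for the same subjects: 2x2 contingency
table, Pearson chi-squared test of independence (Yates correction
optional, off by default), sample odds ratio with Wald log-scale CI
(Haldane-Anscombe 0.5 correction optional for zero cells), Cramer's V,
Fisher's exact fallback, and a long-format flow table (the Sankey data:
how body-fat responders redistribute across the response categories of
each physiological outcome).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassificationResult, RESPONDER, NON_RESPONDER

__all__ = [
    "crosstab",
    "chi2_independence",
    "odds_ratio",
    "cramers_v",
    "fisher_exact",
    "flow_export",
    "pairwise_stats",
    "SmallCellWarning",
]


class SmallCellWarning(UserWarning):
    """Expected cell count below 5: the chi-squared approximation is shaky."""


def _align(labels_a: ClassificationResult, labels_b: ClassificationResult):
    a = labels_a.label_series
    b = labels_b.label_series
    sym = set(a.index).symmetric_difference(b.index)
    if sym:
        raise ValueError(
            "label vectors cover different subjects; symmetric difference: "
            f"{sorted(map(str, sym))}"
        )
    return a, b.reindex(a.index)


def crosstab(labels_a: ClassificationResult, labels_b: ClassificationResult) -> np.ndarray:
    """2x2 count table [[Rs&Rs, Rs&NRs], [NRs&Rs, NRs&NRs]] (a rows, b cols)."""
    a, b = _align(labels_a, labels_b)
    order = [RESPONDER, NON_RESPONDER]
    t = np.zeros((2, 2), dtype=int)
    for i, la in enumerate(order):
        for j, lb in enumerate(order):
            t[i, j] = int(((a == la) & (b == lb)).sum())
    return t


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("contingency table must be a 2-D array of non-negative counts")
    if t.sum() <= 0:
        raise ValueError("contingency table is empty")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError(
            "chi-squared test undefined: a margin of the table is zero\n" + str(t)
        )
    return t


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def chi2_independence(table, *, correction: bool = False) -> Chi2Result:
    """Pearson chi-squared test of independence on a contingency table.

    Yates continuity correction is applied only when ``correction=True``
    (default off). Emits :class:`SmallCellWarning` when any expected count
    is below 5.
    """
    t = _validate_table(table)
    chi2, p, df, expected = stats.chi2_contingency(t, correction=correction)
    if (expected < 5).any():
        warnings.warn(
            f"expected counts below 5 (min {expected.min():.2f}); consider "
            "fisher_exact",
            SmallCellWarning,
            stacklevel=2,
        )
    return Chi2Result(float(chi2), int(df), float(p), expected)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_applied: bool
    degenerate: bool  # zero cell without correction: OR is 0 or inf


def odds_ratio(table, *, haldane: bool = False, ci_level: float = 0.95) -> OddsRatioResult:
    """Sample odds ratio (a*d)/(b*c) of a 2x2 table with Wald log-scale CI.

    With ``haldane=True``, 0.5 is added to every cell when any cell is
    zero (Haldane-Anscombe). Without it, a zero cell yields an explicit
    0 or ``inf`` with ``degenerate=True`` — never a silent NaN.
    """
    t = _validate_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"odds ratio requires a 2x2 table, got shape {t.shape}")
    applied = False
    if haldane and (t == 0).any():
        t = t + 0.5
        applied = True
    a, b, c, d = t.ravel()
    if b * c == 0 or a * d == 0:
        orr = math.inf if (b * c == 0 and a * d > 0) else 0.0
        return OddsRatioResult(orr, math.nan, math.nan, applied, True)
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)
    return OddsRatioResult(float(orr), lo, hi, applied, False)


def cramers_v(table) -> float:
    """Cramer's V = sqrt(chi2 / (N * min(r-1, c-1))), uncorrected chi2."""
    t = _validate_table(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallCellWarning)
        chi2 = chi2_independence(t, correction=False).statistic
    n = t.sum()
    k = min(t.shape[0] - 1, t.shape[1] - 1)
    return float(math.sqrt(chi2 / (n * k)))


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test (two-sided) for small-cell 2x2 tables."""
    t = _validate_table(table)
    orr, p = stats.fisher_exact(t.astype(int))
    return float(orr), float(p)


def flow_export(
    labels_by_outcome: dict[str, ClassificationResult], source_outcome: str = "BFP"
) -> pd.DataFrame:
    """Long flow table: responder-category flows from one source outcome.

    One row per (source category, target category, count), for every
    target outcome other than the source. Counts per target outcome sum to
    the cohort size; this is the plot-ready Sankey data.
    """
    if source_outcome not in labels_by_outcome:
        raise ValueError(f"no labels for source outcome {source_outcome!r}")
    targets = [o for o in labels_by_outcome if o != source_outcome]
    if not targets:
        raise ValueError("need labels for at least one target outcome")
    src = labels_by_outcome[source_outcome]
    rows = []
    order = [RESPONDER, NON_RESPONDER]
    for tgt in targets:
        t = crosstab(src, labels_by_outcome[tgt])
        for i, la in enumerate(order):
            for j, lb in enumerate(order):
                rows.append(
                    {
                        "source": f"{la}_{source_outcome}",
                        "target": f"{lb}_{tgt}",
                        "count": int(t[i, j]),
                    }
                )
    return pd.DataFrame(rows)


def pairwise_stats(
    labels_by_outcome: dict[str, ClassificationResult],
    source_outcome: str = "BFP",
    *,
    correction: bool = False,
    haldane: bool = False,
) -> pd.DataFrame:
    """Chi-squared / OR / Cramer's V for the source outcome vs every other."""
    src = labels_by_outcome[source_outcome]
    rows = []
    for tgt, res in labels_by_outcome.items():
        if tgt == source_outcome:
            continue
        t = crosstab(src, res)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SmallCellWarning)
            c2 = chi2_independence(t, correction=correction)
        orr = odds_ratio(t, haldane=haldane)
        rows.append(
            {
                "source": source_outcome,
                "target": tgt,
                "chi2": c2.statistic,
                "df": c2.df,
                "p_value": c2.p_value,
                "odds_ratio": orr.odds_ratio,
                "or_ci_low": orr.ci_low,
                "or_ci_high": orr.ci_high,
                "cramers_v": cramers_v(t),
            }
        )
    return pd.DataFrame(rows)
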