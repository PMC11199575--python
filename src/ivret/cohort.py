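"""Cohort table schema, validation and CSV round-trip.

A cohort is a wide per-subject :class:`pandas.DataFrame`: one row per
subject with demographics and pre/post values of each analysed outcome
(body fat percentage, systolic/diastolic blood pressure, fitness index).
Simulated cohorts additionally carry ground-truth columns
(``true_delta_<outcome>``, ``true_responder_<outcome>``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeSpec",
    "OUTCOMES",
    "DEFAULT_OUTCOME_SPECS",
    "REQUIRED_COLUMNS",
    "CohortError",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """An analysed outcome: name, units, and direction of benefit.

    ``benefit_direction`` states which sign of change counts as an
    improvement — a *decrease* for adiposity and blood pressure, an
    *increase* for cardiorespiratory fitness. Response classification and
    flow analyses are always phrased on the benefit scale.
    """

    name: str
    units: str
    benefit_direction: str  # "decrease" | "increase"

    def __post_init__(self) -> None:
        if self.benefit_direction not in ("decrease", "increase"):
            raise ValueError(
                f"benefit_direction for {self.name!r} must be 'decrease' or "
                f"'increase', got {self.benefit_direction!r}"
            )

    @property
    def sign(self) -> int:
        """+1 if an increase is beneficial, -1 if a decrease is."""
        return 1 if self.benefit_direction == "increase" else -1

    @property
    def pre_col(self) -> str:
        return f"{self.name}_pre"

    @property
    def post_col(self) -> str:
        return f"{self.name}_post"


OUTCOMES: tuple[str, ...] = ("BFP", "SBP", "DBP", "FI")

DEFAULT_OUTCOME_SPECS: dict[str, OutcomeSpec] = {
    "BFP": OutcomeSpec("BFP", "%", "decrease"),
    "SBP": OutcomeSpec("SBP", "mmHg", "decrease"),
    "DBP": OutcomeSpec("DBP", "mmHg", "decrease"),
    "FI": OutcomeSpec("FI", "score", "increase"),
}

REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    *(f"{o}_{phase}" for o in OUTCOMES for phase in ("pre", "post")),
)

_NUMERIC_COLUMNS = tuple(c for c in REQUIRED_COLUMNS if c not in ("subject_id", "sex"))


class CohortError(ValueError):
    """Raised when a cohort table violates the schema contract."""


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the schema contract.

    Checks required columns, unique subject ids, complete cases in all
    analysis columns, legal sex codes, and BMI consistency when a ``bmi``
    column is present (|bmi - weight/(height/100)^2| <= 0.01). Returns the
    table unchanged on success.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortError(f"missing required column(s): {', '.join(missing)}")

    dup = table["subject_id"][table["subject_id"].duplicated()].unique().tolist()
    if dup:
        raise CohortError(f"duplicate subject_id(s): {', '.join(map(str, dup))}")

    bad_sex = sorted(set(table["sex"]) - {"male", "female"})
    if bad_sex:
        raise CohortError(f"sex must be 'male' or 'female', got {bad_sex}")

    for col in _NUMERIC_COLUMNS:
        na = table.loc[table[col].isna(), "subject_id"].tolist()
        if na:
            raise CohortError(
                f"missing values in analysis column {col!r} for subject(s): "
                f"{', '.join(map(str, na))} (complete-case contract)"
            )

    if "bmi" in table.columns:
        expected = table["weight_kg"] / (table["height_cm"] / 100.0) ** 2
        off = table.loc[(table["bmi"] - expected).abs() > 0.01, "subject_id"]
        if len(off):
            raise CohortError(
                "bmi inconsistent with weight/(height/100)^2 (tolerance 0.01) "
                f"for subject(s): {', '.join(map(str, off))}"
            )
    return table


def write_cohort(table: pd.DataFrame, destination: str | Path | IO[str]) -> None:
    """Write a cohort table to CSV (UTF-8, '.' decimal, full precision)."""
    validate_cohort(table)
    table.to_csv(destination, index=False)


def read_cohort(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read and validate a cohort table from CSV.

    Raises :class:`CohortError` naming the offending column / subjects when
    the file violates the schema.
    """
    table = pd.read_csv(source)
    bool_cols = [c for c in table.columns if c.startswith("true_responder_")]
    for c in bool_cols:
        table[c] = table[c].astype(bool)
    return validate_cohort(table)


def resolve_outcomes(names: Iterable[str] | None = None) -> list[OutcomeSpec]:
    """Map outcome names to their default specs (all four when ``None``)."""
    if names is None:
        names = OUTCOMES
    specs = []
    for n in names:
        if n not in DEFAULT_OUTCOME_SPECS:
            raise KeyError(
                f"unknown outcome {n!r}; declare an OutcomeSpec with an explicit "
                "benefit direction"
            )
        specs.append(DEFAULT_OUTCOME_SPECS[n])
    return specs
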