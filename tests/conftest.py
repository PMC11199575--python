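import numpy as np
import pandas as pd
import pytest

from ivret.cohort import DEFAULT_OUTCOME_SPECS, OUTCOMES
from ivret.classify import ClassificationResult, RESPONDER, NON_RESPONDER


def make_cohort(
    pre_by_group: dict[str, np.ndarray],
    post_by_group: dict[str, np.ndarray],
    outcome: str = "FI",
) -> tuple[pd.DataFrame, ClassificationResult]:
    """Build a minimal cohort table plus a label object from explicit
    per-group pre/post vectors for one outcome (other outcomes are filled
    with inert constants plus a tiny index ramp so validation passes)."""
    groups, pres, posts = [], [], []
    for g in (RESPONDER, NON_RESPONDER):
        if g in pre_by_group:
            pre = np.asarray(pre_by_group[g], dtype=float)
            post = np.asarray(post_by_group[g], dtype=float)
            groups += [g] * len(pre)
            pres.append(pre)
            posts.append(post)
    pre = np.concatenate(pres)
    post = np.concatenate(posts)
    n = len(pre)
    ids = [f"S{i:03d}" for i in range(n)]
    ramp = np.arange(n, dtype=float)
    table = {
        "subject_id": ids,
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "age": np.full(n, 16.0),
        "height_cm": 170.0 + ramp,
        "weight_kg": 60.0 + ramp,
    }
    for o in OUTCOMES:
        if o == outcome:
            table[f"{o}_pre"], table[f"{o}_post"] = pre, post
        else:
            table[f"{o}_pre"] = 50.0 + ramp
            table[f"{o}_post"] = 49.0 + ramp
    df = pd.DataFrame(table)
    lab = pd.DataFrame(
        {
            "subject_id": ids,
            "outcome": outcome,
            "delta": post - pre,
            "benefit": (post - pre) * DEFAULT_OUTCOME_SPECS[outcome].sign,
            "stratum": "all",
            "TE": 0.0,
            "cutoff": 0.0,
            "label": groups,
        }
    )
    labels = ClassificationResult(
        DEFAULT_OUTCOME_SPECS[outcome], lab, {"all": (0.0, 0.0)}
    )
    return df, labels


@pytest.fixture
def two_group_cohort():
    """8-subject cohort with distinct FI change distributions per group."""
    rng = np.random.default_rng(5)
    pre_rs = rng.normal(44, 4, 5)
    pre_nr = rng.normal(44, 4, 6)
    return make_cohort(
        {RESPONDER: pre_rs, NON_RESPONDER: pre_nr},
        {RESPONDER: pre_rs + rng.normal(3.5, 2.0, 5),
         NON_RESPONDER: pre_nr + rng.normal(0.5, 2.0, 6)},
    )


def random_two_group(rng, outcome="FI"):
    """Random small two-group pre/post dataset for oracle checks."""
    n1, n2 = rng.integers(3, 12, 2)
    pre1 = rng.normal(50, 8, n1)
    pre2 = rng.normal(50, 8, n2)
    return make_cohort(
        {RESPONDER: pre1, NON_RESPONDER: pre2},
        {
            RESPONDER: pre1 + rng.normal(rng.normal(0, 2), rng.uniform(0.5, 4), n1),
            NON_RESPONDER: pre2 + rng.normal(rng.normal(0, 2), rng.uniform(0.5, 4), n2),
        },
        outcome=outcome,
    )
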