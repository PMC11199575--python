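"""Typical-error computation and Rs/NRs assignment."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ivret.cohort import DEFAULT_OUTCOME_SPECS, OUTCOMES, OutcomeSpec, CohortError
from ivret.classify import (
    NON_RESPONDER,
    RESPONDER,
    classify,
    deltas,
    typical_error,
)
from ivret.simulate import default_params, simulate_cohort


def cohort_from_deltas(values, outcome="BFP", sexes=None):
    """Wide one-outcome cohort with pre=0 so delta == post."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    table = {
        "subject_id": [f"S{i:02d}" for i in range(n)],
        "sex": sexes if sexes is not None else ["male"] * n,
        "age": 16.0,
        "height_cm": 170.0,
        "weight_kg": 60.0,
    }
    for o in OUTCOMES:
        table[f"{o}_pre"] = 30.0
        table[f"{o}_post"] = 30.0 + (values if o == outcome else 0.0)
    return pd.DataFrame(table)


class TestDeltas:
    def test_sign_preserved(self):
        t = cohort_from_deltas([-2.3, 0.0, 6.0])
        d = deltas(t, DEFAULT_OUTCOME_SPECS["BFP"])
        assert d.tolist() == pytest.approx([-2.3, 0.0, 6.0])

    def test_fi_vector(self):
        t = cohort_from_deltas([6.0, 1.0], outcome="FI")
        d = deltas(t, DEFAULT_OUTCOME_SPECS["FI"])
        assert list(d) == [6.0, 1.0]

    def test_missing_value_names_subject(self):
        t = cohort_from_deltas([1.0, 2.0])
        t.loc[1, "BFP_post"] = np.nan
        with pytest.raises(CohortError, match="S01"):
            deltas(t, DEFAULT_OUTCOME_SPECS["BFP"])


class TestTypicalError:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5.0, 5.0, 5.0], 0.0),  # zero variance
            ([-2.0, 0.0, 2.0], 2.0 / math.sqrt(2)),  # SD = 2
            ([1.0, 3.0], 1.0),  # SD = sqrt(2)
        ],
    )
    def test_values(self, values, expected):
        assert typical_error(values) == pytest.approx(expected, abs=1e-9)

    def test_needs_two_scores(self):
        with pytest.raises(ValueError):
            typical_error([1.0])


class TestClassify:
    def test_published_male_cutoff_applied_as_fixed(self):
        # benefit (BFP decrease) of 7.0 clears the 6.298 cutoff; 6.0 does not
        t = cohort_from_deltas([-7.0, -6.0, -1.0, 2.0])
        res = classify(
            t,
            DEFAULT_OUTCOME_SPECS["BFP"],
            te_source="fixed",
            fixed_cutoffs=6.298,
        )
        assert list(res.labels["label"]) == [RESPONDER] + [NON_RESPONDER] * 3

    def test_tie_at_cutoff_is_non_responder(self):
        t = cohort_from_deltas([-4.0, -3.0, 0.0, 3.0])
        res = classify(
            t, DEFAULT_OUTCOME_SPECS["BFP"], te_source="fixed", fixed_cutoffs=4.0
        )
        # delta exactly at -cutoff: strict inequality, stays NRs
        assert res.labels.loc[0, "label"] == NON_RESPONDER

    def test_increase_direction(self):
        t = cohort_from_deltas([5.0, -5.0], outcome="FI")
        res = classify(
            t, DEFAULT_OUTCOME_SPECS["FI"], te_source="fixed", fixed_cutoffs=3.0
        )
        assert list(res.labels["label"]) == [RESPONDER, NON_RESPONDER]

    def test_adverse_class_flag(self):
        # harmful change beyond the cutoff only becomes ARs when requested
        t = cohort_from_deltas([-5.0, 5.0, 0.0])
        spec = DEFAULT_OUTCOME_SPECS["BFP"]
        binary = classify(t, spec, te_source="fixed", fixed_cutoffs=4.0)
        assert list(binary.labels["label"]) == [RESPONDER, NON_RESPONDER, NON_RESPONDER]
        ternary = classify(
            t, spec, te_source="fixed", fixed_cutoffs=4.0, adverse_class=True
        )
        assert list(ternary.labels["label"]) == [RESPONDER, "ARs", NON_RESPONDER]

    def test_cutoff_is_twice_te(self):
        t = cohort_from_deltas([-6.0, -1.0, 0.0, 2.0, 5.0])
        res = classify(t, DEFAULT_OUTCOME_SPECS["BFP"])
        te, cut = res.cutoffs["all"]
        assert te == pytest.approx(typical_error([-6, -1, 0, 2, 5]))
        assert cut == pytest.approx(2 * te)

    def test_sex_stratified_cutoffs_differ(self):
        vals = [-8.0, -1.0, 1.0, -3.0, -0.5, 0.5]
        sexes = ["male"] * 3 + ["female"] * 3
        res = classify(
            cohort_from_deltas(vals, sexes=sexes),
            DEFAULT_OUTCOME_SPECS["BFP"],
            strata="sex",
        )
        assert set(res.cutoffs) == {"male", "female"}
        assert res.cutoffs["male"][1] != pytest.approx(res.cutoffs["female"][1])

    def test_small_stratum_rejected(self):
        res = cohort_from_deltas([1.0, 2.0, 3.0], sexes=["male", "male", "female"])
        with pytest.raises(ValueError, match="female"):
            classify(res, DEFAULT_OUTCOME_SPECS["BFP"], strata="sex")

    def test_every_subject_labelled_once(self):
        t = simulate_cohort(default_params(seed=8))
        res = classify(t, DEFAULT_OUTCOME_SPECS["BFP"], strata="sex")
        assert len(res.labels) == len(t)
        assert set(res.labels["label"]) <= {RESPONDER, NON_RESPONDER}

    @given(
        st.lists(
            st.floats(-20, 20, allow_nan=False, width=32), min_size=3, max_size=12
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_direction_equivariance(self, vals):
        """Negating all deltas and flipping benefit direction gives the
        identical labelling."""
        dec = OutcomeSpec("BFP", "%", "decrease")
        inc = OutcomeSpec("BFP", "%", "increase")
        a = classify(cohort_from_deltas(np.array(vals)), dec)
        b = classify(cohort_from_deltas(-np.array(vals)), inc)
        assert list(a.labels["label"]) == list(b.labels["label"])

    @given(
        st.lists(
            st.floats(-20, 20, allow_nan=False, width=32), min_size=3, max_size=12
        ),
        st.floats(0.1, 50, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_equivariance(self, vals, c):
        spec = DEFAULT_OUTCOME_SPECS["BFP"]
        a = classify(cohort_from_deltas(np.array(vals)), spec)
        b = classify(cohort_from_deltas(c * np.array(vals)), spec)
        assert list(a.labels["label"]) == list(b.labels["label"])
        assert b.cutoffs["all"][1] == pytest.approx(c * a.cutoffs["all"][1], rel=1e-9)


class TestSimulationRecovery:
    def test_noise_free_labels_match_ground_truth(self):
        base = default_params(seed=21)
        outcomes = {
            o: dataclasses.replace(
                base.outcomes[o],
                sd_individual_response=0.0,
                sd_technical=0.0,
                # keep baselines well inside the physiological range so the
                # generator's floors cannot touch any draw
                baseline_mean=30.0 if o == "BFP" else base.outcomes[o].baseline_mean,
                baseline_sd=6.0 if o == "BFP" else base.outcomes[o].baseline_sd,
                baseline_mean_by_sex=None,
            )
            for o in OUTCOMES
        }
        p = dataclasses.replace(base, outcomes=outcomes, response_correlation=np.eye(4))
        t = simulate_cohort(p)
        for o in OUTCOMES:
            res = classify(t, DEFAULT_OUTCOME_SPECS[o])
            got = res.labels.set_index("subject_id")["label"] == RESPONDER
            truth = t.set_index("subject_id")[f"true_responder_{o}"]
            assert got.equals(truth), o

    def test_pure_technical_error_tail_rate(self):
        """Zero true effect, zero individual response: the responder rate is
        the analytic tail P(benefit > 2*TE) = P(Z > sqrt(2)) ~ 0.0786,
        since the cutoff 2*TE sits sqrt(2) observed-change SDs from zero."""
        base = default_params(seed=22, n_male=2500, n_female=2500)
        op = dataclasses.replace(
            base.outcomes["BFP"],
            mu_delta=0.0,
            sd_individual_response=0.0,
            sd_technical=1.5,
            baseline_mean=30.0,
            baseline_sd=6.0,
            baseline_mean_by_sex=None,
        )
        p = dataclasses.replace(
            base,
            outcomes={**base.outcomes, "BFP": op},
            response_correlation=np.eye(4),
        )
        t = simulate_cohort(p)
        res = classify(t, DEFAULT_OUTCOME_SPECS["BFP"])
        rate = (res.labels["label"] == RESPONDER).mean()
        assert rate == pytest.approx(stats.norm.sf(math.sqrt(2)), abs=0.01)
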