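"""Mixed between-within ANOVA, post-hocs, ANCOVA, effect sizes, diagnostics."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from ivret.classify import NON_RESPONDER, RESPONDER
from ivret.cohort import DEFAULT_OUTCOME_SPECS
from ivret.prepost import (
    ancova_post,
    bonferroni_posthoc,
    cohens_d_between,
    cohens_d_within,
    diagnostics,
    group_ttests,
    mixed_anova,
    percent_change,
)

from .conftest import make_cohort, random_two_group

FI = DEFAULT_OUTCOME_SPECS["FI"]


class TestMixedAnova:
    def test_no_differential_change_gives_zero_interaction(self):
        """Both groups shifted by exactly +1: the interaction vanishes even
        though the groups sit at different levels."""
        t, lab = make_cohort(
            {RESPONDER: [10.0, 20.0], NON_RESPONDER: [30.0, 40.0]},
            {RESPONDER: [11.0, 21.0], NON_RESPONDER: [31.0, 41.0]},
        )
        res = mixed_anova(t, lab, FI)
        assert res.effect("interaction")["F"] == 0.0
        assert res.effect("interaction")["p"] == 1.0

    def test_interaction_equals_squared_delta_ttest(self):
        """On 120 random two-group datasets the interaction F equals the
        squared pooled-variance t comparing change scores."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            t, lab = random_two_group(rng)
            res = mixed_anova(t, lab, FI)
            g = lab.label_series
            merged = t.set_index("subject_id")
            d = merged["FI_post"] - merged["FI_pre"]
            tt, _ = stats.ttest_ind(
                d[g == RESPONDER], d[g == NON_RESPONDER], equal_var=True
            )
            assert res.effect("interaction")["F"] == pytest.approx(
                tt**2, rel=1e-8
            )

    def test_all_three_effects_match_pingouin(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            t, lab = random_two_group(rng)
            res = mixed_anova(t, lab, FI)
            long = pd.DataFrame(
                {
                    "subject_id": np.tile(t["subject_id"], 2),
                    "time": np.repeat(["pre", "post"], len(t)),
                    "grp": np.tile(lab.label_series.loc[t["subject_id"]].values, 2),
                    "y": np.concatenate([t["FI_pre"], t["FI_post"]]),
                }
            )
            aov = pg.mixed_anova(
                data=long, dv="y", within="time", subject="subject_id", between="grp"
            )
            F_pg = dict(zip(aov["Source"], aov["F"]))
            assert res.effect("group")["F"] == pytest.approx(F_pg["grp"], rel=1e-9)
            assert res.effect("time")["F"] == pytest.approx(F_pg["time"], rel=1e-9)
            assert res.effect("interaction")["F"] == pytest.approx(
                F_pg["Interaction"], rel=1e-9
            )

    def test_ges_bounded_and_monotone(self):
        """Generalized eta squared lies in [0, 1] and grows along a
        one-parameter family of increasing group-by-time contrasts."""
        base_pre = np.array([40.0, 42.0, 44.0, 46.0])
        ges = []
        for gap in (0.0, 1.0, 2.0, 4.0, 8.0):
            t, lab = make_cohort(
                {RESPONDER: base_pre, NON_RESPONDER: base_pre},
                {
                    RESPONDER: base_pre + np.array([1.0, 2.0, 1.0, 2.0]) + gap,
                    NON_RESPONDER: base_pre + np.array([1.0, 2.0, 1.0, 2.0]),
                },
            )
            g = mixed_anova(t, lab, FI).effect("interaction")["ges"]
            assert 0.0 <= g <= 1.0
            ges.append(g)
        assert all(a < b for a, b in zip(ges, ges[1:]))

    def test_sphericity_trivial_with_two_levels(self):
        t, lab = make_cohort(
            {RESPONDER: [40.0, 44.0, 41.0], NON_RESPONDER: [42.0, 43.0, 45.0]},
            {RESPONDER: [45.0, 46.0, 44.0], NON_RESPONDER: [42.5, 44.0, 45.5]},
        )
        res = mixed_anova(t, lab, FI)
        assert res.epsilon == 1.0

    def test_small_group_rejected(self):
        t, lab = make_cohort(
            {RESPONDER: [40.0], NON_RESPONDER: [42.0, 43.0, 45.0]},
            {RESPONDER: [45.0], NON_RESPONDER: [42.5, 44.0, 45.5]},
        )
        with pytest.raises(ValueError, match="Rs"):
            mixed_anova(t, lab, FI)

    def test_constant_outcome_rejected(self):
        t, lab = make_cohort(
            {RESPONDER: [40.0, 40.0], NON_RESPONDER: [40.0, 40.0]},
            {RESPONDER: [40.0, 40.0], NON_RESPONDER: [40.0, 40.0]},
        )
        with pytest.raises(ValueError, match="constant"):
            mixed_anova(t, lab, FI)


class TestPosthoc:
    def test_bonferroni_adjustment_and_cap(self):
        rng = np.random.default_rng(1)
        t, lab = random_two_group(rng)
        for c in bonferroni_posthoc(t, lab, FI):
            assert c.p_adj == pytest.approx(min(1.0, 4 * c.p_raw))

    def test_identical_groups_between_contrasts_null(self):
        x = np.array([40.0, 42.0, 44.0, 46.0, 48.0])
        y = x + np.array([1.0, -0.5, 2.0, 0.0, 1.5])
        t, lab = make_cohort(
            {RESPONDER: x, NON_RESPONDER: x}, {RESPONDER: y, NON_RESPONDER: y}
        )
        for c in bonferroni_posthoc(t, lab, FI):
            if c.kind == "unpaired":
                assert c.p_adj == pytest.approx(1.0)
                assert abs(c.t) < 1e-10

    def test_family_of_four(self):
        rng = np.random.default_rng(2)
        t, lab = random_two_group(rng)
        contrasts = bonferroni_posthoc(t, lab, FI)
        assert len(contrasts) == 4
        assert sum(c.kind == "paired" for c in contrasts) == 2

    def test_d_ci_brackets_d(self):
        rng = np.random.default_rng(3)
        t, lab = random_two_group(rng)
        for c in bonferroni_posthoc(t, lab, FI):
            lo, hi = c.d_ci
            assert lo < hi


class TestAncova:
    def test_constant_baseline_degenerates_to_ttest(self):
        pre = np.full(5, 40.0)
        post_rs = np.array([45.0, 46.0, 44.0, 47.0, 45.5])
        post_nr = np.array([41.0, 42.0, 40.5, 43.0, 41.5])
        t, lab = make_cohort(
            {RESPONDER: pre, NON_RESPONDER: pre},
            {RESPONDER: post_rs, NON_RESPONDER: post_nr},
        )
        res = ancova_post(t, lab, FI)
        tt, p = stats.ttest_ind(post_rs, post_nr, equal_var=True)
        assert res.F == pytest.approx(tt**2, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_post_equals_baseline_no_group_effect(self):
        pre = np.array([40.0, 42.0, 44.0, 46.0])
        t, lab = make_cohort(
            {RESPONDER: pre, NON_RESPONDER: pre},
            {RESPONDER: pre, NON_RESPONDER: pre},
        )
        res = ancova_post(t, lab, FI)
        assert res.group_effect == pytest.approx(0.0, abs=1e-10)

    def test_known_adjusted_difference(self):
        rng = np.random.default_rng(9)
        pre_rs = rng.normal(44, 4, 6)
        pre_nr = rng.normal(44, 4, 7)
        t, lab = make_cohort(
            {RESPONDER: pre_rs, NON_RESPONDER: pre_nr},
            {RESPONDER: pre_rs + 2.0, NON_RESPONDER: pre_nr + 0.0},
        )
        res = ancova_post(t, lab, FI)
        assert res.group_effect == pytest.approx(2.0, abs=1e-9)
        assert (
            res.adjusted_means[RESPONDER] - res.adjusted_means[NON_RESPONDER]
        ) == pytest.approx(2.0, abs=1e-9)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "mean_pre, mean_delta, printed",
        [
            (22.23, -2.30, 10.34),
            (21.70, 1.51, 6.96),
            (43.64, 3.28, 7.52),
            (44.38, 0.89, 2.01),
            (119.89, -6.58, 5.49),
            (119.04, -5.89, 4.95),
        ],
    )
    def test_percent_change_reproduces_published_rows(
        self, mean_pre, mean_delta, printed
    ):
        # agreement to one unit in the last printed digit: the published
        # values were derived from unrounded raw statistics
        assert percent_change(mean_pre, mean_delta) == pytest.approx(
            printed, abs=0.01
        )

    def test_percent_change_contract(self):
        assert percent_change(37.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @pytest.mark.parametrize(
        "mean_delta, sd_pre, sd_post, printed",
        [(2.30, 7.97, 8.23, 0.28), (1.51, 8.30, 8.49, 0.18)],
    )
    def test_within_d_convention_matches_published(
        self, mean_delta, sd_pre, sd_post, printed
    ):
        assert round(cohens_d_within(mean_delta, sd_pre, sd_post), 2) == printed

    def test_within_d_zero_and_errors(self):
        assert cohens_d_within(0.0, 3.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            cohens_d_within(1.0, 0.0, 3.0)

    def test_between_d_equal_weight_matches_published_post_row(self):
        assert round(cohens_d_between(19.93, 8.23, 23.21, 8.49), 2) == 0.39

    @pytest.mark.parametrize(
        "args, expected",
        [((5.0, 2.0, 5.0, 3.0), 0.0), ((1.0, 1.0, 0.0, 1.0), 1.0)],
    )
    def test_between_d_simple_cases(self, args, expected):
        assert cohens_d_between(*args) == pytest.approx(expected)

    def test_between_d_sample_size_weighting(self):
        d = cohens_d_between(
            10.0, 2.0, 8.0, 4.0, n_1=30, n_2=10, weighting="sample-size"
        )
        pooled = math.sqrt((29 * 4 + 9 * 16) / 38)
        assert d == pytest.approx(2.0 / pooled)
        with pytest.raises(ValueError):
            cohens_d_between(1, 1, 0, 1, weighting="sample-size")


class TestGroupTTests:
    def test_hand_computed_example(self):
        t, lab = make_cohort(
            {RESPONDER: [1.0, 2.0, 3.0], NON_RESPONDER: [4.0, 5.0, 6.0]},
            {RESPONDER: [1.0, 2.0, 3.0], NON_RESPONDER: [4.0, 5.0, 6.0]},
        )
        res = group_ttests(t, lab, ["FI_pre"])
        assert res.loc[0, "t"] == pytest.approx(-3.674, abs=1e-3)
        assert res.loc[0, "df"] == 4

    def test_identical_groups_null(self):
        t, lab = make_cohort(
            {RESPONDER: [1.0, 2.0, 3.0], NON_RESPONDER: [1.0, 2.0, 3.0]},
            {RESPONDER: [1.0, 2.0, 3.0], NON_RESPONDER: [1.0, 2.0, 3.0]},
        )
        res = group_ttests(t, lab, ["FI_pre"])
        assert res.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = {RESPONDER: [1.0, 2.0, 5.0], NON_RESPONDER: [3.0, 7.0, 8.0]}
        t1, lab1 = make_cohort(base, base)
        scaled = {g: [3.0 * v for v in vals] for g, vals in base.items()}
        t2, lab2 = make_cohort(scaled, scaled)
        r1 = group_ttests(t1, lab1, ["FI_pre"])
        r2 = group_ttests(t2, lab2, ["FI_pre"])
        assert r1.loc[0, "t"] == pytest.approx(r2.loc[0, "t"], rel=1e-10)


class TestDiagnostics:
    def test_tiny_cell_skips_shapiro_with_reason(self):
        t, lab = make_cohort(
            {RESPONDER: [40.0, 44.0], NON_RESPONDER: [42.0, 43.0, 45.0]},
            {RESPONDER: [45.0, 46.0], NON_RESPONDER: [42.5, 44.0, 45.5]},
        )
        d = diagnostics(t, lab, FI)
        skipped = d[(d.test == "shapiro_wilk") & (d.note.str.contains("skipped"))]
        assert len(skipped) == 2  # both Rs cells

    def test_levene_calibrated_under_null(self):
        """Equal-variance groups: Levene p-values are uniform (KS distance
        below 0.05 over 500 replicates)."""
        rng = np.random.default_rng(123)
        ps = [
            stats.levene(
                rng.normal(0, 1, 30), rng.normal(0, 1, 30), center="mean"
            ).pvalue
            for _ in range(500)
        ]
        assert stats.kstest(ps, "uniform").statistic < 0.05

    def test_shapiro_flags_lognormal_cells(self):
        """A heavily skewed cell is detected in at least 90% of seeds."""
        rej = 0
        n_rep = 200
        for s in range(n_rep):
            x = np.random.default_rng(s).lognormal(0.0, 1.0, 30)
            if stats.shapiro(x).pvalue < 0.05:
                rej += 1
        assert rej / n_rep >= 0.90

    def test_sphericity_note_present(self):
        t, lab = make_cohort(
            {RESPONDER: [40.0, 44.0, 41.0], NON_RESPONDER: [42.0, 43.0, 45.0]},
            {RESPONDER: [45.0, 46.0, 44.0], NON_RESPONDER: [42.5, 44.0, 45.5]},
        )
        d = diagnostics(t, lab, FI)
        assert (d.test == "mauchly").any()
        note = d.loc[d.test == "mauchly", "note"].iloc[0]
        assert "epsilon = 1" in note
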