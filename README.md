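# ivret — inter-individual variability in response to exercise training

Not everyone who completes the same training programme improves. When a
school class runs a ten-week high-intensity interval training (HIIT)
programme, some adolescents lose body fat and some do not — and a central
question in exercise science is whether the *body-fat responders* are also
the ones whose blood pressure and cardiorespiratory fitness improve.

`ivret` is an analysis package for exactly this kind of pre/post responder
study. It is written for biostatisticians and exercise scientists who want
the whole chain — classification, concordance, inference, moderation,
within-subject correlation — as tested, reusable code, exercisable on a
calibrated synthetic cohort so that no subject-level data are required.

## The statistics at its core

**Responder classification by typical error.** For each outcome the change
scores Δᵢ = postᵢ − preᵢ give the typical error

    TE = SD(Δ) / √2,

an estimate of the measurement noise attached to one occasion. A subject is
a responder (Rs) when their *beneficial* change (−Δ for body fat and blood
pressure, +Δ for fitness) strictly exceeds 2·TE; otherwise a non-responder
(NRs). Cutoffs can be computed per stratum (e.g. per sex) or supplied as
fixed values.

**Pre/post inference.** A 2 (Rs/NRs) × 2 (pre/post) mixed between-within
ANOVA per outcome, with generalized eta squared (ɳ²_G, the repeated-
measures-appropriate effect size), Bonferroni-corrected post-hoc contrasts
(family of 4) with Cohen's d and noncentral-t CIs, a baseline-adjusted
ANCOVA at post, percent changes |mean Δ|/mean pre × 100, and Shapiro–Wilk /
Levene diagnostics. With two within-subject levels sphericity holds by
construction (ε = 1). The interaction F is algebraically t² of the
pooled-variance t-test on change scores — an identity the test suite
verifies against an independent oracle.

**Concordance.** 2×2 cross-tabulations of response categories across
outcomes with Pearson χ², sample odds ratio (a·d)/(b·c) with Wald CI and
optional Haldane correction, Cramér's V, and a long-format flow table (the
Sankey data).

**Baseline moderation.** Per-group OLS of Δ on baseline body fat, and the
classical two-line comparison Δ = β₀ + β₁·BFP + β₂·group + β₃·BFP·group:
the slope test is β₃; the vertical-shift test is β₂ in the parallel-slopes
model.

**Repeated-measures correlation (r_rm).** The common within-subject
association between body fat and each outcome across the two occasions:
one shared slope with subject-specific intercepts, r_rm = Σx̃ỹ/√(Σx̃²Σỹ²)
on within-subject-centred values, df = N − k − 1. Implemented from first
principles and cross-checked against both a brute-force design-matrix
oracle and an independent library implementation.

**Synthetic cohorts.** The generator separates the three variance sources
such analyses must disentangle — a true mean effect per outcome,
between-subject SD of true response (SD_IR, correlated across outcomes),
and technical error per occasion — and emits ground-truth responder status,
so label recovery and error rates can be verified exactly.

## Worked example

The analysis is a sequence of numbered drivers over the library:

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_classify_responders.py
python analysis/03_response_concordance.py
python analysis/04_prepost_inference.py
python analysis/05_baseline_moderation.py
python analysis/06_rmcorr.py
```

Step 01 draws 73 adolescents (31 male, 42 female) from the calibrated
preset and prints, for seed 1:

```
simulated cohort: n = 73 (31 male, 42 female)
  BFP: baseline  20.70 +/-  8.21   change  -5.02 +/-  3.72
  ...
true body-fat responders: 46
```

Step 02 estimates sex-specific cutoffs and labels the cohort
(`BFP: Rs = 39, NRs = 34 (cutoffs: female 4.813, male 5.843)`, with 84.9 %
agreement against the simulated ground truth — the disagreement is exactly
the subjects whose observed change is pushed across the cutoff by
measurement noise). Step 04 then reproduces the study's headline pattern
on the synthetic cohort:

```
 FI: interaction F(1,71) =  17.07, p = 0.0001, ges = 0.032 | time F =  7.97, p = 0.0062
      Rs: delta =  +2.99 +/-  4.09 (6.63%)
     NRs: delta =  -0.72 +/-  3.50 (1.60%)
SBP: interaction F(1,71) =   2.68, p = 0.1058 ...
```

i.e. a significant fitness-index interaction (responders gain fitness,
non-responders do not) alongside a time effect but no interaction for
blood pressure — fat responders and non-responders lower their blood
pressure about equally. Steps 05–06 show the same asymmetry in the
moderation lines (a significant vertical shift for FI only) and in the
within-subject correlations (strongest negative BFP–FI coupling among
responders).

Everything is also available as a CLI (`ivret simulate|measures|classify|
flow|prepost|moderation|rmcorr|run`) and as a config-driven pipeline
(`ivret run config.yaml`) that writes a fully provenance-stamped,
byte-reproducible report bundle.

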