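# Methods

This note documents the statistical model behind `ivret`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish about real data.

## Responder classification

The typical error TE = SD(Δ)/√2 (sample SD, n−1 denominator) treats the
pre-to-post change scores as carrying two independent copies of the
per-occasion measurement noise, so SD(Δ) = √2·σ_tech when no true
individual variability exists. A subject is a responder when the
beneficial change strictly exceeds 2·TE; a tie at the cutoff is a
non-responder ("greater than two-fold" is read strictly). Benefit
directions are declared explicitly per outcome (decrease for body fat and
both blood pressures, increase for the fitness index) and never inferred.

Which deltas feed SD(Δ) is configurable (`te_source`). The default is the
analysed subjects of each stratum (sex-specific cutoffs from the studied
sample). This confounds technical error with true individual response —
when SD_IR > 0 the estimated TE exceeds the technical noise and the cutoff
is conservative. A control-group- or literature-derived cutoff can be
supplied via `te_source="fixed"`; a genuinely noise-only TE is not
estimable from a single intervention arm, which is a known limitation of
this family of designs, not of the implementation.

Consequences the test suite verifies exactly:

* with all noise off, labels equal ground truth;
* under pure technical error and zero mean effect, the responder rate is
  the analytic tail P(Z > 2·TE/SD(Δ)) = P(Z > √2) ≈ 0.0786 — the
  false-discovery floor any user of the 2·TE rule should expect.

## Mixed between-within ANOVA

For the 2×2 design the decomposition is computed in closed form from
per-subject means and change scores (weighted group means, so unbalanced
groups are handled exactly); the three F statistics agree with
`pingouin.mixed_anova` to machine precision and the interaction F equals
the squared pooled-variance t on change scores by algebra. Effect sizes
are generalized eta squared, SS_effect/(SS_effect + SS_error_between +
SS_error_within), the convention that is comparable across between-,
within- and mixed designs. With two within-subject levels sphericity holds
identically (Greenhouse–Geisser ε = 1); the machinery therefore
short-circuits rather than estimating ε. Degenerate inputs: fully constant
data raise; a zero effect over zero error reports F = 0, p = 1; a non-zero
effect over zero error reports F = ∞, p = 0.

Post-hoc family: the four displayed contrasts (pre vs post within each
group, paired; Rs vs NRs at pre and at post, unpaired Student), Bonferroni
adjusted with m = 4, p_adj = min(1, 4·p_raw).

Effect-size conventions, deliberately fixed:

* **within-group d** = |mean Δ| / √((SD_pre² + SD_post²)/2). The
  alternative mean Δ/SD_Δ is a different quantity (larger whenever pre and
  post correlate strongly) and is recoverable from the reported t and n;
  the pooled-pre/post convention is the default because it is the one that
  reproduces published within-group values from summary rows.
* **between-group d** = |mean₁ − mean₂| / √((SD₁² + SD₂²)/2) by default
  (equal weighting); sample-size weighting by flag.
* d confidence intervals invert the noncentral-t distribution for the
  noncentrality parameter; a normal-approximation fallback is available.

The change-score comparison between response categories is an
independent-samples test (Student by default, Welch by flag): the
categories are disjoint groups of different sizes, so a paired test is not
defined for them.

The ANCOVA at post fits post ~ group + baseline by OLS and reports the
group coefficient with adjusted means at the grand baseline mean. A
globally constant baseline is dropped (the model degenerates to the
unadjusted t-test); a baseline constant within each group but different
between them is perfect confounding and raises.

## Two-line comparison (baseline moderation)

Pooled model Δ = β₀ + β₁·BFP + β₂·group + β₃·BFP·group, with the
non-responders as the reference level so β₂ > 0 means the responder line
sits above. Testing is hierarchical: the interaction β₃ ("test for
slopes") is read from the full model; the vertical shift ("test for
intercepts") from the parallel-slopes model, because a single intercept
difference is only defined when the lines are parallel — this is the
framing under which "no interaction, but a significant shift" is a
coherent conclusion. β₂ from the joint model is also reported, off the
default testing path. The parallel-slopes shift is invariant to centring
the predictor; the joint-model coefficient is not.

## Repeated-measures correlation

r_rm is computed from within-subject-centred values, which is exactly the
ANCOVA with subject intercepts and a common slope: r_rm =
Σx̃ỹ/√(Σx̃²·Σỹ²), df = N_obs − k − 1 (= k − 1 for two occasions), p from
the two-sided t distribution. For two occasions this reduces to the
through-origin correlation of change scores — an identity the tests verify
numerically along with agreement (1e−10) with a brute-force
subject-indicator least-squares oracle and with `pingouin.rm_corr`. The
implementation is generic in the number of occasions, but the supported
and tested surface is two; random-slope multilevel models are out of
scope. Body fat is conventionally the x variable; the magnitude of r_rm is
symmetric in orientation, which only affects the plotted fit lines.

## Synthetic cohort generator

Per subject: observed pre = b + e₁ and post = b + δ + e₂, with baseline
b ~ N(μ_b, σ_b²) (sex-specific means where configured), true response
δ ~ N(μ_δ, SD_IR²) correlated across outcomes through a user-supplied
positive-semidefinite matrix, and technical errors e₁, e₂ drawn
independently per occasion — so SD(Δ|no IR) = σ_tech·√2, matching the TE
definition downstream. Baseline and response are independent by default
("no baseline moderation" is the simulator's null); an optional
baseline–response correlation exists because the moderation analysis
probes exactly that dependence (when used, cross-outcome correlations
attenuate by √(1−ρ²), documented behaviour). All draws flow from a single
`numpy` generator seeded once; equal seeds give byte-identical CSVs. The
model is plain Gaussian without truncation, so additive contracts hold
exactly for every subject; physiologically implausible extremes are
possible in principle and vanishingly rare at the defaults.

### Default calibration (the study conditions)

73 adolescents (31 male, 42 female), age 16.1 ± 0.4 y; height/weight by
sex 176.7 ± 6.1 cm / 65.4 ± 12.5 kg (male) and 164.4 ± 6.5 cm /
56.7 ± 10.2 kg (female). Outcome parameters (units: % for BFP, mmHg for
pressures, score points for FI):

| outcome | baseline mean ± SD | μ_δ | SD_IR | σ_tech |
|---|---|---|---|---|
| BFP | 15.5 (M) / 26.8 (F) ± 5.9 | −0.7 | 2.9 | 1.0 |
| SBP | 119.5 ± 11.1 | −6.2 | 5.5 | 4.5 |
| DBP | 73.1 ± 7.5 | −2.4 | 5.0 | 4.5 |
| FI | 44.0 ± 4.4 | +2.3 | 3.3 | 1.3 |

Baselines and mean effects follow the published pooled summaries; the
within-sex body-fat SD of 5.9 is the pooled SD near 8 with the
between-sex mean gap removed. The split of each observed-change SD into
SD_IR and σ_tech is an instrument-reliability judgement: bioimpedance
body-fat analysers and automated BP monitors have small-to-moderate
per-occasion error, while the step test is the noisiest instrument
relative to its between-subject spread. True responses are correlated
across outcomes (fat loss with fitness gain −0.50, with SBP/DBP reduction
+0.30/+0.20, pressures mutually +0.50); the matrix is checked for
symmetry, unit diagonal and positive semidefiniteness.

`table_calibrated_params` adds a responder-fraction override of 0.59: the
study does not print its group sizes, but the half-widths of its printed
95% CIs for the change scores imply roughly 43 responders vs 30
non-responders. The override re-targets the mean body-fat benefit to
s·(√2 − z_{1−f}) so the expected fraction of observed benefits above the
theoretical cutoff equals f. Under this preset the simulated
between-category fitness-change gap lands on the published group means
(≈ +3.3 vs +1.0). The published group-wise body-fat changes themselves
(−2.30 vs +1.51) are *not* jointly reproducible with the published
cutoffs under any truncated-Gaussian model — a responder group selected by
"benefit > 3.2" cannot average a benefit of 2.3 — so the preset
prioritises the responder split and the fitness coupling and lets the
body-fat group means fall where the selection model puts them.

### What the synthetic cohorts do not show

The generator draws Gaussian baselines and responses with no
regression-to-the-mean coupling, no growth or maturation over the
intervention window, no dropout or missingness, and no floor/ceiling
behaviour in the instruments. Passing tests therefore demonstrate that the
*procedures* are correct and calibrated under a known generative model —
they do not validate the 2·TE criterion's behaviour under skewed
responses, correlated errors, or maturation trends in real adolescents.

## Problem sizes and numerical choices

Monte-Carlo checks use sizes chosen to put the quantity under test well
inside its asymptotic regime while keeping each check to seconds: 200
seeds for moment matching, n = 4000–5000 for tail probabilities and
correlation recovery (tolerances 0.01 and 0.05), 500 cohorts of 73 for the
type-I calibration of the interaction test (±3 binomial SEs around 5%),
and 200 cohorts for the power-style check that the calibrated preset
detects the fitness interaction in the majority of runs. Oracle
equivalences are asserted at rel. 1e−8 (ANOVA vs t²) and abs. 1e−10
(rmcorr vs least-squares oracle); the chi-squared statistic is checked
exhaustively against the direct Σ(O−E)²/E sum for all 2×2 tables with
cells ≤ 8 plus a seeded sample with cells ≤ 20. Correlation matrices are
factored by eigendecomposition (tolerating semidefinite inputs, eigenvalue
floor −1e−10); heart-rate rounding is half-away-from-zero and applied only
at presentation; the step-test duration domain accepts the full 300 s
(excluding subjects who complete the test would be nonsensical even though
the classical formula is quoted for L < 300).

## Known limitations

* Two groups × two time points is the supported inference surface; the
  ANOVA core is closed-form for this design and does not generalise.
* The TE reference sample confound described above: within-sample cutoffs
  overestimate pure technical error whenever true individual variability
  exists.
* Labels are binary Rs/NRs by default (an adverse-responder third class is
  available behind a flag); Bayesian (ROPE + HDI) classification is out of
  scope.
* Fisher's exact test is offered as a small-cell fallback but the default
  chi-squared path only warns (expected counts < 5), mirroring common
  practice in this literature.
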