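# Methods

## The familial loading score

The FLS treats a participant's family history as evidence in a two-hypothesis
comparison.  Under H1 ("the participant is at familial risk") every
first-degree relative carries lifetime prevalence *a*; under H0 they carry
*b*.  With first onsets uniform over the age window [*d*, *c*], the
probability that a relative is affected by age *x* is *p·u(x)* with
*u(x) = clip((x − d)/(c − d), 0, 1)*, giving per-relative likelihood ratios

* affected: (a·u)/(b·u) = a/b — the window factor cancels, so an affected
  relative contributes the same evidence at any age inside the window;
* unaffected: (1 − a·u)/(1 − b·u) — equal to 1 before the window opens and
  decreasing to (1 − a)/(1 − b) once it closes.

The score is the common logarithm of the product over relatives, computed as
a sum of logs (the raw product under- or overflows for no practical family
size here, but the log-sum form is exact, additive and numerically safe).
The affected-relative LR being age-free is a property of the uniform-onset
construction, not an extra assumption: all age adjustment acts through
unaffected relatives.  Both LR functions are isolated so a different onset
algebra is a two-function change.

Degenerate and edge inputs: ages are clamped to the window (ages above *c*
contribute the u = 1 value); negative or implausible ages (> 120 y) are
rejected; an *affected* relative recorded at age ≤ *d* is internally
inconsistent data and yields a/b with a warning; an empty family scores 0 and
is FH− with a warning.  Parameters are validated at construction
(0 < b < a < 1, 0 ≤ d < c), since b ≥ a silently inverts every LR direction.

### Parameters

| name | meaning | default | unit |
|------|---------|---------|------|
| a | lifetime prevalence of depression/anxiety given FH+ | 0.50 | probability |
| b | lifetime prevalence given FH− (half the 26.8% Dutch population lifetime prevalence) | 0.134 | probability |
| c | upper limit of the first-onset risk window | 65 | years |
| d | lower limit of the first-onset risk window | 5 | years |

b is a fixed constant, not auto-derived: a user supplying a different
population prevalence must decide explicitly whether to halve it, because the
halving convention is itself an assumption of the original algorithm.

### Affected-relative rule and data model

A relative is affected iff the informant endorsed (i) at least one
symptom-type question (episodes, core symptoms, restrictions) and (ii) at
least one treatment-type question (treatment, hospital/psychiatric-ward
admission).  The data model accepts the two pre-aggregated booleans or an
explicit `affected` override; an override that contradicts the flags is an
error, as is an unresolved status.  Only parents and siblings are modelled
(first-degree, the scope of the family interview).  For deceased relatives
the observation age is the age at death — the standard censoring choice; the
source instrument is silent on this, and current-age-at-interview would
overstate the evidence of unaffected deceased relatives.  Missing relative
age is a hard error (the motivating study excluded rather than imputed).

## Synthetic cohort generator

The generator's only contract is statistical: it produces cohorts with the
structure the analysis assumes, not realistic genetics.

* **Liability.**  Family shared factor F ~ N(0,1); member liability
  = `familial_effect`·F + N(0,1).  Threshold τ = √(1+f²)·Φ⁻¹(1−K) gives
  marginal lifetime risk K (0.268) in closed form.
* **Expression.**  Lifetime-affected members draw an onset age, uniform on
  [d, c] by default — deliberately the law the score assumes, so score
  behaviour is testable under its own model (`onset_law="beta"` provides a
  mid-window-peaked alternative for robustness checks) — and are symptomatic
  only once onset ≤ observation age.
* **Observed affection.**  A symptomatic relative meets the strict treatment
  criterion with probability `treatment_prob` (default 0.60, reflecting
  under-treatment); only then do they satisfy the two-criterion affected
  rule.  Untreated symptomatic relatives endorse symptoms only; a further
  20% / 5% of non-symptomatic relatives endorse symptoms-only /
  treatment-only, exercising the conjunction rule without ever contradicting
  it.
* **Ascertainment.**  Probands are rejection-sampled until lifetime-affected;
  accepted families are thereby enriched for high shared factors.
* **Demographics.**  Proband ages uniform on [26, 75]; gender
  Bernoulli(0.666 female); education N(13, 3²) truncated to [5, 22] years.
  Parents are 28 ± 5 years older than the proband (≥ 16, ≤ 98); siblings
  differ by 0 ± 6 years.
* **Family size.**  2 parents plus a hurdle sibling count: no siblings with
  probability 0.08, otherwise zero-truncated Poisson(1.1) — jointly matching
  a mean sibling count near 1.5 *and* an 8% no-sibling share, which no plain
  Poisson does.
* **Outcomes.**  Each outcome is linear in a standardized exposure (the
  realised FLS by default; optionally the latent liability) plus small
  age/gender/education effects (0.10, 0.05, −0.05) plus Gaussian noise scaled
  to unit total variance, so the specified standardized coefficient is
  exactly the estimand of the covariate-adjusted regression.  Defining the
  planted effect on the realised score rather than the latent liability is a
  deliberate choice: it makes parameter recovery a sharp test of the fitting
  pipeline (an effect planted on liability would be attenuated by the
  score–liability correlation, turning every recovery test into a joint test
  of the generator's clustering strength).  The default outcome set carries
  the small standardized effects reported for the motivating clinical cohort
  (|β| between 0.07 and 0.13).
* **Polygenic-score stand-in.**  r·z(liability) + √(1−r²)·noise with
  r = 0.07; no genotypes, no ancestry structure.

### Calibration

`familial_effect = 1.0` together with `treatment_prob = 0.60` was tuned so
the *emergent* FH+ fraction (never forced) lands near the 59.8% observed in
the motivating cohort: with uniform onsets and K = 0.268 the FH+ share is
≈ 0.60 even without clustering, and clustering alone would push it to ≈ 0.73;
the strictness of the two-criterion rule (under-treatment of affected
relatives) is what brings it back down, which is also the clinically
plausible mechanism.  At these defaults, measured over 10 seeds at n = 1425:
FH+ ≈ 0.595, corr(FLS, latent liability) ≈ 0.22.  At `treatment_prob = 1`
and `familial_effect ≈ 1.0–1.15` the relatives' conditional lifetime risk in
ascertained families reaches ≈ 0.50–0.53 (the a parameter) and
corr(FLS, liability) exceeds 0.3.

### What the generator does not emulate

Assortative mating, differential parent/sibling correlations (one shared
factor serves both), age- and gender-dependent prevalence, recall error in
informant reports, multi-generational pedigrees, and real polygenic signal.
Passing tests therefore demonstrate correctness of the scoring and inference
machinery under the stated model, not validity of the score on real family
data.

## Association pipeline

For every outcome, three OLS models adjusted for age, gender and years of
education: exposure = FLS, exposure = FH, exposure = FLS residualized on FH
(the component of continuous loading orthogonal to the dichotomy; residuals
are exactly orthogonal to FH by the normal equations, and downstream
coefficients are invariant to constant shifts of the FLS).  Unstandardized b
with 95% CI; standardized β by the full-standardization convention
(β = b·sd(x)/sd(y), identical to refitting with every variable z-scored,
binary included — the convention of the SPSS lineage of this analysis); a
partially-standardized alternative is available.  Two-sided p-values; the
pooled-variance Student t is used for group comparisons so that df = N − 2;
2×2 chi-square tests are Pearson *without* continuity correction; complete
cases per model with n reported per row.

Benjamini–Hochberg step-up control at q = 0.05.  The multiple-testing family
defaults to one family per exposure block across outcomes, with a pooled
("global") option — the family composition is genuinely a reporting choice,
so both are implemented and the choice is a config key.  Adjusted p-values
are provided but raw p-values are preserved in all outputs.

Wave-level repeated measures are averaged over available (non-missing) waves
before modelling; all-missing propagates.

## Problem sizes and numerical choices

The parameter-recovery suite runs 200 replicate cohorts at n = 1425 (the
motivating sample size); the global-null FDR suite runs 500 replicates of 20
null outcomes at n = 400, since BH calibration does not depend on sample
size.  Monte-Carlo assertions use 2–3 standard-error bands.  FLS values are
reported to 4 decimals in output tables (full precision internally); other
floats to 6 significant digits.  Score equality tolerances: additivity
1e−12, product-oracle equivalence 1e−10, FH-orthogonality of residuals
1e−10.

## Known limitations

The score inherits the uniform-onset and fixed-prevalence assumptions; a/b
being age-free means an affected 10-year-old sibling and an affected
70-year-old parent contribute identically, which a hazard-based variant
would distinguish.  The generator's FH+ calibration is specific to its
default age structure.  No mixed models or longitudinal trajectories; the
pipeline is cross-sectional by design.
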