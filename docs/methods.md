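# Methods

This note documents the models, defaults and numerical choices behind
`topicscep`, and what the synthetic-cohort tests do and do not establish
about real data.

## Composite endpoint scoring

The composite condenses eight domains into a 0–10 index. The raw score is a
fixed linear form — intercept 9.00 minus preference-weighted components
(weights 0.18, 0.12, 0.03, 0.03, 0.14, 0.01, 0.17, 0.02 for morbidities,
functional limitations, emotional wellbeing, pain, cognition, social
functioning, self-perceived health and self-perceived quality of life) — and
the index is the affine map of the raw score onto [0, 10] using the minimum
raw score and raw range implied by the component maxima. Because all weights
are positive, the index is strictly decreasing in every component
(worsening any domain lowers the score), and the anchors are exact: an
all-best record scores 10, an all-worst record 0.

**Coding scheme.** The per-item native ranges and reverse-coding directions
are instrument conventions, not part of the composite's definition, so they
live in a versioned, YAML-overridable `CodingScheme`. The shipped defaults
give component maxima 17 / 15 / 25 / 2 / 2 / 4 / 4 / 4, hence
`raw_min = 2.25` and `raw_range = 6.75`. The five emotional-wellbeing items
are taken on their native 6-point frequency scale (0–5 after orientation,
component maximum 25); if a deployment rescales them differently, the
derived quantities follow the overridden scheme automatically — they are
computed, never hard-coded.

**Missing data.** Multi-item components with tolerably few missing items
(fewer than 5 of 17 morbidities, fewer than 5 of 15 functional items, fewer
than 2 of 5 emotional items) are pro-rated:
`answered_sum / n_answered × n_items`. Pro-rating is the identity on
complete components and scale-equivariant. No rounding is applied to
pro-rated morbidity counts — fractional counts are retained. A respondent
exceeding any tolerance, or missing any single-item domain, is not scoreable
and is excluded from all downstream analyses (complete-case behaviour); the
pipeline log reconciles these exclusions against input row counts.

## EQ-5D utilities

Utilities use the published Dutch EQ-5D-3L value set: constant 0.071 for any
departure from full health; level-2/level-3 decrements 0.036/0.161
(mobility), 0.082/0.152 (self-care), 0.032/0.057 (usual activities),
0.086/0.329 (pain/discomfort), 0.124/0.325 (anxiety/depression); extra
0.234 once any dimension is at level 3. State 11111 is exactly 1.00 and the
worst state 33333 is 1 − 1.329 = −0.329, i.e. −0.33 at the two-decimal
reporting convention. Full precision is kept internally; rounding happens
only at the reporting layer (and when testing ceiling/floor membership,
which uses two decimals for the utility).

## Synthetic multi-project cohorts

The generator emulates the structure the validation machinery assumes, with
defaults calibrated to a pooled national dataset of older persons: 28
projects totalling 17,603 respondents with a skewed (lognormal-weight) size
distribution; age ~ Normal(79, 7²) (rounded, floored at 65); prevalences
61.5% women, 5.6% dementia, 9.1% depression, 14.6% dizziness with falls;
marital status, living arrangement and education as categorical draws;
project intercept SD 0.5 points; composite grand mean 7.37 with residual SD
1.1; ladder mean 7.12 (SD 1.40); utility mean 0.63 (SD 0.29); within-project
outcome correlations 0.43 (composite–ladder), 0.63 (composite–EQ-5D), 0.34
(ladder–EQ-5D); default group effects equal to the unadjusted contrasts used
throughout the tests (e.g. depression −1.16, dementia −1.13, female −0.39,
+0.03 per year of age).

**Correlation construction.** A naive design that adds covariate effects to
the composite only would attenuate the observed outcome correlations
whenever group effects are active. Instead, the standardized systematic
part of the composite (covariate effects, with its theoretical mean and
variance computed from the configured prevalences) is embedded as one part
of the first coordinate of a trivariate standard normal; the second and
third coordinates are drawn from their conditional distribution given the
first. Consequences, verified by tests: within-project correlations equal
the configured targets in expectation even with nonzero group effects;
configured contrasts are preserved exactly on the composite (and propagate
realistically to the other two outcomes); and for a fit of the composite on
a configured factor the residual SD is the configured one when no other
effects are active.

**Outcome scales.** Outcome-level mode emits continuous scores by default so
the generating moments and correlations are exact — that is the mode the
statistical machinery is tested on. `discretize=True` produces reported
scales (composite clipped to [0, 10], integer ladder, utility rounded to
two decimals and capped at 1.00), which introduces the ceiling mass real
utilities show; the shell pipeline uses this flavour in outcome mode.

**Item-level mode** drives each of the 42 items (and the five EQ-5D
dimensions) from the respondent's latent via a one-factor graded-threshold
model: item latent = −0.7 × wellbeing + noise, cut at fixed normal quantiles
chosen to give realistic marginal level distributions for an older
population (e.g. 25% per morbidity, 30% per functional limitation). The 0.7
loading corresponds to item-total correlations typical of well-constructed
health-status scales and yields a rank correlation above 0.9 between latent
wellbeing and the scored composite. Items are then masked completely at
random (default 2% per item, giving ≈ 90% scoreable respondents).

What the generator does *not* emulate: real projects' sampling frames,
informative (non-MCAR) missingness, differential item functioning between
settings, true between-project heterogeneity in the outcome correlations
(tau² is 0 by construction unless project-varying configs are composed), and
the empirical per-project size distribution, which is unpublished. Passing
recovery tests therefore show the estimators are correct under the stated
model, not that the model captures every feature of field data.

## Meta-correlation

Per-project Pearson correlations use pairwise-complete deletion; projects
with fewer than 4 complete pairs or zero variance in either outcome are
excluded with a logged warning (the Fisher variance `1/(n−3)` requires
n > 3). Pooling is Fisher-z + DerSimonian–Laird — the standard
moment-estimator pair for meta-analysis of correlations — with
inverse-variance weights `1/(1/(n−3) + tau²)` and a Wald 95% CI
back-transformed by tanh. The estimator functions are small and pure, so an
alternative tau² estimator (REML, Paule–Mandel) can be swapped in by
replacing `pool_random_effects`; none is bundled. Correctness is pinned two
independent ways: a spreadsheet-style hand oracle (plain `math` arithmetic)
to 1e−12, and R's `metafor` (`escalc(measure="ZCOR")` + `rma(method="DL")`)
to 1e−9 on a fixture. Strength bands treat the boundaries 0.3 and 0.5 as
moderate, reading "between 0.3 and 0.5" inclusively, and classify on |r|.

## Known-group models

One model per characteristic (not one joint model): indexed score on the
factor's treatment-coded dummies, plus optional adjusters, with a random
intercept per project, fitted by REML via `statsmodels` MixedLM with Wald
95% CIs — the common default of mainstream mixed-model tooling. Age is
centered at the analysis-sample mean so the intercept stays interpretable
as the reference-group mean at average age. With a single project, or when
the mixed fit is singular or non-convergent, the fit downgrades to OLS with
a logged warning rather than failing. The change-in-estimate statistic is
`|unadjusted − adjusted| / |unadjusted| × 100` with the absolute unadjusted
estimate as denominator; it is flagged when strictly above 15% (a 1e−9
epsilon guards the boundary against float noise) and reported as undefined
(and flagged for review) when the unadjusted estimate is exactly 0. No
multiple-testing correction is applied across characteristics.

## Floor/ceiling

Counts are taken against the *theoretical* instrument bounds (0/10 for the
two 0–10 scales; −0.33/1.00 for the utility, compared after two-decimal
rounding), over non-missing scores, and flagged strictly above 15%.

## Problem sizes and tolerances

Recovery runs use 28 projects × 500 respondents for correlations (pooled-r
Monte-Carlo SE ≈ 0.005, checked within ±0.03) and 28 × 357 ≈ 10,000 for the
mixed-model contrast (SE ≈ 0.04, checked within ±0.08). CI-coverage checks
run 100 replicates at 28 × 120 — coverage probability does not depend on
per-replicate n, so the smaller cohorts just make the replicate loop cheap.
The unbiasedness test for pooled correlations runs 200 replicates at the
full default cohort; its bound allows the O(1/n) Fisher-transformation bias
on top of Monte-Carlo noise. All randomness flows through explicitly seeded
`numpy` generators (one per dataset; item-level draws use a spawned
sub-stream), so every dataset, test and pipeline run is byte-reproducible
given its seed.

## Known limitations

- The exact native codings of some items (notably whether the emotional
  subscale is used on its 6-point scale) vary between deployments; the
  defaults are declared, documented and overridable rather than asserted as
  universal.
- Reported subgroup sizes in published validation work can disagree between
  tables (one source lists a general-population subgroup as N = 3,331 in
  its descriptive table but N = 2,221 in its correlation table); such
  discrepancies are a property of the source material and cannot be
  resolved by this package.
- Longitudinal properties (responsiveness, minimal clinically important
  difference) are out of scope.
- The mixed models assume Gaussian residuals and a single variance
  component; the generator satisfies both, real data need not.
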