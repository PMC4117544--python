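# Methods

## Data model and the bundled study

A sample is one 1-L water grab with design coordinates (pond, day, section
1–3, transect 1–9, water-column position) plus two covariates (fish density
in fish/m³, water temperature in °C) and a binary qPCR detection outcome.
Tables are validated on construction: positions must be
surface/middle/bottom, detections 0/1, densities non-negative, and transect
t must lie in section ⌈t/3⌉.

`builtin_pond_study()` reconstructs the four-pond mesocosm experiment from
its published pond-day-position detection counts. Two reconstruction
choices matter:

- **Which samples in a 9-sample cell are detections is unrecorded.**
  Detections are assigned deterministically to the lowest transect indices.
  For any model without section/transect random intercepts the likelihood
  depends on the data only through the per-cell counts, so this choice is
  inferentially neutral for all the fixed-effects analyses (including the
  best-supported model); random-intercept fits on the reconstruction are
  approximate in exactly this respect.
- **Per-stratum temperatures were never published.** The pond-day mean
  temperature is applied to all 27 samples of a pond-day. The original
  study standardized temperature with an SD of 1.02 °C derived from its
  per-stratum readings; from pond-day means alone the SD is 1.09 °C. The
  package therefore keeps 1.02 as an explicit constant
  (`study_standardization()`), with the mean taken over the nine stocked
  pond-day values (29.60 °C).

Density is standardized over the distinct stocked pond densities
{0.32, 1.75, 5.24}, giving the study's SD of 2.53 fish/m³ (n−1
denominator). Day, when used, enters unstandardized so its coefficient is a
per-day log-odds change.

## Likelihood, priors, sampling

The likelihood is Bernoulli at inverse-logit of the linear predictor plus
optional section/transect random intercepts; random-effect groups are
(pond, section) and (pond, transect) pairs, so physical locations are not
shared across ponds. Defaults:

- fixed effects: Normal(0, sd 10) on the logit scale (a `logistic` family
  is available; Logistic(0, 1) on the intercept makes p uniform on (0, 1),
  which the tests use as a conjugate Beta–binomial oracle);
- random-intercept SDs: Uniform(0, 10), with a half-normal alternative;
- random intercepts: Normal(0, σ) given their SD.

The sampler is componentwise random-walk Metropolis. Per-coordinate step
sizes adapt during burn-in only (batch-of-50 adjustment targeting 0.44
acceptance, diminishing step ~ batch⁻¹ᐟ²) and are frozen afterwards, so the
retained draws come from a fixed Markov kernel. Random-effect SDs are
sampled as log σ with the Jacobian term and stored on the natural scale.
Likelihood evaluations update the cached linear predictor incrementally
(one column, or one group's rows, per proposal), and inverse-logit terms
use `logaddexp`, so extreme coefficients (for example an intercept of −50)
stay finite. Chains start over-dispersed — fixed effects Normal(0, 2) per
chain with chain-indexed sub-seeds — which makes the Gelman–Rubin PSRF
(classic between/within form; flag at 1.1) meaningful. Defaults are 3
chains × 200,000 iterations with 50,000 burn-in; `TEST_PROFILE`
(20,000/5,000) is the desk-scale profile used by the test suite, whose
MCMC-vs-quadrature oracle and PSRF checks pass at that length.

Per-draw deviance D = −2 × Bernoulli log-likelihood (conditional on random
intercepts, priors excluded) is stored with every draw. DIC uses
pD = D̄ − D(θ̄) with θ̄ the posterior mean of every sampled quantity,
including random intercepts. DIC weights normalize exp(−ΔDIC/2) over
whatever model set the caller supplies; `confidence_set` keeps models with
weight ≥ 10% of the best and also reports weights renormalized within the
retained set, since published confidence-set weights are normalized that
way. Plausibility ratios follow the reporting convention of rounding
weights to 2 decimals before forming ratios (the unrounded variant,
exactly exp(ΔDIC/2), is available); reported values are rounded half-up.

## Posterior-predictive checks

`bayesian_p_value` simulates a replicate dataset at each retained draw
(evenly thinned to ≤ 5,000, keeping Monte-Carlo error below ~0.01) and
compares a discrepancy T between observed and replicate data. Three
measures are exposed:

- `pearson_chisq` (default): Σ (y − p)² / (p(1 − p)) over observations;
- `deviance`: −2 Σ [y log p + (1 − y) log(1 − p)];
- `pearson_cells`: Pearson chi-square on pond-day-position cell counts.

For binary data the observation-level chi-square depends on the data only
through the total detection count, so it is calibrated but nearly powerless
against covariate misspecification; the cell-grouped variant is the one
with power, and it is what the misfit tests use. All three are non-extreme
for the global model on the bundled data.

## False positives

With 0 detections in 81 control samples the likelihood only bounds the
false-positive probability from above, so the intercept-only posterior is
prior-dominated: the per-sample probability (posterior mean of
inverse-logit(β₀), not inverse-logit of the mean) falls from ~0.015 under a
prior SD of 2 to ~0.001 under the default SD of 10. `prior_sensitivity` is
therefore a mandatory companion output in the zero-detection case, and the
projection to N stocked-pond samples reports the expected count N·E[p]
together with both the central 95% interval and the min–max of the
posterior-predictive Binomial(N, p) counts ("range" is otherwise
ill-defined).

## Survey design

Per-sample probabilities are plug-in values at supplied coefficients
(posterior means give smooth curves); `posterior_mean_probability` averages
inverse-logit over draws instead, which is larger in the probability tails.
Cumulative detection is 1 − (1 − p)ⁿ and `samples_required` is
⌈log(1 − target)/log(1 − p)⌉ with the boundary re-checked explicitly so
floating-point rounding cannot shift n by one. Design curves default to the
surface position (the baseline and best-detecting stratum).

## Synthetic data

`simulate_study` emulates the stratified design (ponds × days × 9 transects
× 3 positions, one sample per transect-position) with Bernoulli draws from
the same logistic model the fitters assume. Standardization constants live
in `TrueParams` so generator and fitter share one covariate scale. A single
seeded generator draws, in documented order, section intercepts, transect
intercepts (σ × standard normal, so σ = 0 reproduces the fixed-effects
stream exactly), then one uniform per sample; runs are bit-reproducible.
Random intercepts are drawn once per physical location and shared across
days. The generator does not model eDNA shedding/degradation kinetics,
within-pond spatial correlation beyond the random intercepts, or assay-level
error, so passing recovery tests demonstrate correctness of the inference
machinery, not realism of pond biology. `grid_design` (default 30 ponds
over 0.25–6 fish/m³, three days with a cooling trend) exists because the
real study's three stocked ponds confound pond and density; recovery
experiments need a density gradient. Its defaults were chosen once to give
detection rates (~10%) and information content comparable to a realistic
multi-pond study.

## Reproduction scope and known limitations

The packaged pipeline reproduces exactly: the fixture totals (324/28/243/0),
the density SD 2.53, the confidence-set DIC weights
{0.39, 0.27, 0.16, 0.11, 0.07} and the 1.44 best-to-second plausibility
ratio from the published ΔDIC column, odds-ratio arithmetic (e.g. 0.44,
0.60 and its reciprocal 1.67), and the survey-design closed forms (42
samples at p = 0.07; 1 − 0.45⁵ > 0.95). The third published plausibility
ratio is 3.54 in print but 0.39/0.11 = 3.5454… rounds to 3.55; the printed
value appears truncated.

Refitting the best model to the reconstruction under genuinely diffuse
priors gives a density coefficient posterior mean ≈ 2.17 (MLE 2.05),
whereas the original study prints 1.58 with an interval [1.04, 2.22].
Because the likelihood is determined exactly by the published cell counts,
this gap cannot be reconstruction error; the printed coefficient table is
matched only by substantially more informative priors (SD ≈ 1 on the logit
scale), and the printed control-pond intercept −4.20 is matched almost
exactly by a prior SD of 1.6. Meanwhile the diffuse refit reproduces the
study's own downstream numbers — per-sample detection probabilities of
0.55/0.06/0.02 at 28 °C and 3–5 samples for 95% certainty at high density —
which the printed coefficients do not. The package keeps honestly diffuse
defaults and exposes the prior as configuration rather than silently
matching the table; absolute DIC/pD values and the Bayesian p-value of the
original report share this prior dependence, so only rankings and
non-extremeness are treated as reproducible. Model-selection runs at the
full 16-model × 200k-iteration scale take minutes, so examples and tests
use shortened chains; all stated results hold at both profiles.
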