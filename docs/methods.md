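# Methods

This note documents the models, the synthetic-data generator, the
samplers and the numerical conventions in `droughtnorms`, and the design
choices made where more than one reasonable convention exists.

## Drought indices

All three environmental covariates derive from the trailing 30-day
rainfall total `S_t` (the window includes day *t*; the first 29 days of
a record are undefined rather than partially summed, and a window
containing a missing day is undefined).

* **Gap filling.** A missing day is imputed as the mean of the observed
  values among the 15 days before and 15 after, provided at least 15 of
  those 30 neighbours are observed; imputation always uses the original
  record, never previously imputed values, so the result is
  order-independent.
* **Precipitation index.** `P_t = (S_t − m_d) / s_d`, where `m_d, s_d`
  are the mean and sample SD (n−1 denominator) of `S` on the same
  (month, day-of-month) across the index reference years (default
  1996–2013). Calendar-day matching means the index is invariant to
  shifting a series by whole years. Feb 29 borrows Feb 28's statistics.
  If `s_d = 0` (identical reference years), the index is 0 at the mean
  and ±5 (a configurable cap) away from it. A calendar day with fewer
  than two reference values is an error naming the day.
* **Drought risk** is the exact negation of the precipitation index, so
  positive values mean drier than expected. The negation is an
  involution and preserves missingness.
* **Expected rainfall.** `R_d` is the mean over the expected-rainfall
  reference years (default 1997–2013, the complete years) of the
  globally standardized total `(S − m_global)/s_global`, with the global
  moments taken over all totals in that reference period. The curve is a
  smooth description of seasonality (≈ −1 through the dry season, up to
  ≈ +1 at the wet-season peak) whose year-round mean is ≈ 0 by
  construction.

Whether the original index convention used a trailing or centred window
and a sample or population SD is not stated anywhere authoritative;
trailing + sample SD was chosen and is flagged here. Both reference-year
sets are configurable.

## Hormone preparation

Within each female, in order: (1) restrict to the study window
(2008-01-01 to 2013-12-31); (2) drop samples with < 0.1 g dry matter;
(3) keep the earliest sample of each day; (4) collapse each maximal run
of consecutive days — a 1-day run is kept, a 2-day run keeps its first
day, a run of ≥ 3 days keeps its first and last day, so no two retained
samples are ever on consecutive days (keeping both days of a 2-day run
would violate the no-consecutive-days rule; the earlier day wins,
matching the tie convention everywhere else); (5) cap each
female-month at 4 samples, choosing the subset that maximizes first the
minimum pairwise date gap, then the overall span (last − first), ties
broken toward earlier dates. The span criterion is what "most spread
out" requires: among equal-min-gap subsets it prefers the one covering
the month rather than its first three weeks. Selection is deterministic
and idempotent.

Across the pooled candidate set, the 10-SD outlier rule is applied by
**iterative peeling**: the current maximum is flagged if it exceeds the
mean of the *other* unflagged samples by more than 10 of their SDs, the
statistics are re-estimated, and the process repeats until the maximum
is unexceptional. Any single-pass variant (pooled or leave-one-out)
provably masks a cluster of k equal contaminated values once
`10·sqrt(k/n)` approaches 1; peeling does not. Samples whose duplicate
assay CV is ≥ 20% are removed independently. Every removal is logged
with its reason.

Reproductive state uses a 158-day gestation back-dated from each birth:
days 0–78 after conception are early pregnancy, 79–157 late pregnancy;
nursing lasts 365 days or until the infant's death; a non-pregnant,
non-nursing female under 5 years is pre-reproductive. For the
hierarchical models the three non-pregnant states are merged into a
single `not_pregnant` level. The natural log is used for GC (the base is
not stated anywhere authoritative; it only shifts coefficients by a
constant factor). Collection time is minutes since midnight; it, age,
rank and group size are z-scored over the included rows, while drought
risk and expected rainfall stay on their native SD scales (their values,
e.g. "expected rainfall = 1", are meaningful units). Age and rank enter
the survival models fixed at the drought start (15 May 2014); the
covariate screen uses age at the sample date. A constant covariate
column z-scores to zeros rather than raising, so degenerate demographic
tables still produce a frame (the affected model will then fail on a
singular design, which is the right place for the error).

## Hierarchical GC models

Three Gaussian hierarchical models share one sampler:

* the **covariate screen** (collection time, age, rank, group size,
  5-level reproductive state, expected rainfall; female and group
  random intercepts);
* the **reaction-norm model** (drought risk, expected rainfall, their
  interaction, collection time, merged state; by-female random slopes
  for *all* fixed effects, correlated, plus a group intercept);
* the **three-way model** (the reaction-norm model with survival fully
  crossed with drought × rainfall; by-female slopes for drought,
  rainfall, their interaction, time and state — not for the
  survival terms, which are between-female).

**Priors.** Fixed effects: improper flat. Every SD (random-effect,
group, residual): half-Student-t(3, 0, A) with A = 2.5·sd(y), realized
for the random-effect covariance via the Huang–Wand (2013)
inverse-Wishart/inverse-gamma construction, which leaves each SD with
exactly that half-t marginal and the correlations near-uniform, and
keeps all conditionals conjugate.

**Sampler.** A blocked Gibbs scan (fixed effects; per-female effects
jointly per female; group intercepts; covariance; variances) augmented
with three kinds of extra moves that target the known pathologies of
Gibbs sampling for variance components:

1. *Marginal scale moves on Σ*: Metropolis proposals that rescale one
   row/column of the random-effect covariance, accepted against the
   likelihood with the per-female effects integrated out analytically
   (Woodbury identities on the per-female q×q blocks) and against the
   closed-form Huang–Wand marginal prior
   `p(Σ) ∝ det(Σ)^{−(ν+2q)/2} ∏_k (ν(Σ⁻¹)_kk + A⁻²)^{−(ν+q)/2}`
   (auxiliaries integrated out, then refreshed from their exact
   conditional). These break the "funnel" that traps small SDs.
2. *Marginal scale moves on the group variance*, same idea with the
   group effects integrated out.
3. *Exact translation (recentering) moves*: for each random-effect
   column identical to a fixed-effect column, a Gibbs draw of the shift
   `δ` between them (`β_j ← β_j + δ`, `u_{·k} ← u_{·k} − δ`), removing
   the location coupling that otherwise dominates the intercept's
   autocorrelation.

Chains are initialized over-dispersed (OLS ± noise for β, log-uniform
jitter on variances) so split-R̂ is meaningful. At the default settings
(4 chains × 4000 iterations, warmup 1000, thinning 1) the reaction-norm
model on the default synthetic data passes R̂ ≤ 1.01 and bulk/tail
ESS ≥ 600 on every parameter; this is asserted in the test suite. A
reduced profile (2 chains × 600) is used for replicate experiments,
where only point estimates and interval endpoints are needed.

**BLUPs.** A female's reaction norm at expected rainfall `r` is the
posterior mean of her *deviation* components: slope
`E[b_D + b_DR·r]`, intercept `E[b₀ + b_R·r]`; the group intercept is not
included. Because survival-model predictors are z-scored across females,
including the fixed-effect part would cancel anyway. Scaled versions are
z-scored across females (zeros if there is no variation). BLUP spreads
are shrunk relative to the true spread — the attenuation that motivates
the three-way model as a confirmation — and this is asserted over
replicates in the tests.

**Summaries.** Posterior mean, posterior SD ("estimation error"), 89%
equal-tailed interval (5.5% and 94.5% quantiles — the percentile
convention, not HDI), split-R̂ and bulk/tail ESS per parameter.

## Survival models

The BLUP survival model is Bernoulli-logit with fixed effects only
(intercept, scaled BLUP slope, scaled BLUP intercept, scaled age, scaled
rank); the coefficient table has exactly those rows. Optional weakly
penalized per-group intercepts are available but off by default — with
14 fatalities and 14 survivors in 8 groups they are barely informed.
Priors are Normal(0, 2.5) on all coefficients: with n = 28 a flat prior
risks an improper posterior under separation. Quasi-separation (the
posterior mode classifying every female correctly) is detected and
flagged, not fatal.

The sampler alternates a random-walk Metropolis step (covariance
`2.38²/d · H⁻¹` from the Laplace approximation at the mode) with an
independence step from a multivariate t(7) at the mode, giving
near-independent draws (ESS in the thousands at the default settings).

`predict_survival_probability` computes the inverse-logit of the linear
predictor; given arrays of posterior draws it averages the inverse-logit
over draws, the convention for model-based predicted probabilities
(slightly shrunk toward 0.5 relative to plugging in posterior means —
with a slope posterior of 0.73 ± 0.35 the −1 SD probability is 0.33
either way, while the +1 SD probability is 0.67).

The three-way model's `gc_contrast(D, R)` is, per posterior draw,
`Δ = β_surv + β_surv:D·D + β_surv:R·R + β_surv:D:R·D·R` (collection time
0, not-pregnant baseline), summarized as mean and 89% interval; the
percent contrast divides Δ by the fatality group's predicted log GC at
the same covariates. At drought risk 0 with survivor differences
confined to the drought response, Δ's interval covers 0 across the
seasonal range — the "no baseline difference" check.

## Mortality model

Yearly female deaths are `Binomial(exposure, p_category)` under a
logit-link GLM (statsmodels) on the El Niño category; study years run
15 May – 14 May and each year is its own row even within one multi-year
drought. Rate ratios are ratios of predicted *probabilities*, not odds
(at rates near 0.04–0.13 the two agree to one decimal anyway).
`AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1)` with **n = number of year
rows**; the comparison returns AICc(null) − AICc(model), positive when
the category model wins. With two rows the correction is undefined and
accessing AICc raises.

## Synthetic-data generator

The generator's defaults are the study conditions; everything is
configurable but nothing was revisited after testing began.

* **Rainfall**: daily zero-inflated gamma, 1996–2015. Wet season
  May 1 – Nov 30 with P(rain) = 0.55 and mean 9 mm/day (≈ 1900 mm/yr,
  typical for a Central-American tropical dry forest), dry season
  P(rain) = 0.05, mean 0.3 mm/day; gamma shape 0.7 reproduces many dry
  days and right-skewed wet totals. Drought years scale the wet-season
  mean: 0.55 in 2009 and 0.6 in 2012 (the moderate droughts of the
  sampling period), 0.35–0.4 in 2014–2015 (the severe El Niño).
* **Females**: 28, in 8 groups round-robin; ages uniform 8–24 years at
  the drought start; ranks uniform on (0, 1]; group sizes 8–20. Births
  spaced ≥ 500 days (pregnancies cannot overlap) with 20% infant
  mortality, so all reproductive states occur.
* **Random effects** `(b₀, b_D, b_R, b_DR)` multivariate normal with SDs
  (0.2, 0.15, 0.10, 0.15) and identity correlation by default; residual
  SD 0.4. These put BLUP-vs-truth correlations in the regime the
  recovery experiments target (~0.7–0.85 with 28 females × ~27 samples).
* **Fixed effects**: intercept 5 (GC ≈ 150 ng/g), drought 0.2, rainfall
  −0.2 (drier periods → higher GC), interaction 0.15, collection time
  −0.2 per SD (earlier samples higher), early/late pregnancy offsets
  0.15/0.35. Collection time is generated with its theoretical
  standardization (uniform 05:00–18:00 → mean 690 min, SD ≈ 225); the
  fitted coefficient uses the empirical z-score, a ≲ 2% scale
  difference absorbed by the recovery tolerances.
* **Survival**: logit-linear in the z-scored *true* slope and intercept
  at expected rainfall 1, age and rank, with coefficients
  (0, 0.73, 0.09, −0.44, 0.27) — so the two-stage analysis is evaluated
  against a generating process in the regime of interest, and the
  attenuation from using BLUPs instead of truth is measurable.
* **Mortality**: 1990–2023, exposure 45 females/year, baseline rate
  0.04, multiplier 3.3 in the severe El Niño years (1997, 2014, 2015);
  ordinary El Niño years have no excess, matching the modelled contrast.
* **Planted problems**: on request, GC outliers (×50) and assay-CV
  failures are planted on samples that survive the deterministic
  selection rules, so removal logs count them exactly.

Determinism: every component draws from its own substream of the master
seed (`SeedSequence(seed, spawn_key=(component,))`), so rainfall,
individuals, hormones, survival and mortality can be regenerated
independently; the same seed reproduces byte-identical fixture files.

What the generator does **not** emulate: ENSO dynamics or spatial
rainfall structure, serial autocorrelation in a female's consecutive
samples beyond her random effects, assay noise structure (a single
lognormal residual stands in for biological + assay variation),
group-level GC effects (the generative group SD is 0; the fitted models
still estimate one), and any behavioural response (foraging, ranging).
Passing recovery tests therefore shows the *estimators* are correct and
well calibrated under the assumed structure — not that the assumed
structure is true of field data.

## Problem sizes and profiles

Replicate experiments (coverage, sign recovery, three-way detection) use
20 replicates of the full 28-female population at the reduced sampler
profile, and the null-calibration check uses 50 outcome redraws over one
fitted stage-one model — sizes chosen so the entire suite and the
acceptance script each complete in a few minutes on one CPU while
leaving the binomial noise on the reported rates at a few percent. The
full sampler profile is the library default and is exercised once in the
convergence test.

## Known limitations

* The Gibbs sampler assumes the random-effect design is a subset of the
  fixed-effect columns for its recentering moves (true for all three
  shipped models; other designs still sample, just with more
  autocorrelation on the intercept).
* The logistic sampler's independence proposal assumes the Laplace
  approximation is sane; under extreme separation acceptance drops and
  the random-walk component carries the chain.
* Percent GC contrasts divide by the fatality linear predictor and are
  unstable if that predictor is near zero (not the case on the log-GC
  scale, which sits near 5).
* AICc follows the year-rows-as-n convention; with exposure as the
  effective sample size the correction would be negligible.
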