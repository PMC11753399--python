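# droughtnorms

Glucocorticoid reaction norms to drought risk, and their survival
consequences, in a wild primate population.

## The problem

Wild white-faced capuchins in a tropical dry forest experience
unpredictable droughts — rainfall deficits beyond the ordinary, brutal
dry season. A severe El Niño drought can kill a substantial fraction of
the adult females in a population. A long-standing question in
behavioural endocrinology is whether a *robust* acute stress response
(a strong hypothalamic–pituitary–adrenal activation when conditions turn
bad) is adaptive: do individuals that mount a bigger glucocorticoid (GC)
response to drought survive catastrophic droughts at a higher rate?

Answering that requires an individual-level **reaction norm** analysis:
each female's systematic change in (log) fecal glucocorticoids along a
continuous drought gradient, estimated from repeated samples, then
carried into a survival model. This package implements that entire
analysis chain as a tested, reusable pipeline:

1. **Drought indices from daily rainfall** (`droughtnorms.rainfall`).
   For day *t*, the trailing 30-day rainfall total `S_t` is compared with
   the same calendar day across reference years:

   * precipitation index `P_t = (S_t − mean_ref(S)) / sd_ref(S)` (SD units),
   * **drought risk** `D_t = −P_t` (positive = drier than expected),
   * **expected rainfall** `R_t`: the per-calendar-day mean of the
     globally z-scored 30-day total (≈ +1 in the wet season, ≈ −1 in the
     dry season).

   Missing days are gap-filled from the surrounding 30 days when at
   least half of them are observed.

2. **Hormone sample preparation** (`droughtnorms.hormones`).
   Deterministic selection rules (study window, ≥ 0.1 g dry mass,
   earliest sample per day, no consecutive days, ≤ 4 per month chosen
   maximally spread out), a 10-SD outlier rule and a 20% assay-CV rule,
   reproductive-state coding from offspring records (158-day gestation
   split into early/late halves; one year of nursing), and the join
   against the daily index table with natural-log GC and z-scored
   covariates.

3. **Hierarchical Bayesian reaction-norm model**
   (`droughtnorms.glucocorticoids.ReactionNormModel`). For sample *j* of
   female *i*:

   ```
   log GC_ij = β₀ + β_D D_j + β_R R_j + β_DR D_j R_j + β_t t_j + β_state
             + b₀ᵢ + b_Dᵢ D_j + b_Rᵢ R_j + b_DRᵢ D_j R_j + b_tᵢ t_j + b_stateᵢ
             + w_group + ε_ij
   ```

   with correlated per-female random slopes for every fixed effect and a
   group intercept. Each female's **BLUP reaction norm at expected
   rainfall 1** (the wet season, where drought bites hardest) is
   `slope_i = E[b_Dᵢ + b_DRᵢ · 1 | data]`, her individual drought
   responsiveness.

4. **Survival models** (`droughtnorms.survival`,
   `droughtnorms.glucocorticoids.ThreeWayGCModel`). A Bernoulli-logit
   model of surviving the severe El Niño drought on the scaled BLUP slope
   and intercept, controlling for age and rank; and the reverse analysis,
   a three-way `drought × expected rainfall × survived` interaction model
   for log GC that avoids the anticonservatism of two-stage BLUPs.

5. **Year-level mortality** (`droughtnorms.mortality`): a binomial GLM of
   female deaths/exposure on El Niño category with probability-scale
   rate ratios and AICc comparison against the null.

6. **A synthetic-data generator** (`droughtnorms.simulate`) that emulates
   all four inputs with known ground truth — seasonal zero-inflated-gamma
   rainfall with drought years, individual GC reaction norms, survival
   generated from the *true* slopes, and yearly mortality counts — so
   every stage can be validated by parameter recovery.

No probabilistic-programming framework is required: the package ships
its own blocked Gibbs sampler for the Gaussian hierarchical models
(half-Student-t priors on all SDs via the Huang–Wand construction, with
marginal and recentering moves for reliable mixing) and a
Laplace-preconditioned Metropolis sampler for the logistic survival
model. Convergence is reported per parameter as split-R̂ and bulk/tail
effective sample sizes (via arviz), with the convention R̂ ≤ 1.01 and
ESS ≥ 600, and all intervals are 89% equal-tailed posterior quantiles.

## Worked example

```python
import pandas as pd
from droughtnorms import (
    RunConfig, run_pipeline, predict_survival_probability,
)

bundle = run_pipeline(RunConfig(
    output_dir="demo_out", synthetic={}, seed=1, mcmc_profile="test",
))
print(bundle["survival_fit"].summary().round(2)[["mean", "ci_lower", "ci_upper"]])
```

On the default synthetic population (28 females, ~27 samples each,
survival generated with a log-odds slope of 0.73 per SD of true reaction
norm) this prints:

```
                mean  ci_lower  ci_upper
parameter
intercept       0.45     -0.38      1.26
blup_slope      1.38      0.41      2.38
blup_intercept  1.94      0.47      3.62
age            -1.94     -3.55     -0.76
rank           -0.29     -1.18      0.64
```

The `blup_slope` row is the headline estimate: the log-odds of surviving
the drought per SD of drought responsiveness. In this realization its
89% interval excludes zero — more-responsive females survived at
detectably higher rates (at n = 28 the estimate is noisy: across
replicate populations the posterior mean has the right sign about 90% of
the time; see `scripts/acceptance.py`).
The probability contrast implied by a slope coefficient of 0.73:

```python
p_low = predict_survival_probability({"blup_slope": 0.73}, blup_slope_scaled=-1)
p_high = predict_survival_probability({"blup_slope": 0.73}, blup_slope_scaled=+1)
print(round(p_low, 2), round(p_high, 2))   # 0.33 0.67
```

— a female 1 SD below the mean reaction norm survives with probability
0.33, one 1 SD above with probability ~0.67, about twice as likely.

A command-line interface mirrors the library
(`droughtnorms simulate | indices | prep | fit-gc | fit-survival |
fit-mortality | run-all`); every run writes a manifest with the seed,
configuration and SHA-256 of each output, and the same seed reproduces
byte-identical outputs.

## Layout

```
src/droughtnorms/
  rainfall.py         drought indices from daily precipitation
  hormones.py         sample selection, outliers, covariate coding
  simulate.py         synthetic data generator with ground truth
  mcmc.py             Gibbs + Metropolis samplers
  summaries.py        posterior summaries, R-hat / ESS diagnostics
  glucocorticoids.py  hierarchical GC models (screen, reaction norm, three-way)
  survival.py         BLUP survival model and predicted probabilities
  mortality.py        yearly binomial mortality GLM + AICc
  pipeline.py         end-to-end orchestration with manifest
  cli.py              command-line interface
docs/methods.md       model and generator documentation
tests/                pytest suite (unit, property, end-to-end checks)
```
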