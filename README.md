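# steppebird

Demographic estimators for sagebrush-steppe songbirds surveyed on
fixed 25-ha plots: **nest density** from line-transect distance
sampling, **daily nest survival** from a logistic-exposure model, and
**adult abundance** from dependent double-observer counts — plus the
comparison between adult pair density and nest density that asks
whether counting adults is a safe proxy for breeding activity.

It is written for avian ecologists who run plot-based monitoring of
species such as Brewer's sparrow (*Spizella breweri*) and vesper
sparrow (*Pooecetes gramineus*) and want all three estimators, and a
simulator with known truth for checking them, behind one tested API.

## The estimators

**Nest density.** Perpendicular distances x from transect lines to
nests feed a detection function g(x) with g(0) = 1 (half-normal,
hazard-rate or uniform key, optionally multiplied by cosine, simple- or
Hermite-polynomial adjustment series, or with covariates on log σ),
fitted by maximum conditional likelihood and ranked by AICc. Density is

    D̂ = n / (2 w L P̂a),

with truncation distance w, total line length L and average detection
probability P̂a = ∫₀ʷ g(x)dx / w. The variance combines encounter-rate
variation across transects with the delta-method variance of P̂a;
intervals are log-normal with a Satterthwaite-t critical value.

**Nest survival.** An interval of t days between nest checks survives
with probability θᵗ, where logit(θ) = x'β + u_plot and
u_plot ~ N(0, σ²) is integrated out by Gauss–Hermite quadrature.
Candidate covariate models (stage, year, nest density, program
enrollment, vegetation, weather) are ranked by AICc, and seasonal
survival is θ raised to the nesting period (19 days for Brewer's, 15
for vesper sparrow).

**Adult abundance.** In a dependent double-observer survey the primary
observer calls out every bird seen; the secondary records those plus
any the primary missed. With latent N ~ Poisson(λ) the tallies
marginalize exactly by Poisson thinning — x₁ ~ Poisson(λp₁),
x₂ ~ Poisson(λ(1−p₁)p₂), independent — so the hierarchical model
(log λ = species + enrollment + year + plot effect; logit p = observer
+ species + year; vague Normal(0, 1000) priors and Uniform(0, 100) on
the plot SD) is sampled by adaptive Metropolis-within-Gibbs without
data augmentation. Convergence is checked by split-Rhat and ESS.

**Density dependence.** Plot-level nest density and adult pair density
(pairs = λ/2 under monogamy) are joined and tested with a Pearson
correlation, plus a pair:nest ratio summary.

## Worked example

```python
from steppebird import (SimulationConfig, generate_plots,
                        simulate_nest_survey, DistanceSamplingModel,
                        estimate_density)
from steppebird.simulate import survey_effort
from steppebird.config import SpeciesConfig

cfg = SimulationConfig(seed=1, n_plots=30, years=[2016],
                       species=[SpeciesConfig("vesper_sparrow",
                                              nest_density=6.0)])
plots = generate_plots(cfg)
detections, _ = simulate_nest_survey(plots, cfg)
effort = survey_effort(plots, cfg)

model = DistanceSamplingModel(detections, w=25.0)
table, fits = model.fit_all()          # AICc-ranked candidate suite
top = fits[table["model"].iloc[0]]
print(top.summary())
est = estimate_density(top, detections, effort, strata=None)[0]
print(f"D = {est.density:.2f} per 25 ha "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}), P_a = {est.p_a:.3f}")
```

prints (truth: density 6 nests / 25 ha, half-normal σ = 6.5 m):

```
Detection function: half-normal
  n = 71, w = 25.00 m, k = 1
  log-likelihood = -188.3366, AICc = 378.7312
  P_a = 0.3450
  sigma = 6.8833 m
D = 4.57 per 25 ha (95% CI 3.04-6.87), P_a = 0.345
```

AICc picks the generating key, the fitted scale sits near the
generating σ, and the density interval covers the simulated truth
(one 30-plot season is a small sample — the acceptance script shows
the estimator is unbiased over replicate surveys). The same pattern — fit, summarize, check
against the truth table — applies to `LogisticExposureModel` and
`DependentDoubleObserverModel`; `run_pipeline` (or `steppebird
run-all`) chains all stages and writes the CSV artifacts.

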