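# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. Nothing
here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Survey design being modelled

The unit of inference is a 500 × 500 m (25 ha) plot surveyed over a
breeding season (roughly 8 May – 1 July). Half of the plots are
enrolled in a grazing-management conservation program (SGI), a binary
plot covariate. Three data streams come off each plot: perpendicular
nest-to-transect distances from 5 parallel 500-m transects at 100-m
spacing walked 3–4 times a season; dated nest status checks every ~3
days until fledge or failure; and dependent double-observer adult
counts on 3–4 visits.

## Nest density (line-transect distance sampling)

The detection function g(x), with g(0) = 1, has key
half-normal `exp(−x²/2σ²)`, hazard-rate `1 − exp(−(x/σ)^−b)` (b > 1
so g decreases), or uniform. Adjustment series multiply the key —
cosine `cos(jπx/w)` at orders 2–3, simple polynomials `(x/w)^j` at 4
and 6, probabilists' Hermite polynomials at 4 and 6 — and the product
is renormalized to g(0) = 1. Covariates act on log σ; adjustments and
covariates are never combined in one model (the conventional
multiple-covariate restriction). The conditional likelihood
Π g(xᵢ)/μ, μ = ∫₀ʷ g, is maximized by multi-start L-BFGS-B on
log-transformed parameters (gradient tolerance 1e−8); μ uses the erf
closed form for plain half-normal keys and 64-node Gauss-Legendre
quadrature otherwise. Fitted curves that leave [0, 1] on a 101-point
grid are flagged and dropped from the AICc ranking.

Truncation w defaults to the largest observed distance: observers
searched a narrow corridor (strip half-width 25 m; field mean distance
≈ 5 m), so data-driven truncation is the safe default and w is
configurable.

Density is D̂ = n/(2wLP̂a), converted to nests per 25 ha
(× 250,000 m²). The squared CV adds the R2-type encounter-rate
variance across transect lines (lengths as weights) and the
delta-method variance of P̂a from a finite-difference Hessian.
Detections pool across survey rounds while effort L sums line length ×
rounds, so a nest re-detected on a later round re-enters the numerator
— this keeps the encounter rate unbiased, but re-detections of one
nest are clustered rather than independent draws from f(x). The P̂a
variance is therefore inflated by the mean cluster size (detections
per distinct nest) when nest identities are available, and the
log-normal interval uses a Satterthwaite-t critical value pooling the
two components' degrees of freedom (K−1 lines; n−k detections). In
500-replicate simulations this interval covers the true density at
91–95%; without the cluster correction it undercovers (~89%).

Strata follow the reporting unit year × enrollment, with pooled
across-year summaries, plus per-plot-year estimates (where a plot has
≥ 2 detections, the minimum for a detection function) that feed the
survival covariate and the density-dependence comparison. A
single-transect stratum falls back to Poisson encounter-rate variance
with a warning.

## Nest survival (logistic exposure)

Visit histories decompose into consecutive-visit intervals: exposure t
= days between checks, outcome 0 only when the nest was found failed
at the interval's end, stage (egg/nestling) taken at the interval
start; intervals spanning hatch are not split. A failed interval is
credited its full length by default (`midpoint=True` halves it) — the
field convention is unstated, so both are exposed and the default is
the conservative full interval. Opportunistically found nests are
included (they carry no distance but full visit histories).

The likelihood term is θᵗ (survived) or 1 − θᵗ (failed) with
logit(θ) = x'β + u_plot. The plot random intercept u ~ N(0, σ²) is
integrated by 20-node probabilists' Gauss-Hermite quadrature —
non-adaptive, which is accurate here because per-plot interval counts
are moderate and θ is far from boundaries; the t ≡ 1 case reduces
exactly to logistic regression and is cross-checked against a standard
logistic fit to 1e−6. Design matrices come from a light formula
interface (`~ stage + year + shrub_cover`): strings are dummy-coded
dropping the first sorted level, rank deficiency is an error naming
the columns, and one-outcome data triggers a separation warning.
Standard errors come from the finite-difference Hessian at the
optimum.

Seasonal survival is DSR^period with period 19 days (Brewer's) and 15
days (vesper) by default. Reported powers are unrounded: 0.81¹⁵ =
0.0424 and 0.90¹⁹ = 0.1351 (a rounded DSR can print a slightly
different seasonal value than the power of the rounded rate). Apparent
success is the raw fledged fraction over nests with known fate
(censored histories excluded by default); the failure-cause table
normalizes over failed nests only.

## Adult abundance (dependent double-observer MCMC)

Latent per-visit abundance N ~ Poisson(λ) is marginalized exactly by
thinning — x₁ ~ Poisson(λp₁) and x₂ ~ Poisson(λ(1−p₁)p₂),
independent — which the test suite proves equal to the explicit
latent-N augmentation sum to 1e−10. λ is a shared plot-year expected
count (closed season) observed on conditionally independent repeat
visits; log λ = α_species + β_SGI + β_year + ε_plot with
ε_plot ~ N(0, σ²); logit p = observer identity + species + year with
first-level reference coding (observer effects absorb the intercept).
Priors: Normal(0, variance 1000) on every linear-predictor
coefficient, Uniform(0, 100) on σ.

The sampler is random-walk Metropolis within Gibbs: scalar updates for
each coefficient and for σ, and a vectorized simultaneous update of
all plot effects (valid because plots are conditionally independent
given the coefficients). Proposal scales adapt toward 0.3 acceptance
in 50-iteration windows during burn-in only and are frozen afterwards,
preserving detailed balance for the retained draws. Chains initialize
at the method-of-moments detection estimate p̂ = 1 − Σx₂/Σx₁ and the
correspondingly corrected naive abundance. Default run length follows
the study protocol: 3 chains × 10,000 iterations, 1,000 burn-in.
Split-Rhat and ESS (via ArviZ) are reported per parameter with a 1.1
flag threshold; a prior-only run (data term off) returns the
Uniform(0, 100) prior on σ, a direct kernel-correctness check.

Pair density is λ/2 under an assumed 1:1 sex ratio and social
monogamy. Per-plot 95% credible intervals cover true λ at roughly
90–95% in 80-plot simulations; exact nominal coverage is not expected
for individual shrunken plot effects when the species intercept is a
fixed (not prior-drawn) truth.

## Density dependence

Plot-level point estimates (distance-sampling densities, posterior
mean pair densities) are inner-joined on plot/year/species — unmatched
records are logged, duplicates are errors — and correlated with a
Pearson test (r from the product-moment formula; two-sided p from
t = r√(n−2)/√(1−r²) on n−2 df). Estimator uncertainty is not
propagated into the correlation; an errors-in-variables treatment is
out of scope. Pairing pools years within plot by default
(`by="plot-year"` keeps plot-years). The ratio summary reports
mean/min/max of pair ÷ nest density per species and enrollment
stratum, dropping zero-nest-density records with a log entry.

## Synthetic-data generator

Each generator draws from its own stream spawned from the master seed
(stable stream indices), so output is reproducible and adding a
generator never perturbs another's draws. Defaults mirror the study
conditions: 80 plots, half enrolled, three seasons, two species —
Brewer's-like (nest density 5/25 ha, DSR 0.90 egg / 0.92 nestling,
19-day period, 16 adults/25 ha) and vesper-like (6/25 ha, 0.81/0.84,
15 days, 20 adults/25 ha) — half-normal nest detection with σ = 6.5 m
(gives a mean detection distance near the reported ~5.4 m), 0.48
per-observer adult detection (the posterior detection the study
reports), 3 rounds/visits per season, and covariates drawn identically
across enrollment groups (the study found no covariate differences).
The egg→nestling switch is fixed at 55% of the period (rounded), since
only total periods are stated.

Deliberate simplifications, hence what passing recovery tests do and
do not show: nests are independent (no renesting or multibrooding, as
these were unverifiable in the field data); nests are available for
detection on every round regardless of timing; failure causes are
drawn at fixed proportions (predation-dominated); territoriality,
movement and interspecific competition are absent; adult counts have
no double-counting. Recovery therefore demonstrates estimator
correctness under the assumed data-generating processes, not
robustness to their violation.

One site-level log-normal effect per plot (SD 0.25 by default) scales
adult abundance — shared across species and years, matching the
hierarchical model's structure. An optional shared plot-quality effect
(`plot_density_sd`, default 0 = homogeneous plots) scales nest and
adult densities together; it is what gives the density-dependence
comparison a signal, and setting adult density to 4 × nest density on
that gradient yields the "every pair nests" end-to-end scenario (pairs
≡ 2 × nests) used for recovery.

## Problem sizes

Recovery runs use sizes chosen to give stable Monte-Carlo answers on a
single CPU: 500 replicate strata of 10 plots for density recovery in
the test suite (300 in the acceptance script), 5,000 exposure
intervals across 50 plots, 80 plots × 3 visits with 3 × 10,000 MCMC
iterations for abundance, and 500 plots for the end-to-end comparison.

## Known limitations

* Non-adaptive Gauss-Hermite quadrature can lose accuracy for very
  large per-plot cluster sizes with extreme random effects.
* Hazard-rate integrals use fixed-node quadrature on [0, w]; very
  large w with a narrow fitted shoulder would need adaptive rules.
* The detection-variance cluster correction uses mean cluster size, a
  first-order design-effect argument, not a full between-cluster
  variance estimator; a transect-level bootstrap would be the heavier
  alternative.
* Point-transect sampling, spatial density surfaces, open-population
  dynamics and cause-specific competing-risk survival are out of
  scope.
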