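# Methods

This note documents the models, the choices made where the design was open,
the synthetic-data generators and what passing tests do and do not
demonstrate, and the numerical details a user re-deriving results will need.

## Mortality from age-at-death samples

Published odontocete age-structure datasets are tallies of dead animals per
age class. We bin ages into 1-year half-open intervals `[a, a+1)` (sources
report growth-layer ages at varying precision; a 1-year bin matches the
annual deposition of tooth growth layers) and model the counts above the age
at maturity as multinomial draws from the standing adult age distribution.
The cell probability for bin `i` of dataset `d` is

θ_{d,i} ∝ L_i · R_{d,i} · S_{d,i}

* `L_i` — Gompertz survivorship `exp(−(α/β)(e^{β·AGE_i}−1))`, normalized over
  bins; `AGE` counts years past maturity. `β = 0` is handled as the
  exponential limit. α and β are shared by all datasets of a species-sex.
* `R_{d,i} = (1−ρ_d)^{AGE_i}` — the distortion left in a death sample by
  population change during collection. `ρ_d = r / (½·max observed age)`
  converts a prior on total change `r` (shared by datasets from one
  population) into a per-year rate; the transform is taken as given and the
  simulator applies the identical transform so fit and truth share a scale.
* `S_{d,i}` — `s_d + 1` inside the dataset's declared bias window, 1 outside;
  `s_d ≥ 0` is per-dataset.
* Age-estimation error: an estimated age is the true age plus Normal noise of
  sd `(age + B)/20` (B the dataset's systematic ageing offset), rounded to a
  whole year. Rather than sampling a latent true age per individual — which
  mixes poorly — we marginalize: θ is multiplied by a row-stochastic kernel
  whose row `i` is the rounded-Normal distribution centred on bin `i`. The
  two parameterizations agree in expectation; the kernel version is
  sampler-friendly.

Priors (all weakly informative): α ~ half-Normal(0, 0.1), β ~
half-Normal(0, 0.2), s_d ~ Exponential(1), r ~ Normal(source-derived mean,
sd). The age grid runs to ω = max(120 yr, 3× max observed age), beyond any
plausible odontocete lifespan.

**Ordinary maximum lifespan** Z is the smallest grid age by which a fraction
q = 0.9 of adult person-years (trapezoid-integrated survivorship) has been
lived. It is attached per posterior draw, giving a full Z distribution per
species-sex.

**Juvenile mortality** uses the Siler bathtub hazard
`h(x) = a₁e^{−b₁x} + a₂ + a₃e^{b₃x}` fitted to datasets with more than 100
sub-maturity records, same multinomial construction from age 0. The exact
bathtub parameterization is our choice; only the qualitative shape
(declining juvenile + constant + senescent term) is constrained. Species
without adequate juvenile sampling get survival-to-maturity imputed from a
Bayesian regression of logit survival on age at maturity across directly
fitted species (≥5 required); the slope's sign is estimated, never assumed.

## Reproductive lifespan from ovarian corpora

Corpora counts at adult age index `i` (i = 0 is the first adult year) are
Poisson with mean `λ_i = Σ_{j=0..i} Δk_j`, `Δk_j = max(0, α(1−β·j))`.
The raw linear form goes negative past `1/β`; we clamp increments at zero,
which a valid Poisson mean requires, so λ plateaus after cessation.
Datasets of one species share the decline rate β and carry their own initial
rate α_d. Priors: α_d ~ half-Normal(0, 2), β ~ half-Normal(0, 0.1).
Reproductive lifespan (cessation age) is `1/β + age at maturity` per draw.

## Kinship demography

Per joint posterior draw (one mortality draw × one corpora draw) we build a
1-year life table to ω = 120: juvenile yearly survival as the constant rate
compounding to the species' survival-to-maturity (or the Siler ratios when a
direct fit exists), adult survival from the Gompertz draw, and relative
fecundity `φ(age) = max(0, 1−β(age−maturity))`.

Baseline fecundity `f` (daughters per female-year at φ = 1) solves the
stationarity condition. With fertilities `f·φ(x)` in the Leslie first row and
survival on the subdiagonal, the Euler–Lotka condition at growth rate 1 is
`Σ_x l(x)·f·φ(x) = 1`, which is linear in f; we solve it directly and verify
the assembled matrix's dominant eigenvalue is 1 within 1e-6 by power
iteration (the spec-level bracketing search reduces to this closed form).

Kin expectations are deterministic recursions conditional on the focal
female being alive at age x: daughters of age a number `f·φ(x−a)·l(a)`;
matrilineal grandoffspring born while the focal was age t accrue at rate
`Σ_a d[t,a]·f·φ(a)` and survive like anyone else. Sex ratio at birth is 0.5,
so "both sexes" counts are twice the daughter-line numbers, with
grandoffspring routed through daughters only. Metrics:

* grandmother years = Σ_x l(x | maturity) · E[grandoffspring aged < maturity
  at x]; mother years analogous with offspring (both sexes); "relative"
  versions divide by the age at maturity.
* reproductive overlap = Σ_x E[newborn grandoffspring at x] ·
  (Σ_{y≥x} φ(y) / Σ_y φ(y)). Remaining reproductive capacity is
  schedule-based and *not* weighted by focal survivorship — the survival
  factor is stated for grandmother years but not for overlap, and we keep
  that asymmetry; a flag (`survival_weight_overlap`) enables the weighted
  variant for sensitivity analysis.

The recursions are verified against an independent individual-based forward
simulation (Poisson births, Bernoulli survival, 10⁵ replicates) on a worked
three-age toy table with exact hand values (f = 4/3, expected daughters 2,
newborn granddaughters 8/9, grandmother years 4/9, overlap 4/9).

## Phylogenetic regressions

Species summaries enter with their posterior sds. The core model puts an
Ornstein–Uhlenbeck kernel `K = η²e^{−ρ²D}` over patristic distances:

y_true ~ MVN(α + β_SIZE·s_true + β_PR·M, K),  y_obs ~ N(y_true, σ_y),
s_true ~ N(s_obs, σ_s).

Because the chain is jointly Gaussian, latent true values are marginalized
exactly: y_obs ~ MVN(α + β_SIZE·s_obs + β_PR·M, K + diag(σ_y²) +
β_SIZE²·diag(σ_s²)). This reduces a 32-species fit from ~70 to 5 sampled
parameters with an identical posterior; latent posteriors remain available
as Gaussian conditionals per draw. Predictors are standardized internally
and coefficients back-transformed. Priors: slopes ~ Normal(0, 10²) on the
standardized scale, η, ρ ~ half-Normal(0, 2), intercept ~ Normal(mean(y),
(10·sd(y))²). The model is fitted per bootstrap chronogram and pooled with
equal draws per tree; the residual variance is entirely the kernel's
diagonal η² (no separate nugget), matching the model's single dispersion
source.

Tail probabilities are reported as the proportion of the pooled posterior
above/below zero. Model comparison uses leave-one-out expected log pointwise
predictive density: for a multinormal likelihood the per-species
leave-one-out densities have closed-form Gaussian conditionals; draws are
combined with Pareto-smoothed importance weights (the non-factorized-LOO
estimator — the estimator itself was an open choice). Differences are
reported as (without − with) ± se.

The female:male lifespan ratio model treats `δl = τl_f/τl_m` as
log-Normal(α + β_PR·M, σ), σ ~ Exponential(1), with latent true lifespans
per species-sex; a species with a reported sd of 0 has its latent pinned,
which also provides the degenerate-error oracle path used in tests.

Kinship-metric contrasts (menopause vs not) reuse the same regression with
the metric's posterior mean ± sd as the response and no size term.

## Counterfactual scenarios

For each menopause species: *observed* uses the fitted demography unchanged;
*ancestral* rescales the Gompertz ageing rate β — holding α, preserving the
hazard's shape with one degree of freedom (which of α/β to move was an open
choice) — until Z equals the size-predicted non-menopause value, leaving φ
untouched; *slow* stretches φ so cessation equals the observed lifespan.
Baseline fecundity is re-solved per case, so the slow case's f is never
above the observed case's. Draws stay aligned across cases (shared upstream
draws), so contrasts are paired: P(case A > case B) counts ties as half.
Pooled per-species z-scoring across cases supports cross-species display.

## Synthetic data: what it does and does not emulate

`simulate_age_dataset` draws ages from the exact θ the mortality model
assumes (Gompertz survivorship, growth discount with the same ρ transform,
windowed bias, rounded Gaussian age error), so fits are scored against
recorded truth under the model's own assumptions. `simulate_corpora_dataset`
draws ages from the same standing distribution and counts from the Poisson
accumulation process. `simulate_clade` grows a Yule (pure-birth) chronogram,
jitters its depth log-Normally (sd 0.05) for bootstrap replicates, and sets
species lifespans by an allometry on log length plus a menopause offset
(default 40 yr, the magnitude of the long-lived menopausal odontocetes'
excess) plus OU-correlated noise (η = 3 yr, ρ = 0.3); reproductive lifespans
follow the same allometry in *all* species — menopause extends life, not
reproduction. Observation noise: 2 yr on lifespan summaries, 5% on log
length.

Passing tests therefore demonstrate internal correctness and calibration
under the models' assumptions — they do not validate the assumptions against
real strandings data, where age-estimation error can be non-Gaussian,
sampling bias unwindowed, and corpora subject to regression with age (which
the deposition model deliberately excludes).

## Numerical choices and problem sizes

* All samplers are affine-invariant ensembles (differential-evolution moves)
  with a Nelder–Mead (or coarse-grid) start; convergence requires split
  R-hat < 1.01 over four walker groups, and non-converged fits are returned
  flagged, never silently.
* Default study sizes: age samples n = 1000, corpora n = 200, clades of
  16–32 species with 4–5 menopausal, 1–10 bootstrap trees, 100–1000 joint
  kinship draws — sizes at which every recovery and calibration property in
  the test suite is identifiable on a single workstation core.
* Degenerate inputs: survivorship underflow at extreme ages is treated as 0;
  an all-zero corpora dataset is rejected (α unidentifiable); duplicate taxa
  at distance 0 are jittered (1e-8) inside the kernel; ρ ≥ 1 per-year
  population change is rejected.
* The pipeline expands one global seed into fixed per-stage substreams, so
  disabling one stage leaves the others' randomness unchanged; manifests
  record seeds, versions, convergence flags and table hashes.

## Known limitations

Non-Gompertz adult hazards, covariate effects on mortality, corpora
regression with age, paternal kin and sons' offspring in the kinship
currency, Pagel's λ / Brownian alternatives to the OU kernel, and
continuous menopause coding are all out of scope. The age at maturity enters
the life table rounded to a whole year. R-hat across walker groups of a
single ensemble is a weaker diagnostic than across independent chains;
flagged fits should be rerun longer where it matters.
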