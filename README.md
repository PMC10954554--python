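# odontolife

Comparative life-history demography of toothed whales: why do a handful of
odontocete species — like humans, and almost nothing else — stop reproducing
decades before they die?

The package implements, end to end, the statistical machinery needed to ask
that question of published life-history data, and ships a synthetic-data
generator that reproduces the statistical structure of such data so the whole
pipeline runs, and is tested, without any external download. It is written
for comparative biologists and demographers who want the individual models as
library functions as well as the full analysis as a pipeline.

## What it computes

**Mortality.** Counts of dead whales per age class (strandings, by-catch) are
modelled as a multinomial sample from the standing adult age distribution:

    c ~ Multinomial(θ, N),   θ_i ∝ L_i · R_i · S_i

with `L_i` Gompertz survivorship (hazard α·e^{βx}, parameters shared within a
species-sex), `R_i = (1−ρ)^AGE_i` a population-change discount, `S_i = s+1`
inside a dataset-specific sampling-bias window, and Gaussian age-estimation
error of sd `(age+B)/20` marginalized through a row-stochastic kernel. From
the posterior we derive the ordinary maximum lifespan **Z** — the age by
which 90% of adult person-years have been lived.

**Reproduction.** Ovarian corpora persist after each ovulation, so corpora
counts of known-age females index lifetime ovulations. Counts follow
`C ~ Poisson(λ_i)` with `λ_i = Σ_{j≤i} max(0, α(1−β·AGE_j))`: deposition
declines linearly and ceases at `1/β` years past maturity; reproductive
lifespan is `1/β + age at maturity`.

**Kinship demography.** Per posterior draw, a Leslie matrix is assembled from
juvenile survival, Gompertz adult survival, and the fecundity schedule
`φ(age) = max(0, 1−β(age−maturity))`, with baseline fecundity `f` solved so
the population is stationary (Euler–Lotka, dominant eigenvalue 1). Kin
recursions then give expected living offspring and matrilineal grandoffspring
by focal age, from which: **grandmother years** (survivorship-weighted years
alive with sub-maturity grandoffspring), **mother years**, and
**reproductive overlap** (expected newborn grandoffspring × fraction of the
focal's reproductive capacity remaining).

**Comparative regressions.** Species-level estimates (with their posterior
sds as measurement error) enter a Bayesian phylogenetic regression with an
Ornstein–Uhlenbeck covariance `K_ij = η²e^{−ρ²D_ij}` over patristic
distances, fitted on each bootstrap chronogram and pooled:

    Z ~ MultiNormal(α + β_SIZE·log length + β_PR·menopause, K)

Models with and without the menopause term are compared by leave-one-out
expected log predictive density; a log-Normal model compares female:male
lifespan ratios.

**Counterfactual scenarios.** For each menopause species the observed
demography is contrasted with its inferred non-menopausal *ancestral* case
(lifespan reduced to the size-predicted value, reproductive schedule
unchanged) and a *slow life history* case (reproduction extended over the
whole observed lifespan), with baseline fecundity re-solved per case.

## Worked example

```python
import numpy as np
from odontolife.synthetic import AgeSimConfig, simulate_age_dataset
from odontolife.mortality import fit_mortality

ds, truth = simulate_age_dataset(AgeSimConfig(n=1000, alpha=0.05, beta=0.1,
                                              maturity=10.0, seed=2))
post = fit_mortality([ds], maturity=10.0, seed=3, age_error=False)
print(f"alpha {post.draws['alpha'].mean():.4f} ± {post.draws['alpha'].std():.4f}")
print(f"beta  {post.draws['beta'].mean():.4f} ± {post.draws['beta'].std():.4f}")
print(f"Z     {post.draws['Z'].mean():.1f} yr, converged={post.converged}")
```

prints (exactly, given the seeds):

```
alpha 0.0488 ± 0.0076
beta  0.1089 ± 0.0126
Z     23.4 yr, converged=True
```

— the generating hazard (α = 0.05, β = 0.1) is recovered within one
posterior sd, and the fitted species would have lived 90% of its adult
person-years by age 23.4.

The full analysis is the numbered scripts under `analysis/`
(`01_simulate.py` … `06_scenarios.py`), each writing its tables to
`results/`; the same stages run from one configuration via

```bash
odontolife run --config config.yaml
```

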