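# odglmm — overdispersed Binomial mixed models: simulation and estimation

Binomial proportion data in ecology (eggs hatched out of a clutch, hosts
infected out of a group) are routinely overdispersed, and the two standard
fixes — adding an **observation-level random effect (OLRE)** or switching to
a **Beta-Binomial** error structure — do not behave the same way. `odglmm`
is a tool for studying exactly that: it simulates grouped proportion data
under two distinct overdispersion mechanisms, fits three mixed-model
families by exact marginal maximum likelihood (and the Beta-Binomial one by
MCMC as well), computes the Pearson dispersion diagnostic, and runs
replicated parameter-recovery studies over a full scenario grid.

It is written for quantitative ecologists and biostatisticians who want to
check whether their overdispersion strategy recovers unbiased estimates
under a known truth, or to reproduce and extend published simulation
comparisons of OLRE versus Beta-Binomial models.

## The model

All fitted families share a logit-linear hierarchy for individual *i* in
population *j(i)*:

    h_i ~ f(c_i, p_i, dispersion)
    logit(p_i) = alpha_j(i) + β_prey · Prey_i + β_bodysize · Bodysize_i
    alpha_j ~ Normal(μ_pop, σ²_pop)

where *f* is

| family | extra parameter | mechanism |
|---|---|---|
| Binomial | — | none |
| Binomial + OLRE | σ_ε | per-row Normal(0, σ²_ε) logit offset |
| Beta-Binomial | φ | p drawn from Beta(p/φ, (1−p)/φ) per row |

The Beta-Binomial dispersion φ implies within-clutch trial correlation
ρ = φ/(1+φ) and variance inflation 1 + (c−1)ρ. The data generator uses the
same two mechanisms (`od_binomial`, `beta_binomial`), so every
data-mechanism × model-family combination can be crossed. The overdispersion
diagnostic is the classic ratio of summed squared Pearson residuals to
residual degrees of freedom (>1 ⇒ overdispersed), with a parametric
bootstrap interval.

## Worked example

```python
import numpy as np
from odglmm import (
    ScenarioConfig, OverdispersionLevel, ModelSpec,
    simulate_dataset, fit_ml, pearson_dispersion,
)

# strong Beta-Binomial overdispersion, 10 populations x 20, clutch 5;
# truth: mu_pop=-1, sigma_pop=0.5, beta_prey=0.6, beta_bodysize=-0.01
cfg = ScenarioConfig(
    mechanism="beta_binomial",
    overdispersion=OverdispersionLevel(phi=2.0),
    n_populations=10, n_per_population=20, clutch_size=5,
)
ds = simulate_dataset(cfg, np.random.default_rng(1))

naive = fit_ml(ds, ModelSpec("binomial"))
print("naive dispersion:", round(pearson_dispersion(ds, naive, ModelSpec("binomial"))[0], 2))

olre = fit_ml(ds, ModelSpec("binomial", olre=True))
bb = fit_ml(ds, ModelSpec("beta_binomial"))
print("OLRE        beta_prey:", round(olre.beta_prey, 3), " sigma_eps:", round(olre.sigma_eps, 2))
print("BetaBinomial beta_prey:", round(bb.beta_prey, 3), " phi:", round(bb.phi, 2))
```

Output:

```
naive dispersion: 3.34
OLRE        beta_prey: 2.892  sigma_eps: 5.03
BetaBinomial beta_prey: 0.77  phi: 1.89
```

The naive Binomial GLMM is strongly overdispersed (3.34 ≫ 1). Because this
dataset was generated by Beta-Binomial mixing, the OLRE model inflates the
prey slope almost fivefold (2.89 vs the true 0.6), while the correctly
specified Beta-Binomial model stays near the truth and recovers φ ≈ 2. The
disagreement between the two fits is itself the practical diagnostic: when
OLRE and Beta-Binomial estimates diverge like this, the OLRE results should
not be trusted.

## Command line

```bash
odglmm simulate --mechanism beta_binomial --phi 2 -j 10 -n 20 -c 5 --seed 1 --out d.csv
odglmm fit d.csv --family betabinom
odglmm dispersion d.csv --family binomial --n-boot 200
odglmm run-study --reps 200 --seed 1 --out study_out/   # full scenario grid
```

`run-study` accepts a YAML design file (see `odglmm.cli`) and writes a tidy
CSV of per-cell replicate means and 95% quantiles plus a JSON report.

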