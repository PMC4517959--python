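# Methods

## The problem

Proportion data — clutches of eggs of which some number hatch, broods of
which some fledge, hosts of which some are infected — are routinely modelled
with Binomial mixed models. Such data are very often *overdispersed*: the
observed counts vary more than a Binomial with the fitted mean can explain.
Ignoring the excess variation biases slope estimates and their standard
errors. Two standard remedies exist, and this package implements both, plus
the simulation machinery to study when each works:

1. **Observation-level random effects (OLRE).** A Normal(0, σ²_ε) intercept
   unique to each data row is added to the logit-scale linear predictor,
   absorbing extra-Binomial variation.
2. **Beta-Binomial models.** The Binomial success probability of each row is
   drawn from a Beta distribution with mean p_i and dispersion φ, giving
   within-observation trial correlation ρ = φ/(1+φ) and count variance
   n p (1−p) [1 + (n−1) ρ].

The central scientific question is whether each model recovers unbiased
parameter estimates when the *generating* mechanism of the overdispersion is
the other one — i.e., whether OLRE copes with Beta-Binomial mixing and
vice versa — and how that interacts with the number of groups (populations)
carrying the random intercept.

## Models

All three fitted families share the hierarchical logit-linear structure

    h_i        ~ f(c_i, p_i, dispersion)
    logit(p_i) = alpha_{j(i)} + beta_prey * Prey_i + beta_bodysize * Bodysize_i
    alpha_j    ~ Normal(mu_pop, sigma_pop^2)

with f one of: Binomial; Binomial with an extra per-row Normal(0, σ²_ε)
logit offset (OLRE); or Beta-Binomial with dispersion φ (shapes
a = p/φ, b = (1−p)/φ, so E[Beta] = p exactly).

### Maximum likelihood

The population intercept is integrated out per population by non-adaptive
Gauss–Hermite quadrature (default order 20). For the OLRE model each row's
ε_i is integrated by an inner quadrature (default order 15) nested inside
the population integral; the nesting is exact because the ε_i are
independent given alpha_j, so the per-population integrand factors over
rows. A dense-trapezoid integrator (`loglik_bruteforce`, ≥2,000 grid points
per latent dimension on a ±8 SD span) provides an independent accuracy
oracle; on the test fixtures the quadrature agrees with it to ≈1e−13 for
the single-integral families and to better than 1e−6 for the nested OLRE
integral at inner order 20 (≈3e−6 at order 15 — the inner order trades
speed for the last decimal).

Optimization is Nelder–Mead on an unconstrained scale (log for σ_pop and
for σ_ε/φ), started from a plain Binomial GLM for the fixed effects and 0.5
for all variance parameters, with up to three jittered restarts on failure.
The simplex tolerances (xatol 1e−3, fatol 1e−6) were chosen by checking
that the weakly identified bodysize slope reproduces its tightly converged
value; looser settings visibly drag it toward the GLM start. Gradient-based
optimizers (L-BFGS-B) were tried and rejected: on strongly overdispersed
data the OLRE likelihood is multimodal and line searches reliably stall in
an inferior mode that the simplex escapes. Estimated SDs below 1e−4 are
reported as exact zeros (boundary estimates, which genuinely occur for
σ_pop with few populations). Non-convergent fits are returned with
`converged=False`, never raised, and are excluded from study summaries with
the exclusion count reported.

All per-row pmf arithmetic runs in log space through log-gamma/log-beta
functions: at φ = 2 the Beta shapes fall below 0.4, where direct Beta
evaluation underflows. φ = 0 (and φ below 1e−9 inside the fitter) is
treated as the exact Binomial limit, since the betaln difference loses
precision to cancellation once the shapes exceed ~1e8.

### MCMC

The Bayesian Beta-Binomial model samples the population intercepts
explicitly (the classic BUGS formulation) with priors Normal(0, precision
0.001) on the location parameters, Uniform(0, 10) on σ_pop, and
Gamma(0.001, 0.001) on φ; a flag swaps the two scale priors for sensitivity
checks. The sampler is Metropolis-within-Gibbs with Gaussian random-walk
proposals: scalar blocks for each location and log-scale parameter and a
vectorized block of independent one-dimensional updates for the latent
intercepts. Proposal scales adapt every 50 iterations during burn-in toward
a 20–45% acceptance rate and are frozen afterwards, so the retained draws
come from a fixed, detailed-balance-preserving kernel. Default chain
geometry: 2 chains × 20,000 iterations, burn-in 2,000, thinning 20 → 900
retained draws per chain. Convergence is judged by the classic
between/within-variance potential scale reduction factor with acceptance
bound 1.05. The sampler is deliberately a different algorithm from the
quadrature ML fitter — agreement between the two on the same data is itself
a correctness check, exercised in the tests.

### Dispersion statistic

The overdispersion diagnostic is the ratio of the sum of squared Pearson
residuals to the residual degrees of freedom (n minus fixed-effect and
variance parameters). Fitted probabilities are *conditional*: the
population intercept enters at its per-population posterior mode given the
ML parameters, and for OLRE models the observation effects enter at their
conditional modes as well (the joint mode is found by profiling the
concave per-row problems with damped Newton inside a one-dimensional outer
search). Conditioning on the OLRE predictions is what makes the statistic
collapse far below 1 after adding an OLRE to overdispersed data — the
model "soaks up" the excess variation — and matches the convention of the
standard mixed-model residual diagnostics. The parametric bootstrap
interval simulates from the fitted model, refits, and recomputes the
statistic; for a well-specified model the interval covers 1, and an
observed point far above the interval is the overdispersion signal. Refit
failures are dropped and counted; a report with >20% failures is flagged
unreliable.

## The synthetic-data generator

The generator emulates a clutch-hatching study: J populations ×
n individuals, clutch size c constant within a scenario, covariates Prey
and Bodysize, truth fixed at μ_pop = −1, σ_pop = 0.5, β_prey = 0.6,
β_bodysize = −0.01. The default scenario grid is: overdispersion ladder
(φ ∈ {0.1, 1, 2} / σ_ε ∈ {0.1, 1.5, 3}) at J=10, n=20, c=5; random-effect
levels J ∈ {3, 5, 20} at strong overdispersion; clutch sizes c ∈ {2, 4, 10};
and a total-sample-size control with J=3, n=67 (total n ≈ 200 with only 3
groups).

The covariate distributions are a documented choice: Prey is standard
normal (a strong but non-separating effect at β_prey = 0.6) and Bodysize is
uniform on [−10, 10], centered, so that the −0.01 slope spans ≈0.2 logits —
about a 4-percentage-point difference in hatch rate across the bodysize
range around the grand mean of ≈0.27. Both laws are injectable per scenario.
Covariates are drawn fresh for every replicate dataset; replicate r of cell
s uses an independent, platform-stable substream derived from (master seed,
cell, r), so serial and parallel execution agree.

What the generator does *not* emulate: unbalanced group sizes, covariate
measurement error, zero-inflation, or correlated trials beyond the
Beta-Binomial mixing. Passing tests therefore speak to the estimators'
behavior under the idealized balanced design, not to robustness against
those features of real field data.

## Reproduction cells and problem sizes

The `reproduce` module re-runs the headline cells at desk scale: 200
replicates per parameter-recovery cell (the published tables used 1,000)
and 60 replicates per mechanism per dispersion level, sizes chosen so the
full reproduction completes on one CPU in well under half an hour while
keeping Monte-Carlo error on replicate means small relative to the
tolerances of interest. Study summaries are means and empirical 2.5/97.5%
quantiles over converged fits, plus the proportion of replicates with a
positive bodysize slope (a sign error, given the weakly negative truth)
with a 10,000-resample nonparametric bootstrap CI.

Two reproduction caveats, both documented in detail in the test suite's
tolerance choices:

- The dispersion calibration of the naive Binomial model pools both
  generating mechanisms. At the weak level the pooled mean lands near 1.1;
  at the strong level exact moment arithmetic (variance inflation
  1 + (c−1)φ/(1+φ) = 3.67 at φ=2, c=5) puts it near 3.3, and both this
  package and independent reference fits agree on that value.
- The OLRE-on-Beta-Binomial bias magnitude and the Beta-Binomial model's
  σ_pop estimates depend on the covariate distributions, which are not
  fully identified by the published design; reference Laplace fitters
  (lme4, glmmTMB) applied to this generator's data agree with this
  package's fits, so the defaults are kept and results reported as
  computed.

## Known limitations

- ML only; no REML analogue, no random slopes or crossed random effects.
- No OLRE + Beta-Binomial combined family (never needed for the study
  design).
- Hessian-based standard errors are not computed; uncertainty is always
  summarized across replicates or posterior draws.
- Non-adaptive quadrature: with very large σ_ε (≫5) and large clutch sizes
  the inner integral's effective support can outgrow the node span; the
  brute-force oracle is the tool for checking any new regime.
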