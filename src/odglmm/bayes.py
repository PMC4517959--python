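"""Bayesian Beta-Binomial hierarchical model via adaptive random-walk MCMC.

The model matches the Beta-Binomial GLMM of :mod:`odglmm.glmm` but samples
the population intercepts explicitly as latent parameters (the classic
BUGS/JAGS formulation) instead of integrating them out:

    h_i      ~ BetaBinomial(c_i, p_i, phi)
    logit(p_i) = alpha_{j(i)} + beta_prey Prey_i + beta_bodysize Bodysize_i
    alpha_j  ~ Normal(mu_pop, sigma_pop^2)

Default priors: Normal(0, precision 0.001) on mu_pop and the slopes,
Uniform(0, 10) on sigma_pop, Gamma(shape 0.001, rate 0.001) on phi.  An
``swap_scale_priors`` flag exchanges the sigma_pop and phi priors for
prior-sensitivity checks.

The sampler is Metropolis-within-Gibbs with Gaussian random-walk proposals
per block (each scalar location parameter; all latent intercepts updated as
independent one-dimensional blocks; log sigma_pop; log phi).  Proposal
scales adapt during burn-in toward a 20-45% acceptance rate and are frozen
afterwards, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from .datagen import Dataset, inv_logit

__all__ = [
    "PriorSpec",
    "ChainSet",
    "log_posterior",
    "sample_posterior",
    "gelman_rubin",
]


@dataclass(frozen=True)
class PriorSpec:
    normal_precision: float = 0.001
    uniform_upper: float = 10.0
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001
    swap_scale_priors: bool = False  # Uniform(0,10) on phi, Gamma on sigma_pop

    def __post_init__(self) -> None:
        if self.normal_precision <= 0:
            raise ValueError("normal_precision must be positive")
        if self.uniform_upper <= 0:
            raise ValueError("uniform_upper must be positive")

    def log_prior_scales(self, sigma_pop: float, phi: float) -> float:
        """Joint log prior of the two scale parameters (natural scale)."""
        if self.swap_scale_priors:
            unif_val, gamma_val = phi, sigma_pop
        else:
            unif_val, gamma_val = sigma_pop, phi
        if not (0.0 < unif_val < self.uniform_upper):
            return -math.inf
        if gamma_val <= 0.0:
            return -math.inf
        lp = -math.log(self.uniform_upper)
        lp += (
            self.gamma_shape * math.log(self.gamma_rate)
            - gammaln(self.gamma_shape)
            + (self.gamma_shape - 1.0) * math.log(gamma_val)
            - self.gamma_rate * gamma_val
        )
        return float(lp)

    def log_prior_location(self, value: float) -> float:
        tau = self.normal_precision
        return float(0.5 * math.log(tau / (2 * math.pi)) - 0.5 * tau * value * value)


@dataclass
class ChainSet:
    """Retained posterior draws: array (n_chains, n_draws, n_params)."""

    draws: np.ndarray
    param_names: list[str]
    burnin: int
    thin: int

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must have shape (n_chains, n_draws, n_params)")
        if self.draws.shape[0] < 2:
            raise ValueError("at least 2 chains are required")
        if self.draws.shape[1] < 100:
            raise ValueError("at least 100 post-thinning draws per chain required")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.param_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.param_names)
            df.insert(0, "chain", c)
            df.insert(1, "draw", np.arange(self.n_draws))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def posterior_mean(self, name: str) -> float:
        return float(self.parameter(name).mean())

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.parameter(name), [a, 1.0 - a])
        return float(lo), float(hi)


def _loglik_conditional(
    hatched, clutch, coef, eta, alphas, idx, phi: float
) -> float:
    """Beta-Binomial log-likelihood given the latent intercepts."""
    p = inv_logit(eta + alphas[idx])
    a = p / phi
    b = (1.0 - p) / phi
    return float((coef + betaln(hatched + a, clutch - hatched + b) - betaln(a, b)).sum())


def log_posterior(params: dict, dataset: Dataset, priors: PriorSpec | None = None) -> float:
    """Log posterior density (natural scale, no sampling Jacobians).

    ``params`` holds mu_pop, beta_prey, beta_bodysize, sigma_pop, phi and
    ``alphas`` (one latent intercept per population).  Returns -inf outside
    the prior support.
    """
    priors = priors or PriorSpec()
    sigma_pop = params["sigma_pop"]
    phi = params["phi"]
    lp = priors.log_prior_scales(sigma_pop, phi)
    if not np.isfinite(lp):
        return -math.inf
    for name in ("mu_pop", "beta_prey", "beta_bodysize"):
        lp += priors.log_prior_location(params[name])
    alphas = np.asarray(params["alphas"], dtype=float)
    lp += float(
        (-0.5 * ((alphas - params["mu_pop"]) / sigma_pop) ** 2
         - math.log(sigma_pop) - 0.5 * math.log(2 * math.pi)).sum()
    )
    idx, prey, body, clutch, hatched = dataset.design_arrays()
    if len(alphas) != int(idx.max()) + 1:
        raise ValueError("one latent intercept per population is required")
    coef = gammaln(clutch + 1.0) - gammaln(hatched + 1.0) - gammaln(clutch - hatched + 1.0)
    eta = params["beta_prey"] * prey + params["beta_bodysize"] * body
    lp += _loglik_conditional(
        hatched.astype(float), clutch.astype(float), coef, eta, alphas, idx, phi
    )
    return float(lp)


@dataclass
class _State:
    beta: np.ndarray  # beta_prey, beta_bodysize
    mu: float
    alphas: np.ndarray
    log_sigma: float
    log_phi: float


def _run_chain(
    dataset: Dataset,
    priors: PriorSpec,
    n_iter: int,
    burnin: int,
    thin: int,
    rng: np.random.Generator,
):
    idx, prey, body, clutch_i, hatched_i = dataset.design_arrays()
    hatched = hatched_i.astype(float)
    clutch = clutch_i.astype(float)
    coef = gammaln(clutch + 1.0) - gammaln(hatched + 1.0) - gammaln(clutch - hatched + 1.0)
    n_pop = int(idx.max()) + 1

    def row_ll(eta_total, phi):
        p = inv_logit(eta_total)
        a = p / phi
        b = (1.0 - p) / phi
        return coef + betaln(hatched + a, clutch - hatched + b) - betaln(a, b)

    state = _State(
        beta=np.zeros(2),
        mu=0.0,
        alphas=np.zeros(n_pop),
        log_sigma=math.log(1.0),
        log_phi=math.log(1.0),
    )
    X = np.column_stack([prey, body])

    # cached row log-likelihoods at the current state
    def eta_of(state):
        return X @ state.beta + state.alphas[idx]

    cur_rows = row_ll(eta_of(state), math.exp(state.log_phi))

    def alpha_prior(alphas, mu, sigma):
        return -0.5 * ((alphas - mu) / sigma) ** 2 - math.log(sigma)

    # proposal scales and acceptance bookkeeping per block
    scales = {"beta0": 0.1, "beta1": 0.02, "mu": 0.3, "ls": 0.3, "lphi": 0.3}
    alpha_scales = np.full(n_pop, 0.5)
    acc = {k: 0 for k in scales}
    alpha_acc = np.zeros(n_pop)
    tries = {k: 0 for k in scales}
    ADAPT_EVERY = 50

    n_keep = (n_iter - burnin) // thin
    kept = np.empty((n_keep, 5 + n_pop))
    k_out = 0

    for it in range(n_iter):
        sigma = math.exp(state.log_sigma)
        phi = math.exp(state.log_phi)

        # --- slopes, one scalar Metropolis update each (full likelihood) ---
        for b_i, key in ((0, "beta0"), (1, "beta1")):
            prop = state.beta.copy()
            prop[b_i] += rng.normal(0.0, scales[key])
            new_rows = row_ll(X @ prop + state.alphas[idx], phi)
            log_r = (
                new_rows.sum()
                - cur_rows.sum()
                + priors.log_prior_location(prop[b_i])
                - priors.log_prior_location(state.beta[b_i])
            )
            tries[key] += 1
            if math.log(rng.uniform()) < log_r:
                state.beta = prop
                cur_rows = new_rows
                acc[key] += 1

        # --- latent intercepts, independent 1-d blocks, vectorized ---
        prop_alphas = state.alphas + rng.normal(0.0, alpha_scales)
        new_rows = row_ll(X @ state.beta + prop_alphas[idx], phi)
        cur_pop = np.zeros(n_pop)
        new_pop = np.zeros(n_pop)
        np.add.at(cur_pop, idx, cur_rows)
        np.add.at(new_pop, idx, new_rows)
        log_r = (
            new_pop - cur_pop
            + alpha_prior(prop_alphas, state.mu, sigma)
            - alpha_prior(state.alphas, state.mu, sigma)
        )
        accept = np.log(rng.uniform(size=n_pop)) < log_r
        if accept.any():
            state.alphas = np.where(accept, prop_alphas, state.alphas)
            rows_accept = accept[idx]
            cur_rows = np.where(rows_accept, new_rows, cur_rows)
            alpha_acc += accept

        # --- grand mean (cheap: only the alpha prior and its own prior) ---
        prop_mu = state.mu + rng.normal(0.0, scales["mu"])
        log_r = (
            alpha_prior(state.alphas, prop_mu, sigma).sum()
            - alpha_prior(state.alphas, state.mu, sigma).sum()
            + priors.log_prior_location(prop_mu)
            - priors.log_prior_location(state.mu)
        )
        tries["mu"] += 1
        if math.log(rng.uniform()) < log_r:
            state.mu = prop_mu
            acc["mu"] += 1

        # --- log sigma_pop (Jacobian: + theta) ---
        prop_ls = state.log_sigma + rng.normal(0.0, scales["ls"])
        prop_sigma = math.exp(prop_ls)
        lp_new = priors.log_prior_scales(prop_sigma, phi)
        lp_old = priors.log_prior_scales(sigma, phi)
        log_r = (
            alpha_prior(state.alphas, state.mu, prop_sigma).sum()
            - alpha_prior(state.alphas, state.mu, sigma).sum()
            + lp_new - lp_old + prop_ls - state.log_sigma
        )
        tries["ls"] += 1
        if np.isfinite(log_r) and math.log(rng.uniform()) < log_r:
            state.log_sigma = prop_ls
            sigma = prop_sigma
            acc["ls"] += 1

        # --- log phi (full likelihood; Jacobian: + theta) ---
        prop_lphi = state.log_phi + rng.normal(0.0, scales["lphi"])
        prop_phi = math.exp(prop_lphi)
        new_rows = row_ll(eta_of(state), prop_phi)
        lp_new = priors.log_prior_scales(sigma, prop_phi)
        lp_old = priors.log_prior_scales(sigma, phi)
        log_r = (
            new_rows.sum() - cur_rows.sum()
            + lp_new - lp_old + prop_lphi - state.log_phi
        )
        tries["lphi"] += 1
        if np.isfinite(log_r) and math.log(rng.uniform()) < log_r:
            state.log_phi = prop_lphi
            cur_rows = new_rows
            acc["lphi"] += 1

        # --- adaptation, burn-in only ---
        if it < burnin and (it + 1) % ADAPT_EVERY == 0:
            for key in scales:
                rate = acc[key] / max(tries[key], 1)
                if rate < 0.20:
                    scales[key] *= 0.7
                elif rate > 0.45:
                    scales[key] *= 1.4
                acc[key] = 0
                tries[key] = 0
            rate = alpha_acc / ADAPT_EVERY
            alpha_scales *= np.where(rate < 0.20, 0.7, np.where(rate > 0.45, 1.4, 1.0))
            alpha_acc[:] = 0.0

        if it >= burnin and (it - burnin) % thin == 0 and k_out < n_keep:
            kept[k_out, 0] = state.mu
            kept[k_out, 1] = state.beta[0]
            kept[k_out, 2] = state.beta[1]
            kept[k_out, 3] = math.exp(state.log_sigma)
            kept[k_out, 4] = math.exp(state.log_phi)
            kept[k_out, 5:] = state.alphas
            k_out += 1

    return kept[:k_out]


def sample_posterior(
    dataset: Dataset,
    priors: PriorSpec | None = None,
    n_iter: int = 20000,
    burnin: int = 2000,
    thin: int = 20,
    n_chains: int = 2,
    rng: np.random.Generator | None = None,
) -> ChainSet:
    """Run ``n_chains`` adaptive Metropolis-within-Gibbs chains.

    ``n_iter`` counts total iterations per chain including burn-in; after
    discarding the first ``burnin`` iterations every ``thin``-th state is
    retained, so each chain keeps (n_iter - burnin) // thin draws.
    """
    priors = priors or PriorSpec()
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if n_chains < 2:
        raise ValueError("at least 2 chains are required")
    if (n_iter - burnin) // thin < 1:
        raise ValueError("settings leave zero post-thinning draws")
    if rng is None:
        rng = np.random.default_rng(0)

    idx, *_ = dataset.design_arrays()
    n_pop = int(idx.max()) + 1
    names = ["mu_pop", "beta_prey", "beta_bodysize", "sigma_pop", "phi"] + [
        f"alpha_{j}" for j in range(n_pop)
    ]
    chains = [
        _run_chain(dataset, priors, n_iter, burnin, thin, np.random.default_rng(s))
        for s in rng.integers(0, 2**31 - 1, size=n_chains)
    ]
    return ChainSet(
        draws=np.stack(chains), param_names=names, burnin=burnin, thin=thin
    )


def gelman_rubin(chains: ChainSet, parameter: str) -> float:
    """Potential scale reduction factor (PSRF) for one parameter.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of the chain means.  Values
    near 1 indicate convergence; the conventional acceptance bound here is
    1.05.
    """
    x = chains.parameter(parameter)
    m, n = x.shape
    within = x.var(axis=1, ddof=1)
    if np.any(within == 0.0):
        raise ValueError(f"constant chain for parameter {parameter!r}")
    w = within.mean()
    b = n * x.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))
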