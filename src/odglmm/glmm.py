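"""Marginal maximum likelihood for Binomial and Beta-Binomial mixed models.

Three model families share a logit-linear predictor with a population
random intercept alpha_j ~ Normal(mu_pop, sigma_pop^2):

* ``binomial``             — h_i ~ Binomial(c_i, p_i);
* ``binomial`` + OLRE      — an observation-level random effect
  eps_i ~ Normal(0, sigma_eps^2) is added to the linear predictor;
* ``beta_binomial``        — h_i ~ BetaBinomial(c_i, p_i, phi).

The population intercept is integrated out per population with (non-adaptive)
Gauss–Hermite quadrature; for the OLRE model each observation's eps_i is
integrated by an inner quadrature nested inside the population integral.
The nesting is exact because the eps_i are independent given alpha_j, so the
per-population integrand factors over rows.  A dense-trapezoid brute-force
integrator provides an independent accuracy oracle on tiny datasets.

Optimization runs on an unconstrained scale (log for sigma_pop and for
sigma_eps / phi) with deterministic starting values from a plain Binomial
GLM; estimated SDs below 1e-4 are reported as exact zeros (boundary
estimates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .datagen import Dataset

__all__ = [
    "ModelSpec",
    "FitResult",
    "FitOptions",
    "GlmmParams",
    "loglik_marginal",
    "loglik_bruteforce",
    "fit_ml",
]

_SD_FLOOR = 1e-4  # below this an estimated SD/phi is a boundary zero

_LOG_ROOT_PI = 0.5 * math.log(math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Model family and random-effect structure.

    ``olre`` adds the observation-level random effect and is only valid with
    the Binomial family; the Beta-Binomial already carries its own
    per-observation dispersion.
    """

    family: str = "binomial"
    olre: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "beta_binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.olre and self.family != "binomial":
            raise ValueError("olre is only supported with the binomial family")

    @property
    def n_params(self) -> int:
        # mu_pop, beta_prey, beta_bodysize, sigma_pop (+ sigma_eps or phi)
        return 4 + (1 if (self.olre or self.family == "beta_binomial") else 0)

    @property
    def dispersion_name(self) -> str | None:
        if self.olre:
            return "sigma_eps"
        if self.family == "beta_binomial":
            return "phi"
        return None


@dataclass(frozen=True)
class GlmmParams:
    """Parameter point at which a marginal log-likelihood is evaluated."""

    mu_pop: float
    beta_prey: float
    beta_bodysize: float
    sigma_pop: float
    sigma_eps: float | None = None
    phi: float | None = None


@dataclass
class FitResult:
    beta_prey: float
    beta_bodysize: float
    mu_pop: float
    sigma_pop: float
    loglik: float
    converged: bool
    n_obs: int
    n_params: int
    sigma_eps: float | None = None
    phi: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def params(self) -> GlmmParams:
        return GlmmParams(
            mu_pop=self.mu_pop,
            beta_prey=self.beta_prey,
            beta_bodysize=self.beta_bodysize,
            sigma_pop=self.sigma_pop,
            sigma_eps=self.sigma_eps,
            phi=self.phi,
        )


@dataclass(frozen=True)
class FitOptions:
    pop_order: int = 20
    olre_order: int = 15
    max_restarts: int = 3
    restart_seed: int = 0
    maxfev: int = 4000


@lru_cache(maxsize=16)
def _gh_nodes(order: int):
    z, w = hermgauss(order)
    return z, np.log(w) - _LOG_ROOT_PI


def _check_orders(pop_order: int, olre_order: int) -> None:
    if pop_order < 5 or olre_order < 5:
        raise ValueError("quadrature order must be at least 5")


def _log_expit(x):
    """log(1/(1+exp(-x))), stable at both tails (hot path, hence hand-rolled)."""
    return np.minimum(x, 0.0) - np.log(1.0 + np.exp(-np.abs(x)))


def _binom_logpmf_terms(h, c, x):
    """Binomial log-pmf with p = inv_logit(x), without the binomial coefficient.

    Computed from a single log-logistic evaluation via
    log(1 - p) = log_expit(x) - x, so extreme predictors stay finite.
    """
    t = _log_expit(x)
    return c * t - (c - h) * x


def _logsumexp_last(v):
    """logsumexp over the last axis (lean replacement for scipy's)."""
    m = v.max(axis=-1, keepdims=True)
    out = np.log(np.exp(v - m).sum(axis=-1)) + m[..., 0]
    return out


def _row_loglik_at_logit(h, c, x, spec: ModelSpec, phi: float | None):
    """Per-row log density terms (no binomial coefficient) at logit values x."""
    if spec.family == "beta_binomial" and phi >= 1e-9:
        p = 1.0 / (1.0 + np.exp(-x))
        a = p / phi
        b = (1.0 - p) / phi
        # betaln terms of the Beta-Binomial pmf (coefficient added separately)
        return betaln(h + a, c - h + b) - betaln(a, b)
    # plain Binomial; also the phi -> 0 limit, where direct betaln evaluation
    # loses precision to cancellation
    return _binom_logpmf_terms(h, c, x)


def _dataset_arrays(dataset: Dataset):
    idx, prey, body, clutch, hatched = dataset.design_arrays()
    coef = gammaln(clutch + 1.0) - gammaln(hatched + 1.0) - gammaln(clutch - hatched + 1.0)
    return idx, prey, body, clutch.astype(float), hatched.astype(float), coef


def loglik_marginal(
    params: GlmmParams,
    dataset: Dataset,
    spec: ModelSpec,
    pop_order: int = 20,
    olre_order: int = 15,
) -> float:
    """Marginal log-likelihood with random effects integrated by Gauss–Hermite.

    For each population j,

        L_j = ∫ prod_{i in j} f(h_i | alpha) N(alpha; mu_pop, sigma_pop^2) d alpha,

    where ``f`` is the Binomial pmf (optionally with the OLRE integrated by
    an inner quadrature) or the Beta-Binomial pmf.  Returns sum_j log L_j.
    """
    _check_orders(pop_order, olre_order)
    idx, prey, body, clutch, hatched, coef = _dataset_arrays(dataset)
    eta = params.beta_prey * prey + params.beta_bodysize * body
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")

    z, logw = _gh_nodes(pop_order)
    alpha = params.mu_pop + math.sqrt(2.0) * params.sigma_pop * z  # (Q,)

    x = eta[:, None] + alpha[None, :]  # (n, Q)

    if spec.olre:
        sig = params.sigma_eps
        if sig is None or sig < 0:
            raise ValueError("olre model requires sigma_eps >= 0")
        zi, logwi = _gh_nodes(olre_order)
        xe = x[:, :, None] + math.sqrt(2.0) * sig * zi[None, None, :]  # (n, Q, R)
        row_q = _logsumexp_last(
            _binom_logpmf_terms(hatched[:, None, None], clutch[:, None, None], xe)
            + logwi[None, None, :]
        )  # (n, Q)
    else:
        phi = params.phi
        if spec.family == "beta_binomial" and (phi is None or phi <= 0):
            raise ValueError("beta_binomial model requires phi > 0")
        row_q = _row_loglik_at_logit(
            hatched[:, None], clutch[:, None], x, spec, phi
        )  # (n, Q)

    # sum rows within population, integrate the population intercept
    n_pop = int(idx.max()) + 1
    pop_sums = np.zeros((n_pop, len(z)))
    np.add.at(pop_sums, idx, row_q)
    total = _logsumexp_last(pop_sums + logw[None, :]).sum()
    return float(total + coef.sum())


def loglik_bruteforce(
    params: GlmmParams,
    dataset: Dataset,
    spec: ModelSpec,
    n_grid: int = 2001,
    span_sd: float = 8.0,
) -> float:
    """Dense-trapezoid reference for :func:`loglik_marginal` on tiny datasets.

    Integrates each latent dimension on a +/- ``span_sd`` SD grid of
    ``n_grid`` points.  Because the integrand is smooth and decays to zero at
    the grid ends, the trapezoid rule converges extremely fast and serves as
    an independent accuracy oracle for the quadrature.  Refuses datasets with
    more than 3 populations or 10 rows.
    """
    if dataset.n_rows > 10 or len(dataset.populations) > 3:
        raise ValueError(
            "loglik_bruteforce is a test oracle: at most 3 populations and 10 rows"
        )
    if n_grid < 2000:
        raise ValueError("oracle grid must use at least 2000 points per dimension")
    idx, prey, body, clutch, hatched, coef = _dataset_arrays(dataset)
    eta = params.beta_prey * prey + params.beta_bodysize * body

    def norm_logpdf(x, mu, sd):
        return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)

    sig_pop = params.sigma_pop
    if sig_pop > 0:
        a_grid = np.linspace(
            params.mu_pop - span_sd * sig_pop, params.mu_pop + span_sd * sig_pop, n_grid
        )
        a_logw = norm_logpdf(a_grid, params.mu_pop, sig_pop)
        da = a_grid[1] - a_grid[0]
    else:
        a_grid = np.array([params.mu_pop])
        a_logw = np.array([0.0])
        da = 1.0

    if spec.olre and params.sigma_eps and params.sigma_eps > 0:
        sig = params.sigma_eps
        e_grid = np.linspace(-span_sd * sig, span_sd * sig, n_grid)
        e_logw = norm_logpdf(e_grid, 0.0, sig)
        de = e_grid[1] - e_grid[0]

        def row_terms(x):
            # x: (n, A); integrate eps per row and per alpha node, chunked in A
            out = np.empty(x.shape)
            chunk = max(1, 2_000_000 // (x.shape[0] * n_grid))
            for s in range(0, x.shape[1], chunk):
                xe = x[:, s : s + chunk, None] + e_grid[None, None, :]
                ll = _binom_logpmf_terms(
                    hatched[:, None, None], clutch[:, None, None], xe
                )
                out[:, s : s + chunk] = _logsumexp_last(
                    ll + e_logw[None, None, :]
                ) + math.log(de)
            return out

    else:

        def row_terms(x):
            return _row_loglik_at_logit(
                hatched[:, None], clutch[:, None], x, spec, params.phi
            )

    x = eta[:, None] + a_grid[None, :]
    row_q = row_terms(x)
    n_pop = int(idx.max()) + 1
    pop_sums = np.zeros((n_pop, len(a_grid)))
    np.add.at(pop_sums, idx, row_q)
    if len(a_grid) == 1:
        total = (pop_sums[:, 0] + a_logw[0]).sum()
    else:
        # trapezoid in linear space with a per-population log shift
        g = pop_sums + a_logw[None, :]
        m = g.max(axis=1, keepdims=True)
        vals = np.trapezoid(np.exp(g - m), dx=da, axis=1)
        total = (np.log(vals) + m[:, 0]).sum()
    return float(total + coef.sum())


def _glm_start(dataset: Dataset) -> np.ndarray:
    """Deterministic fixed-effect start: plain Binomial GLM, no random effects."""
    _, prey, body, clutch, hatched, _ = _dataset_arrays(dataset)
    endog = np.column_stack([hatched, clutch - hatched])
    exog = sm.add_constant(np.column_stack([prey, body]))
    try:
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        beta = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(beta)):
            raise ValueError
    except Exception:
        p_bar = min(max(hatched.sum() / clutch.sum(), 1e-3), 1 - 1e-3)
        beta = np.array([math.log(p_bar / (1 - p_bar)), 0.0, 0.0])
    # guard against separation blowing up the start
    return np.clip(beta, -10.0, 10.0)


def _pack_bounds(spec: ModelSpec):
    # mu, beta_prey, beta_bodysize, log sigma_pop (+ log sigma_eps / log phi)
    bounds = [(-50, 50), (-50, 50), (-50, 50), (-12.0, 4.0)]
    if spec.dispersion_name is not None:
        bounds.append((-12.0, 4.0))
    return bounds


def _unpack(theta: np.ndarray, spec: ModelSpec) -> GlmmParams:
    mu, bp, bb, lsp = theta[:4]
    kw = {}
    if spec.olre:
        kw["sigma_eps"] = math.exp(theta[4])
    elif spec.family == "beta_binomial":
        kw["phi"] = math.exp(theta[4])
    return GlmmParams(
        mu_pop=mu, beta_prey=bp, beta_bodysize=bb, sigma_pop=math.exp(lsp), **kw
    )


def fit_ml(
    dataset: Dataset, spec: ModelSpec, options: FitOptions | None = None
) -> FitResult:
    """Maximize the marginal likelihood.

    Starts from a plain Binomial GLM for the fixed effects and 0.5 for each
    SD / dispersion parameter; on optimizer failure retries from up to
    ``max_restarts`` jittered starts.  Never raises on non-convergence: the
    best point found is returned with ``converged=False`` so that replicated
    simulation studies can record failure rates.
    """
    opts = options or FitOptions()
    _check_orders(opts.pop_order, opts.olre_order)

    start = np.concatenate(
        [_glm_start(dataset), [math.log(0.5)] * (1 + (spec.dispersion_name is not None))]
    )
    bounds = _pack_bounds(spec)

    def nll(theta):
        try:
            ll = loglik_marginal(
                _unpack(theta, spec),
                dataset,
                spec,
                pop_order=opts.pop_order,
                olre_order=opts.olre_order,
            )
        except (ValueError, FloatingPointError):
            return np.inf
        if not np.isfinite(ll):
            return np.inf
        return -ll

    rng = np.random.default_rng(opts.restart_seed)
    best = None
    converged = False
    theta0 = start.copy()
    for attempt in range(opts.max_restarts + 1):
        res = minimize(
            nll,
            theta0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxfev": opts.maxfev,
                "xatol": 1e-3,
                "fatol": 1e-6,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            best = res if res.fun <= best.fun else best
            break
        theta0 = start + rng.normal(0.0, 0.5, size=start.shape)

    params = _unpack(np.asarray(best.x), spec)
    sigma_pop = 0.0 if params.sigma_pop < _SD_FLOOR else params.sigma_pop
    sigma_eps = params.sigma_eps
    if sigma_eps is not None and sigma_eps < _SD_FLOOR:
        sigma_eps = 0.0
    phi = params.phi
    if phi is not None and phi < _SD_FLOOR:
        phi = 0.0
    return FitResult(
        beta_prey=float(params.beta_prey),
        beta_bodysize=float(params.beta_bodysize),
        mu_pop=float(params.mu_pop),
        sigma_pop=float(sigma_pop),
        sigma_eps=None if sigma_eps is None else float(sigma_eps),
        phi=None if phi is None else float(phi),
        loglik=float(-best.fun),
        converged=bool(converged and np.isfinite(best.fun)),
        n_obs=dataset.n_rows,
        n_params=spec.n_params,
    )
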