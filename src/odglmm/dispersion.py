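"""Pearson-residual dispersion statistic and its parametric bootstrap CI.

The dispersion statistic of a fitted Binomial-type mixed model is the ratio
of the sum of squared Pearson residuals to the residual degrees of freedom,

    D = sum_i (h_i - c_i p_i)^2 / (c_i p_i (1 - p_i))  /  (n - k),

where the fitted probabilities are conditional on the predicted population
intercepts (the per-population posterior mode of alpha_j at the ML
parameters) and k counts both fixed-effect and variance parameters.  Values
above 1 indicate overdispersion relative to the Binomial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln, log_expit

from .datagen import Dataset, inv_logit
from .glmm import FitOptions, FitResult, GlmmParams, ModelSpec, fit_ml

__all__ = [
    "DispersionReport",
    "pearson_dispersion_stat",
    "pearson_dispersion",
    "conditional_fitted_probs",
    "bootstrap_dispersion_ci",
    "simulate_from_fit",
]


@dataclass
class DispersionReport:
    point: float
    boot_lo: float
    boot_hi: float
    n_boot: int
    residual_df: int
    n_failed: int = 0
    unreliable: bool = False  # set when > 20% of bootstrap refits failed

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def pearson_dispersion_stat(hatched, clutch, fitted_p, residual_df: int) -> float:
    """Sum of squared Pearson residuals over the residual degrees of freedom."""
    hatched = np.asarray(hatched, dtype=float)
    clutch = np.asarray(clutch, dtype=float)
    p = np.asarray(fitted_p, dtype=float)
    if residual_df < 1:
        raise ValueError(f"residual_df must be >= 1, got {residual_df}")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("degenerate fit: fitted probability of exactly 0 or 1")
    resid_sq = (hatched - clutch * p) ** 2 / (clutch * p * (1.0 - p))
    return float(resid_sq.sum() / residual_df)


def _olre_modes(h, c, x0, sig_eps, n_iter: int = 30):
    """Per-row conditional modes of the observation-level effects.

    Maximizes h log p - (c - h) log(1-p) - e^2 / (2 sig^2) over e for each
    row (p = inv_logit(x0 + e)).  The objective is strictly concave in e, so
    damped Newton from 0 converges; vectorized across rows.
    """
    s2 = sig_eps * sig_eps
    e = np.zeros_like(x0)
    for _ in range(n_iter):
        p = inv_logit(x0 + e)
        grad = h - c * p - e / s2
        hess = -c * p * (1.0 - p) - 1.0 / s2
        step = grad / hess
        e = e - np.clip(step, -5.0, 5.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return e


def _pop_mode_objective(dataset: Dataset, params: GlmmParams, spec: ModelSpec):
    """Per-population negative log joint density of alpha_j (up to constants).

    For the OLRE model the observation effects are profiled out at their
    conditional modes, so the outer optimum is the joint mode of
    (alpha_j, {eps_i}).
    """
    idx, prey, body, clutch, hatched = dataset.design_arrays()
    eta = params.beta_prey * prey + params.beta_bodysize * body
    sig_pop = max(params.sigma_pop, 1e-8)

    if spec.olre and params.sigma_eps and params.sigma_eps > 0:
        sig_eps = params.sigma_eps

        def row_ll(h, c, x):
            e = _olre_modes(h, c, x, sig_eps)
            xe = x + e
            return (
                h * log_expit(xe)
                + (c - h) * log_expit(-xe)
                - 0.5 * (e / sig_eps) ** 2
            )

    elif spec.family == "beta_binomial":
        phi = params.phi if params.phi and params.phi > 0 else 1e-8

        def row_ll(h, c, x):
            p = inv_logit(x)
            a = p / phi
            b = (1.0 - p) / phi
            return betaln(h + a, c - h + b) - betaln(a, b)

    else:

        def row_ll(h, c, x):
            return h * log_expit(x) + (c - h) * log_expit(-x)

    def make(j):
        rows = idx == j
        h = hatched[rows].astype(float)
        c = clutch[rows].astype(float)
        e = eta[rows]

        def neg_log_joint(a):
            ll = row_ll(h, c, e + a).sum()
            return -(ll - 0.5 * ((a - params.mu_pop) / sig_pop) ** 2)

        return neg_log_joint

    return make, idx, eta


def conditional_fitted_probs(
    dataset: Dataset, fit: FitResult | GlmmParams, spec: ModelSpec
) -> np.ndarray:
    """Fitted probabilities conditional on the predicted random effects.

    For each population the mode of alpha_j given the data at the ML
    parameters is found by one-dimensional optimization; the fitted
    probability is inv_logit(alpha_j + fixed effects).  For OLRE models the
    per-row observation effects enter at their conditional modes as well, so
    the result conditions on the joint mode of (alpha_j, {eps_i}).
    """
    params = fit.params() if isinstance(fit, FitResult) else fit
    make, idx, eta = _pop_mode_objective(dataset, params, spec)
    n_pop = int(idx.max()) + 1
    modes = np.empty(n_pop)
    half_width = 10.0 * max(params.sigma_pop, 1.0)
    lo = params.mu_pop - half_width
    hi = params.mu_pop + half_width
    for j in range(n_pop):
        res = minimize_scalar(make(j), bounds=(lo, hi), method="bounded")
        modes[j] = res.x
    x = eta + modes[idx]
    if spec.olre and params.sigma_eps and params.sigma_eps > 0:
        _, _, _, clutch, hatched = dataset.design_arrays()
        x = x + _olre_modes(
            hatched.astype(float), clutch.astype(float), x, params.sigma_eps
        )
    return inv_logit(x)


def pearson_dispersion(
    dataset: Dataset, fit: FitResult, spec: ModelSpec
) -> tuple[float, int]:
    """Dispersion point estimate and residual degrees of freedom for a fit."""
    if not fit.converged:
        raise ValueError("pearson_dispersion requires a converged fit")
    p_hat = conditional_fitted_probs(dataset, fit, spec)
    _, _, _, clutch, hatched = dataset.design_arrays()
    residual_df = dataset.n_rows - spec.n_params
    point = pearson_dispersion_stat(hatched, clutch, p_hat, residual_df)
    return point, residual_df


def simulate_from_fit(
    dataset: Dataset, fit: FitResult | GlmmParams, spec: ModelSpec, rng: np.random.Generator
) -> Dataset:
    """Parametric-bootstrap draw: new responses at the observed covariates."""
    params = fit.params() if isinstance(fit, FitResult) else fit
    idx, prey, body, clutch, _ = dataset.design_arrays()
    n_pop = int(idx.max()) + 1
    alphas = rng.normal(params.mu_pop, params.sigma_pop, n_pop)
    x = alphas[idx] + params.beta_prey * prey + params.beta_bodysize * body
    if spec.olre and params.sigma_eps and params.sigma_eps > 0:
        x = x + rng.normal(0.0, params.sigma_eps, len(x))
        hatched = rng.binomial(clutch, inv_logit(x))
    elif spec.family == "beta_binomial" and params.phi and params.phi > 0:
        p = inv_logit(x)
        q = rng.beta(p / params.phi, (1.0 - p) / params.phi)
        hatched = rng.binomial(clutch, q)
    else:
        hatched = rng.binomial(clutch, inv_logit(x))
    frame = dataset.frame.copy()
    frame["hatched"] = hatched
    return Dataset(frame=frame)


def bootstrap_dispersion_ci(
    dataset: Dataset,
    fit: FitResult,
    spec: ModelSpec,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    fit_options: FitOptions | None = None,
) -> DispersionReport:
    """Parametric-bootstrap 95% interval for the dispersion statistic.

    Simulates ``n_boot`` datasets from the fitted model, refits, recomputes
    the statistic, and reports the 2.5/97.5 percentiles of the bootstrap
    distribution alongside the observed point estimate.  Non-convergent
    refits are dropped from the percentiles and counted; if more than 20%
    fail the report is flagged unreliable.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if rng is None:
        rng = np.random.default_rng(0)
    point, residual_df = pearson_dispersion(dataset, fit, spec)
    stats = []
    n_failed = 0
    for _ in range(n_boot):
        boot = simulate_from_fit(dataset, fit, spec, rng)
        refit = fit_ml(boot, spec, fit_options)
        if not refit.converged:
            n_failed += 1
            continue
        try:
            stat, _ = pearson_dispersion(boot, refit, spec)
        except ValueError:
            n_failed += 1
            continue
        stats.append(stat)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return DispersionReport(
        point=point,
        boot_lo=float(lo),
        boot_hi=float(hi),
        n_boot=n_boot,
        residual_df=residual_df,
        n_failed=n_failed,
        unreliable=n_failed > 0.2 * n_boot,
    )
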