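"""Beta-Binomial compound distribution in the mean/dispersion parameterization.

A Beta-Binomial observation arises by drawing a success probability
``q ~ Beta(a, b)`` and then a count ``k ~ Binomial(n, q)``.  Here the Beta
shapes are tied to a mean probability ``p`` and a dispersion parameter
``phi`` through

    a = p / phi,        b = (1 - p) / phi,

so that ``E[q] = p`` always, while larger ``phi`` concentrates mass toward
the extremes of (0, 1) and hence inflates the count variance.  The trials
within one observation share the same latent ``q`` and are therefore
positively correlated, with intraclass correlation ``rho = phi / (1 + phi)``
(equivalently ``1 / (a + b + 1)``) and count variance

    Var[k] = n p (1 - p) (1 + (n - 1) rho).

``phi = 0`` is accepted as the exact Binomial limit (no mixing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import binom as _binom

__all__ = [
    "BetaBinomParams",
    "OverdispersionLevel",
    "mean_to_shapes",
    "betabinom_logpmf",
    "betabinom_sample",
    "betabinom_moments",
]


@dataclass(frozen=True)
class BetaBinomParams:
    """Shape pair (a, b) of the mixing Beta distribution."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"Beta shape a must be positive, got {self.a}")
        if not (self.b > 0):
            raise ValueError(f"Beta shape b must be positive, got {self.b}")

    @property
    def mean(self) -> float:
        """Mean success probability a / (a + b)."""
        return self.a / (self.a + self.b)

    @property
    def intraclass_correlation(self) -> float:
        """Within-observation trial correlation, 1 / (a + b + 1)."""
        return 1.0 / (self.a + self.b + 1.0)


@dataclass(frozen=True)
class OverdispersionLevel:
    """Overdispersion magnitude for one generating mechanism.

    Exactly one of the two fields is active per mechanism: ``phi`` for the
    Beta-Binomial mixture, ``sigma_eps`` for logit-scale Normal noise added
    to the linear predictor (the overdispersed-Binomial mechanism).  Both
    default to zero, i.e. no overdispersion.
    """

    phi: float = 0.0
    sigma_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError(f"phi must be nonnegative, got {self.phi}")
        if self.sigma_eps < 0:
            raise ValueError(f"sigma_eps must be nonnegative, got {self.sigma_eps}")
        if self.phi > 0 and self.sigma_eps > 0:
            raise ValueError(
                "at most one of phi and sigma_eps may be positive; "
                f"got phi={self.phi}, sigma_eps={self.sigma_eps}"
            )


def mean_to_shapes(p: float, phi: float) -> BetaBinomParams:
    """Convert a mean probability and dispersion to Beta shapes.

    Parameters
    ----------
    p : float
        Mean success probability, strictly inside (0, 1).
    phi : float
        Dispersion parameter, strictly positive.

    Returns
    -------
    BetaBinomParams
        Shapes ``a = p / phi`` and ``b = (1 - p) / phi``.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got p={p}")
    if not (phi > 0.0):
        raise ValueError(f"phi must be strictly positive, got phi={phi}")
    return BetaBinomParams(a=p / phi, b=(1.0 - p) / phi)


def logpmf_ab(k, n, a, b):
    """Vectorized Beta-Binomial log-pmf given Beta shapes.

    log [ C(n, k) * B(k + a, n - k + b) / B(a, b) ], evaluated entirely via
    log-gamma so that shapes far below 1 (strong overdispersion) do not
    underflow.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    coef = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    return coef + betaln(k + a, n - k + b) - betaln(a, b)


def betabinom_logpmf(k: int, n: int, params: BetaBinomParams) -> float:
    """Log-probability of ``k`` successes in ``n`` trials."""
    return float(logpmf_ab(k, n, params.a, params.b))


def betabinom_sample(n, p: float, phi: float, rng: np.random.Generator):
    """Draw Beta-Binomial counts.

    ``phi = 0`` short-circuits to a plain Binomial(n, p) draw; otherwise the
    two-stage draw q ~ Beta(a, b), k ~ Binomial(n, q).  ``n`` may be a
    scalar or an array; ``p`` may be an array of matching shape.
    """
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("n must be nonnegative")
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValueError("p must lie strictly in (0, 1)")
    if phi < 0:
        raise ValueError(f"phi must be nonnegative, got {phi}")
    if phi == 0.0:
        draw = rng.binomial(n, p_arr)
    else:
        q = rng.beta(p_arr / phi, (1.0 - p_arr) / phi)
        draw = rng.binomial(n, q)
    if np.ndim(draw) == 0:
        return int(draw)
    return draw


def betabinom_moments(n: int, p: float, phi: float) -> tuple[float, float]:
    """Mean and variance of the Beta-Binomial count.

    mean = n p; variance = n p (1-p) [1 + (n-1) rho] with
    rho = phi / (1 + phi).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got p={p}")
    if phi < 0:
        raise ValueError(f"phi must be nonnegative, got {phi}")
    rho = phi / (1.0 + phi)
    mean = n * p
    var = n * p * (1.0 - p) * (1.0 + (n - 1.0) * rho)
    return mean, var


def binom_logpmf(k, n, p):
    """Vectorized Binomial log-pmf (thin scipy wrapper used by the fitters)."""
    return _binom.logpmf(k, n, p)
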