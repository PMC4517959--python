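import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import betabinom as scipy_betabinom, binom

from odglmm.betabinom import (
    BetaBinomParams,
    OverdispersionLevel,
    betabinom_logpmf,
    betabinom_moments,
    betabinom_sample,
    mean_to_shapes,
)

GRID_N = (1, 2, 5, 10)
GRID_P = (0.05, 0.27, 0.5, 0.9)
GRID_PHI = (0.01, 0.1, 1.0, 2.0)


class TestMeanToShapes:
    @pytest.mark.parametrize(
        "p, phi, a, b",
        [
            (0.5, 0.5, 1.0, 1.0),
            (0.5, 1.0, 0.5, 0.5),
            (expit(-1.0), 2.0, 0.13447071068499755, 0.36552928931500245),
        ],
    )
    def test_examples(self, p, phi, a, b):
        params = mean_to_shapes(p, phi)
        assert params.a == pytest.approx(a, abs=1e-12)
        assert params.b == pytest.approx(b, abs=1e-12)

    @given(
        p=st.floats(1e-6, 1 - 1e-6),
        phi=st.floats(1e-6, 50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_mean_roundtrip(self, p, phi):
        """The Beta mean a/(a+b) reproduces the construction p."""
        params = mean_to_shapes(p, phi)
        assert params.mean == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_p_domain_error_names_argument(self, p):
        with pytest.raises(ValueError, match="p"):
            mean_to_shapes(p, 1.0)

    @pytest.mark.parametrize("phi", [0.0, -1.0])
    def test_phi_domain_error_names_argument(self, phi):
        with pytest.raises(ValueError, match="phi"):
            mean_to_shapes(0.5, phi)

    def test_shapes_must_be_positive(self):
        with pytest.raises(ValueError):
            BetaBinomParams(a=-1.0, b=2.0)


class TestLogpmf:
    def test_uniform_mixing(self):
        """Beta(1,1) mixing makes every count 0..n equally likely."""
        params = BetaBinomParams(1.0, 1.0)
        for k in range(6):
            assert betabinom_logpmf(k, 5, params) == pytest.approx(
                math.log(1 / 6), abs=1e-12
            )

    def test_jeffreys_shapes_closed_form(self):
        params = BetaBinomParams(0.5, 0.5)
        assert betabinom_logpmf(0, 2, params) == pytest.approx(math.log(0.375), abs=1e-12)
        assert betabinom_logpmf(1, 2, params) == pytest.approx(math.log(0.25), abs=1e-12)

    def test_binomial_limit(self):
        params = mean_to_shapes(0.3, 1e-8)
        ref = binom.logpmf(2, 5, 0.3)
        assert betabinom_logpmf(2, 5, params) == pytest.approx(ref, abs=1e-6)

    def test_domain_errors(self):
        params = BetaBinomParams(1.0, 1.0)
        with pytest.raises(ValueError):
            betabinom_logpmf(6, 5, params)
        with pytest.raises(ValueError):
            betabinom_logpmf(-1, 5, params)

    @pytest.mark.parametrize("n", GRID_N)
    @pytest.mark.parametrize("p", GRID_P)
    @pytest.mark.parametrize("phi", GRID_PHI)
    def test_normalization(self, n, p, phi):
        params = mean_to_shapes(p, phi)
        total = sum(math.exp(betabinom_logpmf(k, n, params)) for k in range(n + 1))
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("n,p,phi", [(5, 0.27, 2.0), (10, 0.05, 0.1), (2, 0.9, 1.0)])
    def test_agrees_with_scipy(self, n, p, phi):
        """Independent library implementation of the same compound pmf."""
        params = mean_to_shapes(p, phi)
        for k in range(n + 1):
            ref = scipy_betabinom.logpmf(k, n, params.a, params.b)
            assert betabinom_logpmf(k, n, params) == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("n,p,phi", [(5, 0.5, 0.5), (5, 0.27, 2.0), (10, 0.9, 0.01)])
    def test_agrees_with_numerical_integration(self, n, p, phi):
        """pmf equals the Binomial pmf integrated over the Beta mixing density.

        The Beta density's endpoint singularities q^(a-1), (1-q)^(b-1) are
        handled exactly by the algebraic-weight quadrature, leaving a smooth
        polynomial integrand.
        """
        from scipy.integrate import quad
        from scipy.special import beta as beta_fn, comb

        params = mean_to_shapes(p, phi)
        a, b = params.a, params.b
        for k in range(n + 1):
            smooth = lambda q: comb(n, k) * q**k * (1 - q) ** (n - k) / beta_fn(a, b)
            ref, err = quad(
                smooth, 0.0, 1.0, weight="alg", wvar=(a - 1.0, b - 1.0),
                epsabs=1e-12, epsrel=1e-12,
            )
            assert err < 1e-9
            assert math.exp(betabinom_logpmf(k, n, params)) == pytest.approx(
                ref, abs=1e-8
            )


class TestSampling:
    def test_zero_trials(self, rng):
        assert betabinom_sample(0, 0.3, 1.0, rng) == 0

    def test_uniform_case_empirical_pmf(self, rng):
        draws = betabinom_sample(np.full(100_000, 5), np.full(100_000, 0.5), 0.5, rng)
        freq = np.bincount(draws, minlength=6) / 100_000
        se = math.sqrt((1 / 6) * (5 / 6) / 100_000)
        assert np.all(np.abs(freq - 1 / 6) < 3 * se)

    def test_empirical_variance_matches_moments(self, rng):
        n_draw = 100_000
        draws = betabinom_sample(np.full(n_draw, 5), np.full(n_draw, 0.269), 2.0, rng)
        _, var = betabinom_moments(5, 0.269, 2.0)
        # MC SE of a sample variance ~ var * sqrt(2/(n-1)) is conservative here;
        # use the fourth-moment-free bound 3 * var * sqrt(2/n)
        assert abs(draws.var() - var) < 3 * var * math.sqrt(2 / n_draw)

    def test_phi_zero_is_binomial(self):
        d1 = betabinom_sample(10, 0.3, 0.0, np.random.default_rng(5))
        d2 = np.random.default_rng(5).binomial(10, 0.3)
        assert d1 == d2


class TestMoments:
    @pytest.mark.parametrize(
        "n,p,phi,mean,var",
        [
            (5, 0.5, 0.0, 2.5, 1.25),
            (5, 0.5, 0.5, 2.5, 1.25 * (1 + 4 / 3)),
            (1, 0.3, 7.0, 0.3, 0.21),
        ],
    )
    def test_examples(self, n, p, phi, mean, var):
        m, v = betabinom_moments(n, p, phi)
        assert m == pytest.approx(mean, abs=1e-12)
        assert v == pytest.approx(var, abs=1e-10)

    def test_variance_matches_pmf_summation(self):
        n, p, phi = 5, 0.5, 0.5
        params = mean_to_shapes(p, phi)
        ks = np.arange(n + 1)
        pmf = np.exp([betabinom_logpmf(k, n, params) for k in ks])
        mean = (ks * pmf).sum()
        var = ((ks - mean) ** 2 * pmf).sum()
        m, v = betabinom_moments(n, p, phi)
        assert m == pytest.approx(mean, abs=1e-10)
        assert v == pytest.approx(var, abs=1e-10)

    @given(
        phi1=st.floats(0.0, 10.0),
        dphi=st.floats(1e-3, 5.0),
        p=st.floats(0.05, 0.95),
        n=st.integers(2, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_variance_increases_with_phi(self, phi1, dphi, p, n):
        _, v1 = betabinom_moments(n, p, phi1)
        _, v2 = betabinom_moments(n, p, phi1 + dphi)
        assert v2 > v1


class TestOverdispersionLevel:
    def test_rejects_both_positive(self):
        with pytest.raises(ValueError):
            OverdispersionLevel(phi=1.0, sigma_eps=1.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            OverdispersionLevel(phi=-0.1)
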