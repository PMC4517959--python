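import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from odglmm.betabinom import OverdispersionLevel
from odglmm.datagen import (
    Dataset,
    ScenarioConfig,
    TruthParams,
    inv_logit,
    linear_predictor,
    read_dataset,
    simulate_covariates,
    simulate_dataset,
    write_dataset,
)


def _config(**kw):
    defaults = dict(
        mechanism="od_binomial",
        overdispersion=OverdispersionLevel(),
        n_populations=3,
        n_per_population=20,
        clutch_size=5,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestInvLogit:
    def test_zero_is_half(self):
        assert inv_logit(0.0) == pytest.approx(0.5, abs=1e-15)

    def test_minus_one(self):
        assert inv_logit(-1.0) == pytest.approx(0.2689414213699951, abs=1e-12)

    @given(x=st.floats(-30, 30))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, x):
        assert inv_logit(x) + inv_logit(-x) == pytest.approx(1.0, abs=1e-12)

    def test_bodysize_span_is_about_four_points(self):
        """A -0.01 slope across the bodysize range moves the hatch rate ~4%."""
        span = inv_logit(-1 + 0.1) - inv_logit(-1 - 0.1)
        assert span == pytest.approx(0.039, abs=0.002)


class TestCovariates:
    def test_balanced_labels(self, rng):
        covs = simulate_covariates(_config(), rng)
        assert len(covs) == 60
        counts = covs["population"].value_counts()
        assert sorted(counts.index) == [0, 1, 2]
        assert (counts == 20).all()

    def test_reproducible(self):
        c1 = simulate_covariates(_config(), np.random.default_rng(9))
        c2 = simulate_covariates(_config(), np.random.default_rng(9))
        assert c1.equals(c2)

    def test_bodysize_range(self, rng):
        covs = simulate_covariates(_config(n_per_population=2000), rng)
        assert covs["bodysize"].min() >= -10
        assert covs["bodysize"].max() <= 10


class TestLinearPredictor:
    def test_degenerate_equals_mu(self, rng):
        covs = simulate_covariates(_config(), rng)
        covs["prey"] = 0.0
        covs["bodysize"] = 0.0
        truth = TruthParams(sigma_pop=0.0)
        eta = linear_predictor(covs, truth, np.full(3, truth.mu_pop))
        assert np.allclose(eta, -1.0)

    def test_single_row_arithmetic(self, rng):
        covs = simulate_covariates(_config(n_populations=1, n_per_population=1), rng)
        covs["prey"] = 1.0
        covs["bodysize"] = 0.0
        eta = linear_predictor(covs, TruthParams(), np.array([-1.0]))
        assert eta[0] == pytest.approx(-0.4, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        covs = simulate_covariates(_config(), rng)
        alphas = np.array([-1.2, -0.8, -1.0])
        eta = linear_predictor(covs, TruthParams(), alphas)
        perm = rng.permutation(len(covs))
        eta_p = linear_predictor(covs.iloc[perm].reset_index(drop=True), TruthParams(), alphas)
        assert np.allclose(eta[perm], eta_p)

    def test_intercept_count_mismatch(self, rng):
        covs = simulate_covariates(_config(), rng)
        with pytest.raises(ValueError):
            linear_predictor(covs, TruthParams(), np.zeros(2))


class TestSimulateDataset:
    def test_scenario_shape_and_bounds(self, rng):
        cfg = _config(
            mechanism="beta_binomial",
            overdispersion=OverdispersionLevel(phi=2.0),
            n_populations=10,
        )
        ds = simulate_dataset(cfg, rng)
        assert ds.n_rows == 200
        assert (ds.frame["hatched"] >= 0).all()
        assert (ds.frame["hatched"] <= 5).all()
        assert len(ds.pop_intercepts) == 10

    def test_mean_rate_at_degenerate_truth(self, rng):
        truth = TruthParams(sigma_pop=0.0, beta_prey=0.0, beta_bodysize=0.0)
        cfg = _config(n_populations=1, n_per_population=10_000, truth=truth)
        ds = simulate_dataset(cfg, rng)
        rate = (ds.frame["hatched"] / ds.frame["clutch"]).mean()
        p = expit(-1.0)
        se = math.sqrt(p * (1 - p) / (10_000 * 5))
        assert abs(rate - p) < 3 * se

    def test_mechanism_exclusivity_enforced(self):
        with pytest.raises(ValueError):
            _config(mechanism="beta_binomial", overdispersion=OverdispersionLevel(sigma_eps=1.0))
        with pytest.raises(ValueError):
            _config(mechanism="od_binomial", overdispersion=OverdispersionLevel(phi=1.0))
        with pytest.raises(ValueError):
            _config(mechanism="poisson")

    def test_od_population_mean_spread_grows_with_sigma_eps(self):
        """Logit-scale spread of per-population rates tracks the noise ladder."""
        spreads = []
        for i, sig in enumerate((0.1, 1.5, 3.0)):
            cfg = _config(
                overdispersion=OverdispersionLevel(sigma_eps=sig),
                n_populations=200,
                n_per_population=50,
                truth=TruthParams(sigma_pop=0.0, beta_prey=0.0, beta_bodysize=0.0),
            )
            ds = simulate_dataset(cfg, np.random.default_rng(40 + i))
            rates = ds.frame.groupby("population")["hatched"].sum() / (50 * 5)
            spreads.append(np.var(logit(np.clip(rates, 0.01, 0.99))))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_bb_variance_inflation_factor(self):
        """Per-row variance exceeds Binomial by 1 + (c-1) phi/(1+phi)."""
        phi, c = 2.0, 5
        truth = TruthParams(sigma_pop=0.0, beta_prey=0.0, beta_bodysize=0.0)
        cfg = _config(
            mechanism="beta_binomial",
            overdispersion=OverdispersionLevel(phi=phi),
            n_populations=1,
            n_per_population=200_000,
            truth=truth,
        )
        ds = simulate_dataset(cfg, np.random.default_rng(41))
        h = ds.frame["hatched"].to_numpy()
        p = expit(-1.0)
        inflation = h.var() / (c * p * (1 - p))
        expected = 1 + (c - 1) * phi / (1 + phi)
        assert inflation == pytest.approx(expected, rel=0.03)


class TestCsvRoundTrip:
    def test_round_trip(self, rng, tmp_path):
        ds = simulate_dataset(_config(), rng)
        path = tmp_path / "d.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.frame.equals(ds.frame[back.frame.columns])
        assert path.read_text().splitlines()[0] == "population,prey,bodysize,clutch,hatched"

    def test_invalid_hatched_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "population,prey,bodysize,clutch,hatched\n0,0.1,1.0,5,3\n0,0.2,2.0,5,6\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_dataset(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("population,prey,clutch,hatched\n0,0.1,5,3\n")
        with pytest.raises(ValueError, match="bodysize"):
            read_dataset(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_dataset(path)
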