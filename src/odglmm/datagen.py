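"""Simulated clutch-hatching datasets under two overdispersion mechanisms.

The study system is a clutch-success design: individual ``i`` from
population ``j(i)`` lays a clutch of ``c_i`` eggs of which ``h_i`` hatch.
The hatch probability follows a logit-linear model with a population random
intercept,

    logit(p_i) = alpha_{j(i)} + beta_prey * Prey_i + beta_bodysize * Bodysize_i,
    alpha_j ~ Normal(mu_pop, sigma_pop^2),

and overdispersion enters through one of two mechanisms:

* ``od_binomial`` — an observation-level Normal(0, sigma_eps^2) term is
  added to the linear predictor before the Binomial draw;
* ``beta_binomial`` — the Binomial success probability is drawn from a
  Beta with mean ``p_i`` and dispersion ``phi`` (see :mod:`odglmm.betabinom`).

Default truth: mu_pop = -1, sigma_pop = 0.5, beta_prey = 0.6,
beta_bodysize = -0.01.  Prey is standard normal; Bodysize is uniform on
[-10, 10], so the -0.01 slope spans about 0.2 logits across the bodysize
range — roughly a 4-percentage-point difference in hatch rate around the
grand mean.  Both covariate laws are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .betabinom import OverdispersionLevel, betabinom_sample

__all__ = [
    "TruthParams",
    "ScenarioConfig",
    "Dataset",
    "inv_logit",
    "simulate_covariates",
    "linear_predictor",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

CSV_COLUMNS = ["population", "prey", "bodysize", "clutch", "hatched"]

MECHANISMS = ("beta_binomial", "od_binomial")


@dataclass(frozen=True)
class TruthParams:
    """Fixed generating values on the logit scale."""

    mu_pop: float = -1.0
    sigma_pop: float = 0.5
    beta_prey: float = 0.6
    beta_bodysize: float = -0.01

    def __post_init__(self) -> None:
        if self.sigma_pop < 0:
            raise ValueError(f"sigma_pop must be nonnegative, got {self.sigma_pop}")


def _default_prey(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.standard_normal(size)


def _default_bodysize(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(-10.0, 10.0, size)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: mechanism, overdispersion level and design.

    The balanced design has ``n_populations`` populations with
    ``n_per_population`` individuals each, every individual laying a clutch
    of exactly ``clutch_size`` eggs.
    """

    mechanism: str = "beta_binomial"
    overdispersion: OverdispersionLevel = field(default_factory=OverdispersionLevel)
    n_populations: int = 10
    n_per_population: int = 20
    clutch_size: int = 5
    truth: TruthParams = field(default_factory=TruthParams)
    seed: int = 0
    prey_law: Callable[[np.random.Generator, int], np.ndarray] = _default_prey
    bodysize_law: Callable[[np.random.Generator, int], np.ndarray] = _default_bodysize

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.n_per_population < 1:
            raise ValueError("n_per_population must be >= 1")
        if self.clutch_size < 1:
            raise ValueError("clutch_size must be >= 1")
        if self.mechanism == "beta_binomial" and self.overdispersion.sigma_eps > 0:
            raise ValueError("beta_binomial mechanism uses phi, not sigma_eps")
        if self.mechanism == "od_binomial" and self.overdispersion.phi > 0:
            raise ValueError("od_binomial mechanism uses sigma_eps, not phi")

    @property
    def n_rows(self) -> int:
        return self.n_populations * self.n_per_population

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass
class Dataset:
    """Per-individual records plus, when simulated, the latent intercepts."""

    frame: pd.DataFrame
    config: ScenarioConfig | None = None
    pop_intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        validate_frame(self.frame)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def populations(self) -> np.ndarray:
        """Population labels in order of first appearance."""
        return self.frame["population"].unique()

    def design_arrays(self):
        """(pop_index, prey, bodysize, clutch, hatched) as numpy arrays.

        ``pop_index`` maps each row to 0..J-1 in order of first appearance.
        Cached after the first call; the frame must not be mutated afterwards.
        """
        cached = getattr(self, "_arrays", None)
        if cached is not None:
            return cached
        pops = self.populations
        lookup = {p: i for i, p in enumerate(pops)}
        idx = self.frame["population"].map(lookup).to_numpy()
        arrays = (
            idx,
            self.frame["prey"].to_numpy(dtype=float),
            self.frame["bodysize"].to_numpy(dtype=float),
            self.frame["clutch"].to_numpy(dtype=int),
            self.frame["hatched"].to_numpy(dtype=int),
        )
        object.__setattr__(self, "_arrays", arrays)
        return arrays


def validate_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    if len(frame) == 0:
        raise ValueError("dataset has no rows")
    bad = frame.index[
        (frame["hatched"] < 0)
        | (frame["hatched"] > frame["clutch"])
        | (frame["clutch"] < 1)
    ]
    if len(bad) > 0:
        row = int(bad[0])
        raise ValueError(
            f"row {row}: hatched must satisfy 0 <= hatched <= clutch and clutch >= 1 "
            f"(hatched={frame.loc[row, 'hatched']}, clutch={frame.loc[row, 'clutch']})"
        )


def inv_logit(x):
    """Logistic function 1 / (1 + exp(-x)); maps the linear predictor to (0, 1)."""
    return expit(x)


def simulate_covariates(
    config: ScenarioConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the covariate columns for one balanced dataset.

    Returns a frame with ``population`` (0..J-1, n_per_population consecutive
    rows each), ``prey`` and ``bodysize``.
    """
    n = config.n_rows
    population = np.repeat(np.arange(config.n_populations), config.n_per_population)
    prey = np.asarray(config.prey_law(rng, n), dtype=float)
    bodysize = np.asarray(config.bodysize_law(rng, n), dtype=float)
    return pd.DataFrame(
        {"population": population, "prey": prey, "bodysize": bodysize}
    )


def linear_predictor(
    covariates: pd.DataFrame, truth: TruthParams, pop_intercepts: np.ndarray
) -> np.ndarray:
    """logit_i = alpha_{j(i)} + beta_prey * Prey_i + beta_bodysize * Bodysize_i."""
    pops = covariates["population"].unique()
    if len(pop_intercepts) != len(pops):
        raise ValueError(
            f"expected one intercept per population ({len(pops)}), "
            f"got {len(pop_intercepts)}"
        )
    lookup = {p: i for i, p in enumerate(pops)}
    idx = covariates["population"].map(lookup).to_numpy()
    return (
        np.asarray(pop_intercepts, dtype=float)[idx]
        + truth.beta_prey * covariates["prey"].to_numpy(dtype=float)
        + truth.beta_bodysize * covariates["bodysize"].to_numpy(dtype=float)
    )


def simulate_dataset(config: ScenarioConfig, rng: np.random.Generator | None = None) -> Dataset:
    """Simulate one dataset under the configured mechanism.

    Draws population intercepts alpha_j ~ Normal(mu_pop, sigma_pop^2), forms
    the linear predictor, then draws hatched counts either by adding
    observation-level logit noise (od_binomial) or through the Beta-Binomial
    mixture (beta_binomial).  The latent intercepts are retained on the
    returned Dataset.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    covs = simulate_covariates(config, rng)
    truth = config.truth
    alphas = rng.normal(truth.mu_pop, truth.sigma_pop, config.n_populations)
    eta = linear_predictor(covs, truth, alphas)
    clutch = np.full(config.n_rows, config.clutch_size, dtype=int)

    if config.mechanism == "od_binomial":
        eps = rng.normal(0.0, config.overdispersion.sigma_eps, config.n_rows)
        hatched = rng.binomial(clutch, inv_logit(eta + eps))
    elif config.mechanism == "beta_binomial":
        hatched = betabinom_sample(
            clutch, inv_logit(eta), config.overdispersion.phi, rng
        )
    else:  # pragma: no cover - guarded by ScenarioConfig
        raise ValueError(f"unknown mechanism {config.mechanism!r}")

    frame = covs.assign(clutch=clutch, hatched=np.asarray(hatched, dtype=int))
    return Dataset(frame=frame, config=config, pop_intercepts=alphas)


def write_dataset(dataset: Dataset, path) -> None:
    """Write the dataset as CSV with the fixed header (lossless floats)."""
    dataset.frame[CSV_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> Dataset:
    """Read a dataset CSV, enforcing the column contract and row invariants."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty, not a dataset") from None
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("clutch", "hatched"):
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else 0
            raise ValueError(f"{path}: row {row}: column {col!r} is not numeric")
    return Dataset(frame=frame[CSV_COLUMNS])
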