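"""Synthetic trial-level data with the hierarchical structure the method
assumes.

Participant true means are drawn Normal(M, sigma_b); each participant's
trials scatter Normal(mu_i, sigma_w_i) around their own mean.  The
within-participant SD can be a single fixed value or itself vary across
participants (normal or gamma), which is how real datasets behave; a
correlated two-condition variant generates paired designs with a chosen
between-condition correlation; a Bernoulli outcome mode produces binary
choice data whose per-participant probability is the (clamped) true mean.

Everything is seeded through ``numpy.random.default_rng`` and
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PowerGrid
from .subsample import TrialTable

__all__ = [
    "WithinSDDistribution",
    "GeneratorSpec",
    "generate_hierarchical",
    "generate_correlated_pair",
    "power_curves_by_within_dist",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WithinSDDistribution:
    """How the within-participant SD varies across participants.

    kind='fixed'  : every participant shares ``value``.
    kind='normal' : sigma_w_i ~ Normal(mean, sd), resampled while below
                    ``floor`` (default 1% of the mean) so SDs stay
                    strictly positive.
    kind='gamma'  : sigma_w_i ~ Gamma(shape, scale).
    """

    kind: str
    value: float | None = None
    mean: float | None = None
    sd: float | None = None
    shape: float | None = None
    scale: float | None = None
    floor: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.value is None or self.value < 0:
                raise ValueError("fixed distribution needs value >= 0")
        elif self.kind == "normal":
            if self.mean is None or self.sd is None or self.mean <= 0 \
                    or self.sd <= 0:
                raise ValueError("normal distribution needs mean > 0, sd > 0")
            if self.floor is not None and self.floor <= 0:
                raise ValueError("truncation floor must be positive")
        elif self.kind == "gamma":
            if self.shape is None or self.scale is None or self.shape <= 0 \
                    or self.scale <= 0:
                raise ValueError("gamma distribution needs shape, scale > 0")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    @classmethod
    def fixed(cls, value: float) -> "WithinSDDistribution":
        return cls(kind="fixed", value=value)

    @classmethod
    def normal(cls, mean: float, sd: float,
               floor: float | None = None) -> "WithinSDDistribution":
        return cls(kind="normal", mean=mean, sd=sd, floor=floor)

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "WithinSDDistribution":
        return cls(kind="gamma", shape=shape, scale=scale)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw per-participant within-SD values (strictly positive)."""
        if self.kind == "fixed":
            return np.full(size, float(self.value))
        if self.kind == "normal":
            floor = self.floor if self.floor is not None else 0.01 * self.mean
            out = rng.normal(self.mean, self.sd, size)
            bad = out < floor
            while bad.any():  # truncate by resampling below the floor
                out[bad] = rng.normal(self.mean, self.sd, int(bad.sum()))
                bad = out < floor
            return out
        return rng.gamma(self.shape, self.scale, size)

    def mean_value(self) -> float:
        if self.kind == "fixed":
            return float(self.value)
        if self.kind == "normal":
            return float(self.mean)
        return float(self.shape * self.scale)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full specification of one synthetic dataset."""

    n: int
    k: int
    mean_effect: float
    sigma_b: float
    within: WithinSDDistribution
    rho: float = 0.0
    drift: float = 0.0  # linear trend of the participant mean, units/trial
    outcome: str = "continuous"  # continuous | bernoulli
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.k < 1:
            raise ValueError("n and k must be positive")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")
        if self.outcome not in ("continuous", "bernoulli"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def _records(participant_ids, condition: str, values: np.ndarray):
    n, k = values.shape
    return pd.DataFrame({
        "participant": np.repeat(participant_ids, k),
        "condition": condition,
        "trial": np.tile(np.arange(k), n),
        "value": values.ravel(),
    })


def _trial_values(mu: np.ndarray, spec: GeneratorSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Trials for participants with true means ``mu`` (shape (n,))."""
    n, k = mu.size, spec.k
    if spec.outcome == "bernoulli":
        p = np.clip(mu, 0.0, 1.0)
        n_clamped = int(np.sum((mu < 0) | (mu > 1)))
        if n_clamped:
            logger.info("clamped %d participant probabilities to [0, 1]",
                        n_clamped)
        return rng.binomial(1, p[:, None], size=(n, k)).astype(float)
    sigma_w = spec.within.sample(n, rng)
    drift_term = spec.drift * np.arange(k)
    return (mu[:, None] + drift_term[None, :]
            + rng.normal(0.0, 1.0, (n, k)) * sigma_w[:, None])


def generate_hierarchical(spec: GeneratorSpec) -> TrialTable:
    """One-condition hierarchical dataset.

    mu_i ~ Normal(M, sigma_b); trial t of participant i ~
    Normal(mu_i + drift*t, sigma_w_i); Bernoulli outcome instead draws
    binary trials at probability clip(mu_i, 0, 1).
    """
    rng = np.random.default_rng(spec.seed)
    mu = rng.normal(spec.mean_effect, spec.sigma_b, spec.n)
    values = _trial_values(mu, spec, rng)
    ids = [f"p{i:04d}" for i in range(spec.n)]
    return TrialTable(_records(ids, "A", values))


def generate_correlated_pair(spec: GeneratorSpec) -> TrialTable:
    """Two-condition paired dataset with between-condition correlation rho.

    Per participant the pair of condition true means is bivariate normal
    with means (0, M), common SD sigma_b and correlation rho.  sigma_b and
    sigma_w are held fixed across rho, so only the covariance term moves
    and the total variance of each condition stays constant; higher rho
    shrinks the variance of difference scores, which is what a paired
    analysis discounts.
    """
    rng = np.random.default_rng(spec.seed)
    cov = spec.rho * spec.sigma_b**2
    cov_matrix = np.array([[spec.sigma_b**2, cov], [cov, spec.sigma_b**2]])
    mu_pair = rng.multivariate_normal([0.0, spec.mean_effect], cov_matrix,
                                      size=spec.n)
    frames = []
    ids = [f"p{i:04d}" for i in range(spec.n)]
    for j, cond in enumerate(("A", "B")):
        values = _trial_values(mu_pair[:, j], spec, rng)
        frames.append(_records(ids, cond, values))
    return TrialTable(pd.concat(frames, ignore_index=True))


def power_curves_by_within_dist(
    dist_specs: Sequence[WithinSDDistribution],
    n_values: Sequence[int],
    k_values: Sequence[int],
    mean_effect: float,
    sigma_b: float,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[PowerGrid]:
    """Rejection-rate power for several within-SD distributions.

    For each distribution and each (N, k) cell, ``reps`` fresh datasets
    are drawn and a two-sided one-sample t test is run on the participant
    means; the cell records the rejection rate.  Participant means are
    simulated directly as Normal(mu_i, sigma_w_i/sqrt(k)), which is the
    exact distribution of a k-trial average under the generator, so the
    curves are identical in law to aggregating full trial tables.  All
    grids share the lattice; one child seed per (distribution, cell).
    """
    n_arr = np.asarray(n_values, dtype=int)
    k_arr = np.asarray(k_values, dtype=int)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(dist_specs) * n_arr.size * k_arr.size)
    grids = []
    for s, dist in enumerate(dist_specs):
        power = np.empty((n_arr.size, k_arr.size))
        for i, n in enumerate(n_arr):
            for j, k in enumerate(k_arr):
                idx = (s * n_arr.size + i) * k_arr.size + j
                rng = np.random.default_rng(children[idx])
                mu = rng.normal(mean_effect, sigma_b, (reps, n))
                sw = dist.sample(reps * n, rng).reshape(reps, n)
                means = mu + rng.normal(0, 1, (reps, n)) * sw / np.sqrt(k)
                m = means.mean(axis=1)
                sd = means.std(axis=1, ddof=1)
                t_stat = m / (sd / np.sqrt(n))
                p = 2 * stats.t.sf(np.abs(t_stat), n - 1)
                power[i, j] = float(np.mean(p < alpha))
        grids.append(PowerGrid(
            n_arr.copy(), k_arr.copy(), power, alpha=alpha,
            test_label=f"simulated_t:{dist.kind}", reps=reps, seed=seed,
        ))
    return grids
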