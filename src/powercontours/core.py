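"""Closed-form power analysis over the (sample size, trials) plane.

The central quantity is the sample standard deviation of per-participant
means.  When each of N participants contributes the mean of k noisy trials,
that SD decomposes into a between-participants component sigma_b and a
within-participant component sigma_w shrunk by the number of trials:

    sigma_s = sqrt(sigma_b**2 + sigma_w**2 / k)

Cohen's d is the mean effect divided by sigma_s, so d -- and hence the
power of a one-sample (or paired, on difference scores) t test -- is a
joint function of N and k.  This module evaluates that function on integer
lattices, extracts iso-power contours, and searches for cost-optimal
designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VarianceModel",
    "SampleStats",
    "PowerGrid",
    "ContourPath",
    "DesignPoint",
    "ImaginaryResultError",
    "InfeasibleDesignError",
    "sample_sd",
    "between_sd",
    "sample_se",
    "cohens_d",
    "t_power",
    "analytic_power_grid",
    "extract_contour",
    "optimal_design",
]


class ImaginaryResultError(ValueError):
    """sqrt of a negative radicand when inverting the variance composition.

    Raised by :func:`between_sd` when ``sigma_w**2 / k`` exceeds
    ``sigma_s**2``, i.e. the observed sample SD is smaller than the
    within-participant contribution alone can explain.  Callers building
    summary tables conventionally fall back to ``sigma_b := sigma_s``.
    """


class InfeasibleDesignError(ValueError):
    """No (N, k) pair within the search bounds reaches the target power."""


@dataclass(frozen=True)
class VarianceModel:
    """Population parameters driving all analytic power computations.

    Parameters
    ----------
    mean_effect : float
        Group mean effect M, in units of the dependent variable.  Sign
        encodes direction.
    sigma_b : float
        Between-participants SD of true means, same units.
    sigma_w : float
        (Average) within-participant trial-to-trial SD, same units.
    """

    mean_effect: float
    sigma_b: float
    sigma_w: float

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_w < 0:
            raise ValueError("sigma_b and sigma_w must be non-negative")

    def sample_sd(self, k: int) -> float:
        return sample_sd(self.sigma_b, self.sigma_w, k)

    def cohens_d(self, k: int) -> float:
        return cohens_d(self.mean_effect, self.sample_sd(k))


@dataclass(frozen=True)
class SampleStats:
    """Observed summary statistics of per-participant means."""

    mean_effect: float
    sigma_s: float
    se_s: float
    d: float
    n: int
    k: int


@dataclass
class PowerGrid:
    """Power over an (N, k) lattice with its provenance.

    ``power[i, j]`` is the power at ``n_values[i]`` participants and
    ``k_values[j]`` trials per participant.  ``reps == 0`` marks an
    analytic grid; Monte-Carlo grids carry their iteration count and seed.
    Missing cells (no valid Monte-Carlo iteration) are NaN.
    """

    n_values: np.ndarray
    k_values: np.ndarray
    power: np.ndarray
    alpha: float = 0.05
    test_label: str = "one_sample_t"
    reps: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.n_values.size, self.k_values.size):
            raise ValueError(
                f"power matrix shape {self.power.shape} does not match "
                f"({self.n_values.size}, {self.k_values.size})"
            )
        finite = self.power[np.isfinite(self.power)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("power values must lie in [0, 1]")


@dataclass
class ContourPath:
    """Locus of (n, k) pairs achieving a target power within a grid.

    ``points`` are ordered by k; n is linearly interpolated between the
    bracketing grid rows and is therefore real-valued.
    """

    target_power: float
    points: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.points:
            return np.empty(0), np.empty(0)
        arr = np.asarray(self.points, dtype=float)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class DesignPoint:
    """A cost-optimal study design.

    ``cost`` is the per-participant recruitment overhead expressed in
    trial-equivalents; the objective minimised is ``n * (k + cost)``.
    """

    n: int
    k: int
    cost: float
    objective: float
    achieved_power: float


def _check_positive_int(value, name: str) -> None:
    arr = np.asarray(value)
    if not np.all(arr >= 1) or not np.all(arr == np.floor(arr)):
        raise ValueError(f"{name} must be a positive integer, got {value!r}")


def sample_sd(sigma_b: float, sigma_w: float, k: int) -> float:
    """Sample SD of participant means: sqrt(sigma_b^2 + sigma_w^2 / k).

    Strictly decreasing in k when sigma_w > 0, with limit sigma_b as the
    number of trials grows.
    """
    _check_positive_int(k, "k")
    if sigma_b < 0 or sigma_w < 0:
        raise ValueError("standard deviations must be non-negative")
    return math.sqrt(sigma_b**2 + sigma_w**2 / k)


def between_sd(sigma_s: float, sigma_w: float, k: int) -> float:
    """Invert the variance composition: sqrt(sigma_s^2 - sigma_w^2 / k).

    Raises
    ------
    ImaginaryResultError
        When the radicand is negative, i.e. the within-participant
        contribution alone exceeds the observed sample variance.
    """
    _check_positive_int(k, "k")
    if sigma_s < 0 or sigma_w < 0:
        raise ValueError("standard deviations must be non-negative")
    radicand = sigma_s**2 - sigma_w**2 / k
    if radicand < 0:
        raise ImaginaryResultError(
            f"sigma_s^2 - sigma_w^2/k = {radicand:.6g} < 0; "
            "between-participants SD is imaginary"
        )
    return math.sqrt(radicand)


def sample_se(sigma_b: float, sigma_w: float, k: int, n: int) -> float:
    """Standard error of the group mean: sample_sd / sqrt(N).

    Equivalently sqrt(sigma_b^2/N + sigma_w^2/(k N)), making explicit that
    precision depends on both the sample size and the number of trials.
    """
    _check_positive_int(n, "n")
    return sample_sd(sigma_b, sigma_w, k) / math.sqrt(n)


def cohens_d(mean_effect: float, sigma_s: float) -> float:
    """Standardised effect size d = M / sigma_s (sign-preserving)."""
    if sigma_s <= 0:
        raise ValueError(f"sigma_s must be positive, got {sigma_s}")
    return mean_effect / sigma_s


def t_power(d, n, alpha: float = 0.05, tails: str = "two"):
    """Power of a one-sample t test at effect size d and sample size n.

    Computed from the noncentral t distribution with df = n - 1 and
    noncentrality d * sqrt(n), against the central-t critical value at
    ``alpha``.  A paired design on difference scores is mathematically the
    same test.  The one-tailed variant assumes the test is directed with
    the effect (noncentrality |d| * sqrt(n)).

    Accepts scalars or broadcastable arrays for ``d`` and ``n``; returns a
    float for scalar input.  At d = 0 the power equals alpha exactly.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    d_arr = np.asarray(d, dtype=float)
    n_arr = np.asarray(n)
    if np.any(n_arr < 2) or np.any(n_arr != np.floor(n_arr)):
        raise ValueError("n must be an integer >= 2")
    d_b, n_b = np.broadcast_arrays(d_arr, n_arr.astype(float))
    df = n_b - 1.0
    nc = np.abs(d_b) * np.sqrt(n_b)
    if tails == "two":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        lower = stats.nct.cdf(-tcrit, df, nc)
        # scipy's noncentral t loses the (negligible) far lower tail for
        # large noncentrality; treat it as exactly zero there
        lower = np.where(np.isnan(lower) & (nc > 2), 0.0, lower)
        upper = stats.nct.sf(tcrit, df, nc)
        upper = np.where(np.isnan(upper) & (nc > 2), 1.0, upper)
        power = upper + lower
    else:
        tcrit = stats.t.ppf(1 - alpha, df)
        power = stats.nct.sf(tcrit, df, nc)
        power = np.where(np.isnan(power) & (nc > 2), 1.0, power)
    # exact null calibration: noncentrality 0 reduces to the central t
    power = np.where(d_b == 0.0, alpha, power)
    power = np.clip(power, 0.0, 1.0)
    if np.isscalar(d) and np.isscalar(n):
        return float(power)
    return power


def analytic_power_grid(
    model: VarianceModel,
    n_values: Sequence[int],
    k_values: Sequence[int],
    alpha: float = 0.05,
    tails: str = "two",
) -> PowerGrid:
    """Closed-form power over an (N, k) lattice.

    Each cell is ``t_power(M / sample_sd(sigma_b, sigma_w, k), n)``.
    ``n_values`` and ``k_values`` must be non-empty and strictly
    increasing.
    """
    n_arr = np.asarray(n_values, dtype=int)
    k_arr = np.asarray(k_values, dtype=int)
    for name, arr in (("n_values", n_arr), ("k_values", k_arr)):
        if arr.size == 0:
            raise ValueError(f"{name} must be non-empty")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError(f"{name} must be strictly increasing")
    _check_positive_int(k_arr, "k_values")
    if np.any(n_arr < 2):
        raise ValueError("all n_values must be >= 2")
    sigma_s = np.sqrt(model.sigma_b**2 + model.sigma_w**2 / k_arr)
    if np.any(sigma_s <= 0):
        raise ValueError("degenerate model: sigma_s = 0 (both SDs zero)")
    d = model.mean_effect / sigma_s  # shape (k,)
    power = t_power(d[np.newaxis, :], n_arr[:, np.newaxis], alpha, tails)
    return PowerGrid(n_arr, k_arr, power, alpha=alpha, reps=0,
                     test_label=f"analytic_t_{tails}_tailed")


def extract_contour(grid: PowerGrid, target_power: float) -> ContourPath:
    """Trace the iso-power contour at ``target_power`` through a grid.

    For each k column the crossing n is found by linear interpolation of
    power against n between the bracketing grid rows (power is treated as
    monotone in n; the first upward crossing is used).  Columns that never
    reach the target, or whose bracketing cells are missing, contribute no
    point.  Points are ordered by k.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    points: list[tuple[float, float]] = []
    n_vals = grid.n_values.astype(float)
    for j, k in enumerate(grid.k_values):
        col = grid.power[:, j]
        if not np.isfinite(col[0]):
            continue
        if col[0] >= target_power:
            # already above target at the smallest n: the crossing lies
            # below the grid, so only an exact hit on the boundary counts
            if col[0] == target_power:
                points.append((n_vals[0], float(k)))
            continue
        for i in range(1, col.size):
            if not np.isfinite(col[i]):
                break
            if col[i] >= target_power:
                lo, hi = col[i - 1], col[i]
                frac = 0.0 if hi == lo else (target_power - lo) / (hi - lo)
                n_cross = n_vals[i - 1] + frac * (n_vals[i] - n_vals[i - 1])
                points.append((float(n_cross), float(k)))
                break
    return ContourPath(target_power=target_power, points=points)


def _min_feasible_n(model: VarianceModel, k: int, target: float,
                    alpha: float, tails: str, n_max: int) -> int | None:
    """Smallest integer n in [2, n_max] with analytic power >= target."""
    d = model.cohens_d(k)
    if t_power(d, n_max, alpha, tails) < target:
        return None
    lo, hi = 2, n_max
    while lo < hi:
        mid = (lo + hi) // 2
        if t_power(d, mid, alpha, tails) >= target:
            hi = mid
        else:
            lo = mid + 1
    return lo


def optimal_design(
    model: VarianceModel,
    cost: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
    tails: str = "two",
    n_max: int = 1000,
    k_max: int = 1000,
) -> DesignPoint:
    """Cheapest (N, k) design achieving the target power.

    Minimises ``n * (k + cost)`` over the integer lattice
    ``2 <= n <= n_max``, ``1 <= k <= k_max`` subject to analytic power
    >= ``target_power``.  ``cost`` is the recruitment overhead per
    participant in trial-equivalents.  Ties are broken by smaller n, then
    smaller k.  Since power is monotone in n, only the minimal feasible n
    per k needs to be examined.
    """
    if cost < 0:
        raise ValueError("cost must be non-negative")
    if n_max < 2 or k_max < 1:
        raise ValueError("search bounds must allow n >= 2, k >= 1")
    best: tuple[float, int, int] | None = None  # (objective, n, k)
    for k in range(1, k_max + 1):
        n = _min_feasible_n(model, k, target_power, alpha, tails, n_max)
        if n is None:
            continue
        objective = n * (k + cost)
        key = (objective, n, k)
        if best is None or key < best:
            best = key
    if best is None:
        raise InfeasibleDesignError(
            f"no (n <= {n_max}, k <= {k_max}) reaches power {target_power}"
        )
    objective, n, k = best
    return DesignPoint(
        n=n, k=k, cost=cost, objective=objective,
        achieved_power=t_power(model.cohens_d(k), n, alpha, tails),
    )
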