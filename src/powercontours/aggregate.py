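"""Trial-to-summary aggregators and participant-level tests.

The subsampling engine is paradigm-agnostic: what changes between reaction
times, choice proportions, steady-state EEG amplitudes and fMRI betas is
(a) how a participant's trials collapse to one number and (b) which test
runs on the participant summaries.  Both plug points are registered here
by name.

Complex-valued trials (e.g. Fourier amplitudes with phase) support two
averaging schemes.  Coherent averaging takes the modulus of the complex
mean, so non-phase-locked noise cancels across trials; incoherent
averaging takes the mean of moduli and retains a noise floor.  The
triangle inequality guarantees incoherent >= coherent for any input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "mean_aggregator",
    "paired_difference",
    "coherent_mean",
    "incoherent_mean",
    "one_sample_t",
    "rm_anova_oneway",
    "AGGREGATORS",
    "TESTS",
    "get_aggregator",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a participant-level significance test."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    alpha: float
    significant: bool


def _as_nonempty(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def mean_aggregator(values: Sequence[float]) -> float:
    """Arithmetic mean of a participant's trial values."""
    return float(_as_nonempty(values).real.mean()) if np.iscomplexobj(
        np.asarray(values)
    ) else float(_as_nonempty(values).mean())


def coherent_mean(values: Sequence[complex]) -> float:
    """Modulus of the complex mean (amplitude and phase averaged jointly)."""
    return float(np.abs(_as_nonempty(values).astype(complex).mean()))


def incoherent_mean(values: Sequence[complex]) -> float:
    """Mean of moduli (phase discarded before averaging)."""
    return float(np.abs(_as_nonempty(values).astype(complex)).mean())


def paired_difference(values_a, values_b,
                      aggregator: Callable = mean_aggregator) -> float:
    """Per-participant condition difference: agg(a) - agg(b)."""
    _as_nonempty(values_a, "values_a")
    _as_nonempty(values_b, "values_b")
    return aggregator(values_a) - aggregator(values_b)


# axis-aware implementations used by the vectorised subsampling engine;
# each maps an array of trials to real summaries along `axis`
def _mean_axis(arr: np.ndarray, axis: int) -> np.ndarray:
    out = arr.mean(axis=axis)
    return out.real if np.iscomplexobj(out) else out


def _coherent_axis(arr: np.ndarray, axis: int) -> np.ndarray:
    return np.abs(arr.mean(axis=axis))


def _incoherent_axis(arr: np.ndarray, axis: int) -> np.ndarray:
    return np.abs(arr).mean(axis=axis)


AGGREGATORS: dict[str, Callable] = {
    "mean": mean_aggregator,
    "coherent_mean": coherent_mean,
    "incoherent_mean": incoherent_mean,
}

_AXIS_AGGREGATORS: dict[str, Callable] = {
    "mean": _mean_axis,
    "coherent_mean": _coherent_axis,
    "incoherent_mean": _incoherent_axis,
}


def get_aggregator(key: str, axis_aware: bool = False) -> Callable:
    table = _AXIS_AGGREGATORS if axis_aware else AGGREGATORS
    try:
        return table[key]
    except KeyError:
        raise KeyError(
            f"unknown aggregator {key!r}; available: {sorted(AGGREGATORS)}"
        ) from None


def one_sample_t(values: Sequence[float], mu0: float = 0.0,
                 alpha: float = 0.05, tails: str = "two") -> TestResult:
    """One-sample t test of participant summaries against ``mu0``.

    A paired test is the same computation on per-participant difference
    scores with ``mu0 = 0``.  Degenerate zero-variance input raises rather
    than returning an infinite statistic.
    """
    arr = _as_nonempty(values).astype(float)
    n = arr.size
    if n < 2:
        raise ValueError("one_sample_t requires at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    t_stat = (arr.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    if tails == "two":
        p = 2 * stats.t.sf(abs(t_stat), df)
    elif tails == "one":
        p = stats.t.sf(t_stat, df)
    else:
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    p = float(min(p, 1.0))
    return TestResult(statistic=float(t_stat), df=float(df), p_value=p,
                      alpha=alpha, significant=p < alpha)


def _rm_anova_F(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-subjects one-way F over the last two axes (subjects, conditions).

    Accepts a stack of matrices: shape (..., n, c).  Returns (F, ss_err)
    so callers can detect degenerate zero-residual inputs.
    """
    n, c = data.shape[-2], data.shape[-1]
    grand = data.mean(axis=(-2, -1), keepdims=True)
    subj_mean = data.mean(axis=-1, keepdims=True)
    cond_mean = data.mean(axis=-2, keepdims=True)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_subj = c * ((subj_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_total = ((data - grand) ** 2).sum(axis=(-2, -1))
    ss_err = np.maximum(ss_total - ss_cond - ss_subj, 0.0)
    df_cond = c - 1
    df_err = (c - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df_cond) / (ss_err / df_err)
    return F, ss_err


def rm_anova_oneway(data, alpha: float = 0.05) -> TestResult:
    """One-way repeated-measures ANOVA on a participants x conditions matrix.

    Uses the standard within-subjects decomposition (subject, condition and
    residual sums of squares) with df = (c - 1, (c - 1)(n - 1)).  No
    sphericity correction is applied.  With two conditions F equals the
    square of the paired t statistic.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("data must be a 2-D participants x conditions matrix")
    n, c = arr.shape
    if n < 2 or c < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if not np.all(np.isfinite(arr)):
        raise ValueError("incomplete matrix: non-finite entries present")
    F, ss_err = _rm_anova_F(arr)
    if ss_err == 0:
        raise ValueError("zero residual variance: F statistic undefined")
    df = (float(c - 1), float((c - 1) * (n - 1)))
    p = float(stats.f.sf(F, df[0], df[1]))
    return TestResult(statistic=float(F), df=df, p_value=p,
                      alpha=alpha, significant=p < alpha)


TESTS: dict[str, Callable] = {
    "one_sample_t": one_sample_t,
    "rm_anova_oneway": rm_anova_oneway,
}
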