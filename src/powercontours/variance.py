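"""Variance-component estimation.

Three routes to the within/between decomposition:

* ``pooled_within_sd`` -- direct: pool trial variances across conditions
  within each participant, average across participants, take the root.
* ``between_sd_with_fallback`` -- invert the variance composition from an
  observed sample SD; when the radicand is negative (the within
  contribution alone exceeds the sample variance) fall back to
  sigma_b := sigma_s.
* ``fit_sigma_w`` -- indirect, for paradigms where the per-participant
  summary comes from a model fit (thresholds, coherent averages, GLM
  betas) and no trial-level SD exists: sweep candidate sigma_w values,
  rebuild the analytic power surface for each, and keep the candidate
  whose surface best matches a subsampled one.  The fitted value is the
  SD of a power-equivalent design using plain trial averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (ImaginaryResultError, PowerGrid, VarianceModel,
                   analytic_power_grid, between_sd)
from .subsample import TrialTable

__all__ = [
    "VarianceEstimate",
    "FanoPair",
    "pooled_within_sd",
    "between_sd_with_fallback",
    "fit_sigma_w",
    "fano_factors",
]


@dataclass(frozen=True)
class VarianceEstimate:
    """An estimated variance decomposition and how it was obtained."""

    sigma_w_hat: float
    sigma_b_hat: float
    method: str  # pooled | surface_fit | eq2 | fallback_sigma_s
    fit_loss: float | None = None


@dataclass(frozen=True)
class FanoPair:
    """Within/between variances scaled by the mean effect.

    Dividing each variance by |M| puts paradigms with different units on
    a common footing; fano_w > fano_b indicates that adding trials buys
    real power.
    """

    fano_w: float
    fano_b: float


def pooled_within_sd(table: TrialTable,
                     conditions: Sequence | None = None) -> float:
    """Within-participant SD pooled across conditions and participants.

    Per participant, trial variances of the named conditions are pooled
    weighting by within-cell degrees of freedom (n_trials - 1); the
    pooled variances are then averaged across participants and the square
    root returned.  Every participant x condition cell needs >= 2 trials.
    """
    conditions = list(conditions or table.conditions)
    sub = table.data[table.data["condition"].isin(conditions)]
    pooled = []
    for p, grp in sub.groupby("participant"):
        num = 0.0
        den = 0
        for c in conditions:
            vals = grp.loc[grp["condition"] == c, "value"].to_numpy()
            if np.iscomplexobj(vals):
                vals = vals.real
            if vals.size < 2:
                raise ValueError(
                    f"participant {p}, condition {c!r}: need >= 2 trials "
                    "to estimate a variance"
                )
            num += vals.var(ddof=1) * (vals.size - 1)
            den += vals.size - 1
        pooled.append(num / den)
    return float(np.sqrt(np.mean(pooled)))


def between_sd_with_fallback(sigma_s: float, sigma_w: float,
                             k: int) -> VarianceEstimate:
    """Between-participants SD from the inverted composition, with fallback.

    When the inversion would be imaginary (estimated sigma_w too large
    relative to the observed sigma_s), returns sigma_b := sigma_s with
    method 'fallback_sigma_s' -- the convention used when tabulating
    decompositions across paradigms.
    """
    try:
        b = between_sd(sigma_s, sigma_w, k)
        return VarianceEstimate(sigma_w_hat=sigma_w, sigma_b_hat=b,
                                method="eq2")
    except ImaginaryResultError:
        return VarianceEstimate(sigma_w_hat=sigma_w, sigma_b_hat=sigma_s,
                                method="fallback_sigma_s")


def _surface_loss(subsampled: PowerGrid, sigma_w: float, mean_effect: float,
                  sigma_s: float, k_full: int, alpha: float) -> float:
    """Mean squared power difference between analytic and subsampled grids."""
    est = between_sd_with_fallback(sigma_s, sigma_w, k_full)
    model = VarianceModel(mean_effect, est.sigma_b_hat, sigma_w)
    analytic = analytic_power_grid(model, subsampled.n_values,
                                   subsampled.k_values, alpha=alpha)
    diff = analytic.power - subsampled.power
    finite = np.isfinite(diff)
    if not finite.any():
        return np.nan
    return float(np.mean(diff[finite] ** 2))


def fit_sigma_w(subsampled: PowerGrid, mean_effect: float, sigma_s: float,
                k_full: int, candidates: Sequence[float],
                alpha: float = 0.05, refine: bool = False,
                refine_tol: float = 1e-3) -> VarianceEstimate:
    """Estimate sigma_w by matching analytic to subsampled power surfaces.

    For each candidate sigma_w, sigma_b is derived by inverting the
    variance composition at the full trial count ``k_full`` (falling back
    to sigma_b := sigma_s when imaginary), the analytic surface is built
    on the subsampled grid's own lattice, and the candidate is scored by
    the mean squared power difference over non-missing cells.  The
    loss-minimising candidate is returned; with ``refine=True`` a
    golden-section search between the bracketing candidates sharpens the
    estimate.
    """
    cand = np.asarray(list(candidates), dtype=float)
    if cand.size == 0:
        raise ValueError("candidates must be non-empty")
    if np.any(cand <= 0):
        raise ValueError("candidate sigma_w values must be positive")
    cand = np.sort(cand)
    losses = np.array([
        _surface_loss(subsampled, w, mean_effect, sigma_s, k_full, alpha)
        for w in cand
    ])
    if not np.isfinite(losses).any():
        raise RuntimeError("all candidates produced degenerate surfaces")
    best_idx = int(np.nanargmin(losses))
    best_w = float(cand[best_idx])
    best_loss = float(losses[best_idx])

    if refine and cand.size >= 3 and 0 < best_idx < cand.size - 1:
        lo, hi = cand[best_idx - 1], cand[best_idx + 1]
        invphi = (np.sqrt(5.0) - 1) / 2
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = _surface_loss(subsampled, c, mean_effect, sigma_s, k_full, alpha)
        fd = _surface_loss(subsampled, d, mean_effect, sigma_s, k_full, alpha)
        while b - a > refine_tol:
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = _surface_loss(subsampled, c, mean_effect, sigma_s,
                                   k_full, alpha)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = _surface_loss(subsampled, d, mean_effect, sigma_s,
                                   k_full, alpha)
        w_ref = float((a + b) / 2)
        loss_ref = _surface_loss(subsampled, w_ref, mean_effect, sigma_s,
                                 k_full, alpha)
        if loss_ref < best_loss:
            best_w, best_loss = w_ref, float(loss_ref)

    final = between_sd_with_fallback(sigma_s, best_w, k_full)
    method = ("fallback_sigma_s" if final.method == "fallback_sigma_s"
              else "surface_fit")
    return VarianceEstimate(sigma_w_hat=best_w,
                            sigma_b_hat=final.sigma_b_hat,
                            method=method, fit_loss=best_loss)


def fano_factors(mean_effect: float, sigma_w: float,
                 sigma_b: float) -> FanoPair:
    """Variances scaled by |mean effect|: (sigma_w^2/|M|, sigma_b^2/|M|)."""
    if mean_effect == 0:
        raise ValueError("Fano factors are undefined for a zero mean effect")
    m = abs(mean_effect)
    return FanoPair(fano_w=sigma_w**2 / m, fano_b=sigma_b**2 / m)
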