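"""Monte-Carlo power estimation by subsampling trial-level data.

Given a full dataset in long format (participant, condition, trial,
value), the engine emulates smaller experiments by repeatedly drawing
n_sub participants and k_sub trials per participant *without replacement*,
collapsing each participant's drawn trials with an aggregator, and scoring
power either directly from the subsample's effect size (noncentral-t
power at the observed d, the computationally efficient route) or as the
rejection rate of an explicit test across iterations (required when no
d-to-power formula applies, e.g. repeated-measures ANOVA).

Averaged over many iterations this yields an empirical power surface over
the (N, k) lattice that can be compared with, or used in place of, the
closed-form surface from :mod:`powercontours.core`.

Trial-selection modes
---------------------
random      k_sub trials drawn uniformly without replacement per
            participant x condition.
sequential  the first k_sub trials in recorded order, preserving
            learning / non-stationarity effects.
fraction    ceil(fraction x available) random trials per participant,
            for datasets where trial counts differ across participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import AGGREGATORS, _AXIS_AGGREGATORS, _rm_anova_F
from .core import PowerGrid, SampleStats, t_power

__all__ = [
    "TrialTable",
    "SubsampleConfig",
    "subsample_once",
    "subsample_grid",
    "summary_table",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("participant", "condition", "trial", "value")


@dataclass
class TrialTable:
    """Long-format per-trial observations.

    One row per (participant, condition, trial); ``value`` may be real or
    complex.  Trial indices must be unique within each participant x
    condition cell; their order is meaningful for sequential subsampling.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"TrialTable is missing columns: {missing}")
        if self.data.empty:
            raise ValueError("TrialTable must contain at least one record")
        dupes = self.data.duplicated(["participant", "condition", "trial"])
        if dupes.any():
            first = self.data[dupes].iloc[0]
            raise ValueError(
                "duplicate (participant, condition, trial) key: "
                f"({first['participant']}, {first['condition']}, "
                f"{first['trial']})"
            )

    @property
    def participants(self) -> list:
        return sorted(self.data["participant"].unique().tolist())

    @property
    def conditions(self) -> list:
        return sorted(self.data["condition"].unique().tolist())

    @property
    def n_participants(self) -> int:
        return self.data["participant"].nunique()

    def trial_counts(self, conditions: Sequence | None = None) -> pd.DataFrame:
        """Participants x conditions table of available trial counts."""
        conditions = list(conditions or self.conditions)
        sub = self.data[self.data["condition"].isin(conditions)]
        counts = sub.pivot_table(index="participant", columns="condition",
                                 values="trial", aggfunc="count",
                                 fill_value=0)
        return counts.reindex(columns=conditions)

    def to_dense(self, conditions: Sequence | None = None):
        """Pack values into a (P, C, T_max) array padded with NaN.

        Trials are ordered by trial index within each cell.  Returns
        (values, counts, participant_ids) with counts shaped (P, C).
        """
        conditions = list(conditions or self.conditions)
        sub = self.data[self.data["condition"].isin(conditions)]
        if sub.empty:
            raise ValueError(f"no records for conditions {conditions}")
        participants = sorted(sub["participant"].unique().tolist())
        counts = self.trial_counts(conditions).reindex(participants)
        if (counts.to_numpy() == 0).any():
            bad = counts[(counts == 0).any(axis=1)].index.tolist()
            raise ValueError(
                f"participants {bad} lack trials in some of {conditions}"
            )
        t_max = int(counts.to_numpy().max())
        is_complex = np.iscomplexobj(sub["value"].to_numpy())
        dtype = complex if is_complex else float
        values = np.full((len(participants), len(conditions), t_max),
                         np.nan, dtype=dtype)
        p_pos = {p: i for i, p in enumerate(participants)}
        c_pos = {c: j for j, c in enumerate(conditions)}
        ordered = sub.sort_values(["participant", "condition", "trial"])
        p_codes = ordered["participant"].map(p_pos).to_numpy()
        c_codes = ordered["condition"].map(c_pos).to_numpy()
        slots = ordered.groupby(["participant", "condition"]).cumcount()
        values[p_codes, c_codes, slots.to_numpy()] = \
            ordered["value"].to_numpy()
        return values, counts.to_numpy().astype(int), participants


@dataclass
class SubsampleConfig:
    """Parameters of a Monte-Carlo subsampling run.

    ``summary_bounds``, when set, excludes per-participant effect scores
    outside [lo, hi] from an iteration (mirroring the rejection of
    implausible fitted summaries); exclusions are logged.  ``fraction`` is
    required for trial_mode='fraction'.  ``k_multipliers`` optionally
    scales the nominal k per condition (e.g. a condition with three times
    as many trials as the grid's k axis).
    """

    reps: int = 10_000
    alpha: float = 0.05
    trial_mode: str = "random"  # random | sequential | fraction
    power_method: str = "effect_size"  # effect_size | rejection_rate
    seed: int = 0
    aggregator: str = "mean"
    test: str = "one_sample_t"
    mu0: float = 0.0
    tails: str = "two"
    fraction: float | None = None
    summary_bounds: tuple[float, float] | None = None
    k_multipliers: Mapping | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.trial_mode not in ("random", "sequential", "fraction"):
            raise ValueError(f"unknown trial_mode {self.trial_mode!r}")
        if self.power_method not in ("effect_size", "rejection_rate"):
            raise ValueError(f"unknown power_method {self.power_method!r}")
        if self.trial_mode == "fraction":
            if self.fraction is None or not 0 < self.fraction <= 1:
                raise ValueError("fraction mode requires fraction in (0, 1]")
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.test not in ("one_sample_t", "rm_anova_oneway"):
            raise ValueError(f"unknown test {self.test!r}")


def _masked_aggregate(values: np.ndarray, mask: np.ndarray,
                      k: np.ndarray, key: str) -> np.ndarray:
    """Aggregate selected trials (mask over last axis) to real summaries."""
    if key == "mean":
        picked = np.where(mask, np.nan_to_num(values), 0)
        out = picked.sum(axis=-1) / k
        return out.real if np.iscomplexobj(out) else out
    if key == "coherent_mean":
        picked = np.where(mask, np.nan_to_num(values), 0)
        return np.abs(picked.sum(axis=-1) / k)
    if key == "incoherent_mean":
        picked = np.where(mask, np.nan_to_num(np.abs(values)), 0.0)
        return picked.sum(axis=-1) / k
    raise KeyError(f"aggregator {key!r} has no vectorised form")


def _effective_k(counts_sel: np.ndarray, k_sub, cfg: SubsampleConfig,
                 conditions: Sequence) -> np.ndarray:
    """Per (rep, participant, condition) number of trials to draw."""
    if cfg.trial_mode == "fraction":
        k = np.ceil(cfg.fraction * counts_sel).astype(int)
    else:
        k = np.full_like(counts_sel, int(k_sub))
        if cfg.k_multipliers:
            for j, cond in enumerate(conditions):
                mult = cfg.k_multipliers.get(cond, 1.0)
                k[..., j] = max(1, int(round(k_sub * mult)))
    if np.any(k > counts_sel):
        raise ValueError(
            "requested trials exceed availability for some participant; "
            f"max request {k.max()} vs min available {counts_sel.min()}"
        )
    return k


def _draw_participants(rng: np.random.Generator, P: int, n_sub: int,
                       r: int) -> np.ndarray:
    """r independent without-replacement subsets of size n_sub from P.

    When the subset is small relative to the pool, draws with replacement
    and rejects rows containing collisions (uniform over distinct
    n-tuples, hence over subsets); otherwise partial sorts random keys.
    """
    if n_sub == P:
        return np.broadcast_to(np.arange(P), (r, P))
    if n_sub * n_sub * 4 < P:  # collision probability < ~12% per row
        idx = rng.integers(0, P, (r, n_sub))
        while True:
            dup = (np.diff(np.sort(idx, axis=1), axis=1) == 0).any(axis=1)
            if not dup.any():
                return idx
            idx[dup] = rng.integers(0, P, (int(dup.sum()), n_sub))
    keys = rng.random((r, P))
    return np.argpartition(keys, n_sub - 1, axis=1)[:, :n_sub]


def _cell_estimates(values: np.ndarray, counts: np.ndarray,
                    n_sub: int, k_sub, cfg: SubsampleConfig,
                    conditions: Sequence, rng: np.random.Generator,
                    reps: int) -> np.ndarray:
    """Per-iteration power estimates (or rejection indicators) for a cell.

    Fully vectorised over iterations: trial selection uses random sort
    keys (padded slots forced last), so each participant's draw is a
    uniform without-replacement subset of their own available trials.
    """
    P, C, T = values.shape
    if n_sub > P:
        raise ValueError(f"n_sub={n_sub} exceeds {P} available participants")
    out = np.full(reps, np.nan)
    # chunk iterations so the (reps, n_sub, C, T) workspaces stay modest
    chunk = max(1, int(8e6 / max(1, n_sub * C * T)))
    done = 0
    excluded_total = 0
    while done < reps:
        r = min(chunk, reps - done)
        p_idx = _draw_participants(rng, P, n_sub, r)
        counts_sel = counts[p_idx]                       # (r, n_sub, C)
        k_eff = _effective_k(counts_sel, k_sub, cfg, conditions)
        v_sel = values[p_idx]                            # (r, n_sub, C, T)
        uniform_k = k_eff.min() == k_eff.max()
        if cfg.trial_mode == "sequential":
            if uniform_k:
                kk = int(k_eff.max())
                S = _AXIS_AGGREGATORS[cfg.aggregator](v_sel[..., :kk], -1)
            else:
                mask = np.arange(T) < k_eff[..., None]
                S = _masked_aggregate(v_sel, mask, k_eff, cfg.aggregator)
        else:
            keys = rng.random((r, n_sub, C, T))
            keys[np.arange(T) >= counts_sel[..., None]] = np.inf
            if uniform_k:
                kk = int(k_eff.max())
                if kk == T:
                    picked = v_sel
                else:
                    t_idx = np.argpartition(keys, kk - 1, axis=-1)[..., :kk]
                    picked = np.take_along_axis(v_sel, t_idx, axis=-1)
                S = _AXIS_AGGREGATORS[cfg.aggregator](picked, -1)
            else:
                rank = np.argsort(np.argsort(keys, axis=-1), axis=-1)
                mask = rank < k_eff[..., None]
                S = _masked_aggregate(v_sel, mask, k_eff, cfg.aggregator)

        if cfg.test == "rm_anova_oneway":
            if C < 2:
                raise ValueError("rm_anova_oneway needs >= 2 conditions")
            F, ss_err = _rm_anova_F(S)
            p = stats.f.sf(F, C - 1, (C - 1) * (n_sub - 1))
            est = np.where(ss_err > 0, (p < cfg.alpha).astype(float), np.nan)
            out[done:done + r] = est
            done += r
            continue

        if C == 1:
            x = S[:, :, 0] - cfg.mu0
        elif C == 2:
            x = (S[:, :, 0] - S[:, :, 1]) - cfg.mu0
        else:
            raise ValueError(
                "one_sample_t path supports 1 or 2 conditions, got "
                f"{C}; use rm_anova_oneway for more"
            )
        if cfg.summary_bounds is not None:
            lo, hi = cfg.summary_bounds
            bad = (x < lo) | (x > hi)
            excluded_total += int(bad.sum())
            x = np.where(bad, np.nan, x)
        n_eff = np.isfinite(x).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.nanmean(x, axis=1)
            sd = np.nanstd(x, axis=1, ddof=1)
        valid = (n_eff >= 2) & (sd > 0)
        est = np.full(r, np.nan)
        if valid.any():
            if cfg.power_method == "effect_size":
                d = m[valid] / sd[valid]
                est[valid] = t_power(d, n_eff[valid], cfg.alpha, cfg.tails)
            else:
                t_stat = m[valid] / (sd[valid] / np.sqrt(n_eff[valid]))
                df = n_eff[valid] - 1
                if cfg.tails == "two":
                    p = 2 * stats.t.sf(np.abs(t_stat), df)
                else:
                    p = stats.t.sf(t_stat, df)
                est[valid] = (p < cfg.alpha).astype(float)
        out[done:done + r] = est
        done += r
    if excluded_total:
        logger.info("excluded %d out-of-bounds participant summaries",
                    excluded_total)
    return out


def subsample_once(table: TrialTable, n_sub: int, k_sub,
                   config: SubsampleConfig,
                   conditions: Sequence | None = None) -> float:
    """A single subsampling draw.

    Returns the effect-size power estimate of the draw, or a 0/1
    rejection indicator under the rejection_rate method.
    """
    conditions = list(conditions or table.conditions)
    values, counts, _ = table.to_dense(conditions)
    rng = np.random.default_rng(config.seed)
    est = _cell_estimates(values, counts, n_sub, k_sub, config,
                          conditions, rng, reps=1)
    return float(est[0])


def subsample_grid(table: TrialTable, n_values: Sequence[int],
                   k_values: Sequence[int], config: SubsampleConfig,
                   conditions: Sequence | None = None) -> PowerGrid:
    """Estimate power over an (N, k) lattice by repeated subsampling.

    Each cell averages ``config.reps`` independent draws.  A single root
    seed spawns one child stream per cell, so results are bit-reproducible
    and independent of cell evaluation order.  Cells whose iterations all
    fail (e.g. every draw degenerate) become NaN rather than aborting the
    grid.
    """
    conditions = list(conditions or table.conditions)
    values, counts, _ = table.to_dense(conditions)
    n_arr = np.asarray(n_values, dtype=int)
    k_arr = np.asarray(k_values, dtype=int)
    if n_arr.size == 0 or k_arr.size == 0:
        raise ValueError("n_values and k_values must be non-empty")
    if n_arr.max() > values.shape[0]:
        raise ValueError(
            f"largest n {n_arr.max()} exceeds the {values.shape[0]} "
            "participants in the table"
        )
    if config.trial_mode != "fraction" and k_arr.max() > counts.min():
        raise ValueError(
            f"largest k {k_arr.max()} exceeds the minimum availability "
            f"({counts.min()}) across participants"
        )
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n_arr.size * k_arr.size)
    power = np.full((n_arr.size, k_arr.size), np.nan)
    for i, n_sub in enumerate(n_arr):
        for j, k_sub in enumerate(k_arr):
            rng = np.random.default_rng(children[i * k_arr.size + j])
            est = _cell_estimates(values, counts, int(n_sub), int(k_sub),
                                  config, conditions, rng, config.reps)
            if np.isfinite(est).any():
                power[i, j] = np.nanmean(est)
    label = f"{config.aggregator}+{config.test}:{config.power_method}"
    return PowerGrid(n_arr, k_arr, power, alpha=config.alpha,
                     test_label=label, reps=config.reps, seed=config.seed)


def summary_table(table: TrialTable, aggregator: str = "mean",
                  conditions: Sequence | None = None,
                  mu0: float = 0.0) -> tuple[pd.DataFrame, SampleStats]:
    """Per-participant summaries and the full-data sample statistics.

    With one condition the per-participant effect is the aggregated
    summary minus ``mu0``; with two conditions it is the difference of
    aggregated summaries (first minus second) minus ``mu0``.  Returns the
    summary frame and a :class:`SampleStats` with the mean effect, its SD
    across participants (denominator n - 1), the standard error, and
    Cohen's d.
    """
    conditions = list(conditions or table.conditions)
    if len(conditions) not in (1, 2):
        raise ValueError("summary_table supports 1 or 2 conditions")
    agg = AGGREGATORS[aggregator]
    rows = []
    sub = table.data[table.data["condition"].isin(conditions)]
    for p, grp in sub.groupby("participant"):
        entry = {"participant": p}
        for c in conditions:
            vals = grp.loc[grp["condition"] == c, "value"].to_numpy()
            if vals.size == 0:
                raise ValueError(f"participant {p} has no trials in {c!r}")
            entry[str(c)] = agg(vals)
            entry[f"k_{c}"] = vals.size
        if len(conditions) == 1:
            entry["effect"] = entry[str(conditions[0])] - mu0
        else:
            entry["effect"] = (entry[str(conditions[0])]
                               - entry[str(conditions[1])]) - mu0
        rows.append(entry)
    frame = pd.DataFrame(rows)
    if len(frame) < 2:
        raise ValueError("need at least 2 participants for sample statistics")
    eff = frame["effect"].to_numpy(dtype=float)
    n = eff.size
    sigma_s = float(eff.std(ddof=1))
    if sigma_s == 0:
        raise ValueError("zero variance across participant summaries")
    k_cols = frame[[f"k_{c}" for c in conditions]].to_numpy()
    k_typ = int(round(float(np.mean(k_cols))))
    sample_stats = SampleStats(
        mean_effect=float(eff.mean()),
        sigma_s=sigma_s,
        se_s=sigma_s / np.sqrt(n),
        d=float(eff.mean()) / sigma_s,
        n=n,
        k=k_typ,
    )
    return frame, sample_stats
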