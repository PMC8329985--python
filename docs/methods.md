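# Methods

## Model

A repeated-measures experiment is modelled hierarchically. Participant
*i* has a true effect `mu_i ~ Normal(M, sigma_b)`; each of their *k*
trials is observed as `x_it ~ Normal(mu_i, sigma_w_i)`. The sample SD of
participant means then composes as

    sigma_s(k) = sqrt(sigma_b^2 + sigma_w^2 / k),

so the standardised effect `d(k) = M / sigma_s(k)` and, through it, the
power of a two-sided one-sample *t* test at level `alpha` depend jointly
on *N* and *k*:

    power(N, k) = P(|T'| > t_crit),  T' ~ noncentral-t(df = N-1,
                                                       nc = d(k) * sqrt(N))

A paired design is handled on per-participant difference scores, which is
algebraically the same test; accordingly no independent-groups variant is
provided. One-tailed power is computed with the test directed toward the
effect (noncentrality `|d|*sqrt(N)`). At `d = 0` the two-tailed power is
returned as exactly `alpha` (the noncentral distribution degenerates to
the central one, so this is a definition, not an approximation).

Inverting the composition at an observed sample SD,
`sigma_b = sqrt(sigma_s^2 - sigma_w^2/k)`, can produce a negative
radicand when the (estimated) within-SD is large; `between_sd` raises a
distinct `ImaginaryResultError` rather than clamping, and
`between_sd_with_fallback` implements the tabulation convention
`sigma_b := sigma_s` for that case.

## Defaults and units

* `alpha = 0.05`, two-tailed, everywhere; both are explicit parameters.
* All SDs are in the units of the dependent variable; `k` and `N` are
  counts; `cost` (design search) is a per-participant recruitment
  overhead expressed in trial-equivalents, so the objective `N*(k+cost)`
  is total trial-equivalents.
* Grids are evaluated on user-supplied integer lattices; no spacing is
  imposed.

## Contours and design search

Contour extraction interpolates *N* at fixed *k*: within each k column
the first upward crossing of the target power is located and *N* is
linearly interpolated between the bracketing rows. The direction is fixed
(power is monotone in *N*; along *k* it need not be sampled finely
enough to make column-wise interpolation safe in both directions).
Columns that never reach the target contribute no point; missing
(NaN) cells terminate the column scan. The cost search exploits
monotonicity in *N*: for each *k* the minimal feasible *N* is found by
bisection, and ties in the objective are broken by smaller *N*, then
smaller *k* (a convention; ties are otherwise arbitrary).

## The subsampling engine

`subsample_grid` emulates smaller experiments inside an existing dataset:
per iteration it draws `n_sub` participants and, per participant and
condition, `k_sub` trials, both **without replacement** — subsets, not
bootstrap resamples, so a drawn design has exactly the trial budget it
claims. Trials can be drawn uniformly (`random`), as the first `k_sub` in
recorded order (`sequential`, which preserves learning and other
non-stationarities), or as `ceil(fraction * available)` per participant
(`fraction`, for datasets with unequal trial counts). A per-condition
multiplier option scales the nominal k where conditions have unequal
budgets (e.g. a 3:1 trial ratio).

Two power estimators are available:

* `effect_size` (default): compute the subsample's Cohen's *d* and return
  the noncentral-*t* power at (`d_hat`, `n_sub`); cells average this over
  iterations. This mirrors common practice and is cheap, but note it is
  **not** an unbiased estimate of true power: averaging `power(d_hat)`
  over the sampling distribution of `d_hat` incurs a Jensen-type bias of
  up to ~0.1 where the power function is strongly curved (small `n_sub`,
  small effects). We measured this directly by fresh-sample simulation.
* `rejection_rate`: run the test on each subsample and average the
  rejection indicator. This is the unbiased estimator of the power of the
  subsampled design (up to the finite size of the source table) and is
  required for statistics with no d-to-power formula (the rm-ANOVA); all
  internal comparisons against the closed form use it.

Two further finite-data caveats, both verified empirically: (1) the
source table is itself one sample, so every cell inherits the table's
own `d_hat` error — comparisons against population-level closed forms
need a large table (we size reference tables so that
`slope * SE(d_hat) <= 0.015`); (2) when `n_sub` approaches the number of
participants in the table, without-replacement draws concentrate around
the table mean and rejection rates are pushed away from fresh-sample
power — keep `n_sub` well below the pool size when the target is
population power.

Per-participant summaries outside user-set bounds can be excluded per
iteration (mirroring the rejection of implausible fitted summaries);
exclusions are logged and an iteration with fewer than two surviving
participants is dropped. Cells whose iterations all fail become NaN and
are skipped by contour extraction.

Reproducibility: one root `SeedSequence` spawns an independent child
stream per grid cell, so results are bit-identical for a given seed and
independent of evaluation order or chunking.

## Aggregators and tests

Trial-to-summary aggregation and the participant-level test are plug
points registered by name, which is what lets one engine serve reaction
times, choice proportions, evoked amplitudes and betas alike. Complex
trial values support coherent averaging (modulus of the complex mean;
non-phase-locked noise cancels with k) and incoherent averaging (mean of
moduli; a noise floor survives); the triangle inequality makes incoherent
>= coherent always, with equality only at a common phase. The one-way
repeated-measures ANOVA uses the unadjusted univariate F from the
subject/condition/residual decomposition — no sphericity correction —
and reduces exactly to the squared paired t at two conditions. Degenerate
inputs (zero variance, zero residual) raise instead of returning infinite
statistics.

## Variance-component estimation

* `pooled_within_sd`: per participant, condition variances are pooled
  weighted by within-cell degrees of freedom (`n_trials - 1`); pooled
  variances are averaged across participants and rooted. Requires >= 2
  trials per cell.
* `fit_sigma_w`: when the dependent variable is produced by a per-
  participant model fit (thresholds, coherent averages, GLM betas), no
  trial-level SD exists. Candidate `sigma_w` values are scored by the
  mean squared difference between the analytic surface (with `sigma_b`
  re-derived from the observed `sigma_s` at the full trial count, falling
  back to `sigma_b := sigma_s` when imaginary) and the subsampled surface
  on the same lattice, over non-missing cells, unweighted. Mean squared
  power difference is our fixed, documented loss; cells are not weighted
  toward any contour. The canonical estimate is the best grid candidate;
  an optional golden-section refinement between the bracketing candidates
  is off by default so results are exactly reproducible from the
  candidate list. The fitted value is the within-SD of a power-equivalent
  design that uses plain trial averaging, not a property of the raw
  measurement scale.
* `fano_factors` scales both variances by `|M|` (absolute value so the
  factors stay non-negative for negative effects), putting paradigms with
  different units on one plot.

## Synthetic data

The generator emulates the hierarchical structure above, which is what
the analytic theory assumes; passing tests on it demonstrates internal
consistency of the engine and formulas, not that any particular real
paradigm satisfies the assumptions (real data add non-stationarity,
outlier participants, non-normal trial noise, and item effects, none of
which are modelled here beyond linear drift and heavy-tailed sigma_w
distributions).

Per-participant within-SDs may be fixed, Normal(mean, sd) — truncated by
resampling below a floor of 1% of the mean (any positive floor may be
supplied; SDs must stay positive, and the choice of floor is not
critical) — or Gamma(shape, scale). Correlated condition pairs draw the
two true means from a bivariate normal with common SD `sigma_b` and
correlation `rho`; `sigma_b` and `sigma_w` are held fixed while only the
covariance varies, so each condition's total variance is constant across
`rho` and only the difference-score variance moves. Bernoulli outcomes
clamp `mu_i` to [0, 1] on the linear scale (no logit link — choice
probabilities are treated linearly) and log when clamping occurs. Drift
is linear in trial index only. Per-participant sigma_w values are drawn
independently of participant means.

`power_curves_by_within_dist` compares power under different sigma_w
distributions by rejection rate over fresh simulated datasets. It
simulates participant k-trial means directly as
`Normal(mu_i, sigma_w_i / sqrt(k))` — the exact distribution of a k-trial
average under the model — so the curves are identical in law to building
and aggregating full trial tables, at a fraction of the cost.

## Problem sizes used in the test suite

Monte-Carlo checks are sized so the whole suite runs in a few minutes on
one core: the engine/closed-form equivalence uses a 40,000-participant
reference table, a 6x6 lattice spanning N 16–64 and k 10–150, and 6,000
iterations per cell (per-cell binomial SE <= 0.007); null calibrations
use 100,000 (t) and 20,000 (rm-ANOVA) simulations; component recovery
uses N = 200, k = 200 tables, with the between-SD assessed as the mean
over eight replicate tables because a single table determines it only to
~5%.

## Known limitations

* No independent-groups designs, factorial ANOVA, sphericity
  corrections, nonparametric or Bayesian tests.
* No stimulus-item ("crossed") variance component; item variance folds
  into the within/between components.
* The effect-size power method's bias (above) is inherent to that
  estimator; use `rejection_rate` when unbiased power is the point.
* Subsampled surfaces estimate the power supported by the source
  dataset, not the population, to the extent the dataset is small or
  unrepresentative.
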