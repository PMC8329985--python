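"""The Monte-Carlo subsampling engine."""

import numpy as np
import pytest
from scipy import stats

from powercontours import (GeneratorSpec, SubsampleConfig, VarianceModel,
                           WithinSDDistribution, analytic_power_grid,
                           generate_hierarchical, subsample_grid,
                           subsample_once, summary_table, t_power)

from conftest import make_table


@pytest.fixture(scope="module")
def hier_table():
    """Moderate hierarchical dataset: 120 participants, 60 trials."""
    spec = GeneratorSpec(n=120, k=60, mean_effect=1.0, sigma_b=2.0,
                         within=WithinSDDistribution.fixed(10.0), seed=21)
    return generate_hierarchical(spec)


class TestSubsampleOnce:
    def test_full_data_draw_is_deterministic(self, hier_table):
        cfg = SubsampleConfig(seed=0)
        frame, ss = summary_table(hier_table)
        expected = t_power(ss.d, ss.n)
        for seed in (0, 1, 99):
            cfg2 = SubsampleConfig(seed=seed)
            got = subsample_once(hier_table, ss.n, ss.k, cfg2)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_sequential_with_all_trials_equals_random(self, hier_table):
        n_all = hier_table.n_participants
        a = subsample_once(hier_table, n_all, 60,
                           SubsampleConfig(seed=3, trial_mode="random"))
        b = subsample_once(hier_table, n_all, 60,
                           SubsampleConfig(seed=4, trial_mode="sequential"))
        assert a == pytest.approx(b, abs=1e-12)

    def test_requests_beyond_availability_signal(self, hier_table):
        with pytest.raises(ValueError):
            subsample_once(hier_table, 10_000, 5, SubsampleConfig(seed=0))
        with pytest.raises(ValueError):
            subsample_once(hier_table, 5, 10_000, SubsampleConfig(seed=0))


class TestSubsampleGrid:
    def test_same_seed_reproduces_grid_exactly(self, hier_table):
        cfg = SubsampleConfig(reps=200, seed=11)
        g1 = subsample_grid(hier_table, [10, 20], [5, 20], cfg)
        g2 = subsample_grid(hier_table, [10, 20], [5, 20], cfg)
        assert np.array_equal(g1.power, g2.power)
        assert g1.reps == 200 and g1.seed == 11

    def test_null_data_rejection_rate_is_alpha(self):
        spec = GeneratorSpec(n=2000, k=20, mean_effect=0.0, sigma_b=2.0,
                             within=WithinSDDistribution.fixed(5.0), seed=8)
        table = generate_hierarchical(spec)
        cfg = SubsampleConfig(reps=4000, seed=9,
                              power_method="rejection_rate")
        grid = subsample_grid(table, [20], [10], cfg)
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert grid.power[0, 0] == pytest.approx(0.05, abs=3 * se + 0.003)

    def test_effect_size_method_matches_brute_force_oracle(self, hier_table):
        # the effect-size estimator averages t_power(d_hat) over draws;
        # reproduce that estimand directly from participant means
        cfg = SubsampleConfig(reps=3000, seed=13, power_method="effect_size")
        n_sub = 15
        grid = subsample_grid(hier_table, [n_sub], [60], cfg)
        pm = hier_table.data.groupby("participant")["value"].mean()
        pm = pm.to_numpy()
        rng = np.random.default_rng(99)
        draws = np.array([
            rng.choice(pm, n_sub, replace=False) for _ in range(6000)
        ])
        d_hat = draws.mean(axis=1) / draws.std(axis=1, ddof=1)
        oracle = float(np.mean(t_power(d_hat, np.full(d_hat.size, n_sub))))
        spread = float(np.std(t_power(d_hat, np.full(d_hat.size, n_sub))))
        margin = 3 * spread * np.sqrt(1 / 3000 + 1 / 6000)
        assert grid.power[0, 0] == pytest.approx(oracle, abs=margin)

    def test_power_monotone_in_n_and_k(self, hier_table):
        cfg = SubsampleConfig(reps=3000, seed=17,
                              power_method="rejection_rate")
        grid = subsample_grid(hier_table, [10, 30, 90], [5, 15, 45], cfg)
        noise = 4 * np.sqrt(0.25 / 3000)
        assert np.all(np.diff(grid.power, axis=0) > -noise)
        assert np.all(np.diff(grid.power, axis=1) > -noise)

    def test_near_zero_within_variance_gives_vertical_structure(self):
        spec = GeneratorSpec(n=150, k=30, mean_effect=1.0, sigma_b=2.0,
                             within=WithinSDDistribution.fixed(1e-6), seed=5)
        table = generate_hierarchical(spec)
        cfg = SubsampleConfig(reps=500, seed=6)
        grid = subsample_grid(table, [10, 40], [2, 8, 30], cfg)
        # columns should be essentially identical: trials add nothing
        assert np.allclose(grid.power, grid.power[:, [0]], atol=0.02)

    def test_agrees_with_analytic_grid_at_fitted_parameters(self, hier_table):
        # compare against the closed form evaluated at the table's own
        # fitted decomposition, which removes the table-level sampling
        # error of a 120-participant dataset and leaves Monte-Carlo noise
        from powercontours import between_sd, pooled_within_sd
        # n_sub stays well below the pool size: subsampling a large share
        # of the pool concentrates the subsample mean (without-replacement
        # draws) and inflates rejection rates above fresh-sample power
        cfg = SubsampleConfig(reps=3000, seed=23,
                              power_method="rejection_rate")
        grid = subsample_grid(hier_table, [10, 24], [10, 40], cfg)
        _, ss = summary_table(hier_table)
        sw = pooled_within_sd(hier_table)
        sb = between_sd(ss.sigma_s, sw, ss.k)
        analytic = analytic_power_grid(
            VarianceModel(ss.mean_effect, sb, sw), [10, 24], [10, 40])
        assert np.abs(grid.power - analytic.power).max() < 0.04


class TestTrialModes:
    def test_fraction_mode_handles_unequal_trial_counts(self):
        rng = np.random.default_rng(31)
        table = make_table({
            f"p{i}": rng.normal(1, 0.5, int(rng.integers(8, 20)))
            for i in range(30)
        })
        cfg = SubsampleConfig(reps=50, seed=1, trial_mode="fraction",
                              fraction=0.5)
        grid = subsample_grid(table, [10, 20], [1], cfg)
        assert np.all(np.isfinite(grid.power))
        # fraction 1.0 with all participants reproduces the full-data power
        cfg_full = SubsampleConfig(reps=5, seed=2, trial_mode="fraction",
                                   fraction=1.0)
        _, ss = summary_table(table)
        g = subsample_grid(table, [30], [1], cfg_full)
        assert g.power[0, 0] == pytest.approx(t_power(ss.d, 30), abs=1e-12)

    def test_per_condition_k_multiplier(self):
        # one condition has a 3:1 trial budget relative to the k axis
        rng = np.random.default_rng(37)
        a = make_table({f"p{i}": rng.normal(1, 1, 30) for i in range(20)},
                       condition="A")
        b = make_table({f"p{i}": rng.normal(0, 1, 10) for i in range(20)},
                       condition="B")
        from conftest import merge_tables
        table = merge_tables(a, b)
        cfg = SubsampleConfig(reps=100, seed=8, k_multipliers={"A": 3.0})
        grid = subsample_grid(table, [10], [5], cfg, conditions=["A", "B"])
        assert np.isfinite(grid.power[0, 0])
        # requesting k = 15 would need 45 trials of A: unavailable
        with pytest.raises(ValueError):
            subsample_grid(table, [10], [15],
                           SubsampleConfig(reps=10, seed=8,
                                           k_multipliers={"A": 3.0}),
                           conditions=["A", "B"])

    def test_fraction_mode_requires_fraction(self):
        with pytest.raises(ValueError):
            SubsampleConfig(trial_mode="fraction")

    def test_sequential_mode_uses_leading_trials(self):
        # strong drift: early trials are near 0, late trials near 10, so
        # sequential and random subsets of k=2 disagree systematically
        table = make_table({
            f"p{i}": [0.0 + 0.1 * i, 0.1 + 0.1 * i] + [10.0] * 8
            for i in range(12)
        })
        seq = subsample_once(table, 12, 2,
                             SubsampleConfig(seed=1, trial_mode="sequential"))
        _, ss_first2 = summary_table(
            make_table({f"p{i}": [0.0 + 0.1 * i, 0.1 + 0.1 * i]
                        for i in range(12)}))
        assert seq == pytest.approx(t_power(ss_first2.d, 12), abs=1e-12)


class TestSummaryTable:
    def test_two_participant_example(self):
        table = make_table({"a": [1, 1], "b": [3, 3]})
        frame, ss = summary_table(table, mu0=0.0)
        assert ss.mean_effect == pytest.approx(2)
        assert ss.sigma_s == pytest.approx(np.sqrt(2))
        assert ss.d == pytest.approx(np.sqrt(2))
        assert ss.n == 2 and ss.k == 2

    def test_recovers_generator_mean(self):
        spec = GeneratorSpec(n=400, k=40, mean_effect=1.0, sigma_b=2.0,
                             within=WithinSDDistribution.fixed(10.0), seed=2)
        frame, ss = summary_table(generate_hierarchical(spec))
        se = np.sqrt(2**2 / 400 + 10**2 / (400 * 40))
        assert ss.mean_effect == pytest.approx(1.0, abs=3 * se)

    def test_bernoulli_sample_sd_follows_variance_composition(self):
        # choice data: p ~ N(0.54, 0.15), k = 100 binary trials; the
        # composition predicts sigma_s ~ sqrt(0.15^2 + E[p(1-p)]/100)
        spec = GeneratorSpec(n=2000, k=100, mean_effect=0.54, sigma_b=0.15,
                             within=WithinSDDistribution.fixed(1.0),
                             outcome="bernoulli", seed=41)
        frame, ss = summary_table(generate_hierarchical(spec), mu0=0.5)
        predicted = np.sqrt(0.15**2 + 0.54 * 0.46 / 100)
        assert ss.sigma_s == pytest.approx(predicted, rel=0.06)
        assert ss.sigma_s == pytest.approx(0.16, abs=0.01)

    def test_too_few_participants_signal(self):
        with pytest.raises(ValueError):
            summary_table(make_table({"a": [1, 2]}))
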