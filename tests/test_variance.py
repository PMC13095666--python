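"""Bottleneck simulation, depth-variance quantile model and supporting statistics."""

import numpy as np
import pytest
from scipy import stats

from mitoscreen import (
    DepthBin,
    SimulationConfig,
    bh_adjust,
    bin_equal_count,
    bootstrap_variance_band,
    brown_forsythe_test,
    empirical_two_sided_p,
    expected_sampled_variance,
    fit_depth_variance_quantiles,
    holm_adjust,
    simulate_bottleneck_null,
    simulate_sampling_accuracy,
)
from mitoscreen.variance import pinball_loss


class TestBrownForsythe:
    def test_identical_groups(self):
        g = np.arange(1, 6, dtype=float)
        assert brown_forsythe_test([g, g]) == (0.0, 1.0)

    def test_hand_computed_anova_on_deviations(self):
        # |x - median| maps {0,0,10,10} -> {5,5,5,5} and {4,5,5,6} -> {1,0,0,1};
        # one-way ANOVA on those: SSB = 40.5, SSW = 1 with df (1, 6) -> F = 243
        w, p = brown_forsythe_test([np.array([0, 0, 10, 10.0]), np.array([4, 5, 5, 6.0])])
        assert w == pytest.approx(243.0)
        assert p == pytest.approx(float(stats.f.sf(243.0, 1, 6)))

    def test_matches_levene_median_oracle(self, rng):
        for _ in range(50):
            groups = [rng.normal(0, rng.uniform(0.5, 2), rng.integers(5, 30)) for _ in range(3)]
            w, p = brown_forsythe_test(groups)
            ref = stats.levene(*groups, center="median")
            assert w == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestAdjustments:
    def test_holm_hand_example(self):
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_bh_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("adjust", [holm_adjust, bh_adjust])
    def test_single_and_saturated(self, adjust):
        assert adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("adjust", [holm_adjust, bh_adjust])
    def test_adjusted_at_least_raw_and_capped(self, adjust, rng):
        p = rng.uniform(0, 1, 25)
        adj = adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    def test_holm_smallest_equals_bonferroni(self, rng):
        p = rng.uniform(0, 1, 10)
        assert holm_adjust(p).min() == pytest.approx(min(1.0, p.min() * len(p)))

    @pytest.mark.parametrize("adjust", [holm_adjust, bh_adjust])
    def test_out_of_range_rejected(self, adjust):
        with pytest.raises(ValueError):
            adjust([0.5, 1.5])


class TestEmpiricalP:
    def test_add_one_formula(self):
        null = np.linspace(1, 2, 99)
        assert empirical_two_sided_p(null, 0.5) == pytest.approx(2 / 100)

    def test_center_and_degenerate(self):
        null = np.arange(101, dtype=float)
        assert empirical_two_sided_p(null, 50.0) == 1.0
        assert empirical_two_sided_p(np.full(10, 3.0), 3.0) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_two_sided_p(np.array([]), 1.0)


class TestExpectedVariance:
    def test_pure_binomial(self):
        assert expected_sampled_variance(0.0, 0.5, [10] * 5) == pytest.approx(0.025)

    def test_infinite_depth_limit(self):
        assert expected_sampled_variance(0.01, 0.6, [10**9]) == pytest.approx(0.01, rel=1e-6)

    @pytest.mark.parametrize("mean_h", [0.0, 1.0])
    def test_boundary_mean_rejected(self, mean_h):
        with pytest.raises(ValueError):
            expected_sampled_variance(0.01, mean_h, [10])


class TestBottleneckNull:
    def test_infinite_depth_limit(self, rng):
        h = rng.uniform(0.3, 0.8, 200)
        null = simulate_bottleneck_null(h, [10**6] * 50, n_kd=100, n_sims=200, seed=1)
        # at enormous depth the binomial layer vanishes: null variances are
        # just variances of 100-cell subsamples of the pool
        assert null.null_variances.mean() == pytest.approx(np.var(h, ddof=1), rel=0.05)

    def test_mean_matches_closed_form(self, rng):
        h = np.clip(rng.normal(0.58, 0.11, 500), 0, 1)
        depths = rng.integers(5, 60, 400)
        null = simulate_bottleneck_null(h, depths, n_kd=300, n_sims=3000, seed=2)
        expected = expected_sampled_variance(float(np.var(h, ddof=1)), float(h.mean()), depths)
        mc_se = null.null_variances.std() / np.sqrt(null.n_sims)
        assert abs(null.null_variances.mean() - expected) < 3 * mc_se

    def test_seed_reproducibility(self, rng):
        h = rng.uniform(0.3, 0.8, 100)
        a = simulate_bottleneck_null(h, [20] * 50, 50, n_sims=100, seed=7)
        b = simulate_bottleneck_null(h, [20] * 50, 50, n_sims=100, seed=7)
        c = simulate_bottleneck_null(h, [20] * 50, 50, n_sims=100, seed=8)
        assert np.array_equal(a.null_variances, b.null_variances)
        assert not np.array_equal(a.null_variances, c.null_variances)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate_bottleneck_null([0.5] * 10, [20] * 5, n_kd=11)

    def test_attached_observed_and_p(self, rng):
        h = rng.uniform(0.3, 0.8, 200)
        null = simulate_bottleneck_null(
            h, [30] * 100, 100, observed_variance=10.0, n_sims=500, seed=3
        )
        assert null.p_empirical == pytest.approx(2 / 501)


class TestBinning:
    def test_even_split(self, rng):
        d = rng.uniform(1, 100, 100)
        bins = bin_equal_count(d, rng.random(100), 10)
        assert [b.n_cells for b in bins] == [10] * 10
        means = [b.mean_depth for b in bins]
        assert means == sorted(means)

    def test_remainder_to_lowest_depth_bins(self, rng):
        bins = bin_equal_count(rng.uniform(1, 100, 103), rng.random(103), 10)
        assert [b.n_cells for b in bins] == [11, 11, 11] + [10] * 7

    def test_constant_h_zero_variance(self, rng):
        bins = bin_equal_count(rng.uniform(1, 100, 40), np.full(40, 0.6), 4)
        assert all(b.het_variance < 1e-30 for b in bins)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            bin_equal_count([1, 2, 3], [0.1, 0.2, 0.3], 2)


class TestQuantileFit:
    def test_exact_recovery_zero_loss(self):
        bins = [DepthBin(5, d, 0.01 + 0.2 / d) for d in (5.0, 10.0, 20.0, 40.0, 80.0)]
        for fit in fit_depth_variance_quantiles(bins, taus=(0.05, 0.5, 0.95)):
            assert fit.beta0 == pytest.approx(0.01, abs=1e-8)
            assert fit.beta1 == pytest.approx(0.2, abs=1e-7)
            assert fit.pinball_loss < 1e-10

    def test_grid_search_optimality(self, rng):
        for _ in range(10):
            depths = rng.uniform(2, 100, 12)
            y = 0.01 + 0.3 / depths + rng.normal(0, 0.003, 12)
            bins = [DepthBin(5, d, max(v, 0.0)) for d, v in zip(depths, y)]
            [fit] = fit_depth_variance_quantiles(bins, taus=(0.3,))
            x_inv = 1.0 / depths
            vals = np.array([b.het_variance for b in bins])
            b0s = fit.beta0 + np.linspace(-0.01, 0.01, 80)
            b1s = fit.beta1 + np.linspace(-0.2, 0.2, 80)
            grid_losses = [
                pinball_loss(vals - (b0 + b1 * x_inv), 0.3) for b0 in b0s for b1 in b1s
            ]
            assert fit.pinball_loss <= min(grid_losses) + 1e-9

    def test_matches_statsmodels_quantreg(self, rng):
        import statsmodels.api as sm

        depths = rng.uniform(2, 100, 40)
        y = 0.02 + 0.5 / depths + rng.normal(0, 0.005, 40)
        bins = [DepthBin(5, d, v) for d, v in zip(depths, y)]
        [fit] = fit_depth_variance_quantiles(bins, taus=(0.5,))
        x = sm.add_constant(1.0 / depths)
        ref = sm.QuantReg(y, x).fit(q=0.5)
        ours = pinball_loss(y - fit.predict(depths), 0.5)
        theirs = pinball_loss(y - ref.predict(x), 0.5)
        assert ours <= theirs + 1e-8

    def test_upper_quantile_above_lower(self, rng):
        depths = rng.uniform(2, 100, 100)
        noise = rng.normal(0, 0.004, 100)
        bins = [DepthBin(5, d, max(0.02 + 0.3 / d + e, 0)) for d, e in zip(depths, noise)]
        lo, hi = fit_depth_variance_quantiles(bins, taus=(0.05, 0.95))
        grid = np.linspace(depths.min(), depths.max(), 30)
        assert np.all(hi.predict(grid) >= lo.predict(grid) - 1e-12)

    def test_collinear_design_rejected(self):
        bins = [DepthBin(5, 10.0, v) for v in (0.1, 0.2, 0.3)]
        with pytest.raises(ValueError):
            fit_depth_variance_quantiles(bins)


class TestBootstrapBand:
    def make_bins(self, rng, noise=0.0):
        depths = rng.uniform(5, 80, 20)
        return [
            DepthBin(5, d, 0.01 + 0.25 / d + (rng.normal(0, noise) if noise else 0.0))
            for d in depths
        ]

    def test_noise_free_band_collapses(self, rng):
        band = bootstrap_variance_band(self.make_bins(rng), tau=0.5, n_boot=50, seed=1)
        assert np.all(band.upper - band.lower < 1e-7)

    def test_seed_determinism(self, rng):
        bins = self.make_bins(rng, noise=0.002)
        a = bootstrap_variance_band(bins, 0.5, n_boot=40, seed=5)
        b = bootstrap_variance_band(bins, 0.5, n_boot=40, seed=5)
        c = bootstrap_variance_band(bins, 0.5, n_boot=40, seed=6)
        assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)
        assert not np.array_equal(a.lower, c.lower)

    def test_band_ordered_and_contains_fit_mostly(self, rng):
        bins = self.make_bins(rng, noise=0.002)
        [fit] = fit_depth_variance_quantiles(bins, taus=(0.5,))
        band = bootstrap_variance_band(bins, 0.5, n_boot=100, seed=2)
        assert np.all(band.lower <= band.upper)
        inside = (fit.predict(band.depth_grid) >= band.lower) & (
            fit.predict(band.depth_grid) <= band.upper
        )
        assert inside.mean() >= 0.95


class TestAccuracySimulation:
    def test_exhaustive_sampling_reproduces_pool(self):
        config = SimulationConfig(n_cells=200, copy_number=400, sample_sizes=(400,), seed=4)
        out = simulate_sampling_accuracy(config)
        df = out["per_size"][400]
        pool_frac = np.rint(df["true_h"] * 400) / 400
        assert np.allclose(df["sampled_h"], pool_frac)
        assert out["fits"][400]["r_squared"] > 0.999

    def test_r_squared_increases_with_sample_size(self):
        out = simulate_sampling_accuracy(SimulationConfig(seed=5))
        r2 = [out["fits"][n]["r_squared"] for n in (5, 20, 50, 100)]
        assert all(a < b for a, b in zip(r2, r2[1:]))

    def test_sigma_zero_limit_matches_hypergeometric(self):
        config = SimulationConfig(
            n_cells=4000, true_sd=1e-9, copy_number=1750, sample_sizes=(20,), seed=6
        )
        out = simulate_sampling_accuracy(config)
        sampled = out["per_size"][20]["sampled_h"].to_numpy()
        p0 = np.rint(0.582 * 1750) / 1750
        n, big_n = 20, 1750
        expected = p0 * (1 - p0) / n * (big_n - n) / (big_n - 1)
        mc_se = expected * np.sqrt(2.0 / (len(sampled) - 1))
        assert abs(np.var(sampled, ddof=1) - expected) < 4 * mc_se

    def test_matched_depth_mode(self, rng):
        config = SimulationConfig(n_cells=300, seed=7)
        out = simulate_sampling_accuracy(config, depth_distribution=rng.integers(5, 200, 1000))
        assert len(out["matched"]) == 300
        assert np.all(out["matched"]["depth"] <= 1750)

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(copy_number=50, sample_sizes=(100,))
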