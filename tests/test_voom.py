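import numpy as np
import pytest

import voomlite as vl
from voomlite.linmod import DesignMatrix
from voomlite.voom import MeanVarTrend


class TestAvgLogCount:
    def test_offsets_cancel_at_million_minus_one(self, design33):
        y = np.full((3, 6), 4.2)
        fit = vl.fit_genewise(y, design33)
        r = vl.avg_log_count(fit, np.full(6, 1e6 - 1))
        assert np.allclose(r, fit.avg_logcpm)

    def test_substitution_example(self, design33):
        # ybar = 0 (1 cpm), geomean(R + 1) = 1e7 -> r~ = log2(10)
        y = np.zeros((1, 6))
        fit = vl.fit_genewise(y, design33)
        r = vl.avg_log_count(fit, np.full(6, 1e7 - 1))
        assert r[0] == pytest.approx(np.log2(10), abs=1e-12)

    def test_geometric_not_arithmetic_mean(self, design33):
        sizes = np.array([2e6, 2e7, 2e6, 2e7, 2e6, 2e7])
        y = np.zeros((1, 6))
        fit = vl.fit_genewise(y, design33)
        r = vl.avg_log_count(fit, sizes)
        geo = np.mean(np.log2(sizes + 1))
        ari = np.log2(np.mean(sizes + 1))
        assert r[0] == pytest.approx(geo - np.log2(1e6), abs=1e-12)
        assert abs(r[0] - (ari - np.log2(1e6))) > 0.1


class TestFitTrend:
    x = np.linspace(2, 12, 400)

    def test_constant_sqrt_sd_preserved(self):
        trend = vl.fit_trend(self.x, np.full(400, 0.49))
        grid = np.linspace(0, 14, 50)
        assert np.allclose(trend.lo(grid), 0.7, atol=1e-8)

    def test_linear_sqrt_sd_reproduced_interior(self):
        sqrt_sd = 1.0 - 0.05 * self.x  # sigma = sqrt_sd^2
        trend = vl.fit_trend(self.x, sqrt_sd**2)
        interior = np.linspace(4, 10, 20)
        assert np.allclose(trend.lo(interior), 1.0 - 0.05 * interior, atol=5e-3)

    def test_single_outlier_barely_moves_trend(self):
        rng = np.random.default_rng(8)
        sigma = (0.8 - 0.03 * self.x + rng.normal(0, 0.01, 400)) ** 2
        t_clean = vl.fit_trend(self.x, sigma)
        sigma_out = sigma.copy()
        sigma_out[200] = 100.0
        t_dirty = vl.fit_trend(self.x, sigma_out)
        grid = np.linspace(2, 12, 60)
        rel = np.abs(t_dirty.lo(grid) - t_clean.lo(grid)) / t_clean.lo(grid)
        assert rel.max() < 0.01

    def test_degenerate_all_zero_sd(self):
        with pytest.raises(ValueError):
            vl.fit_trend(self.x, np.zeros(400))

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            vl.fit_trend(np.arange(5.0), np.ones(5))

    def test_constant_extrapolation_beyond_knots(self):
        trend = MeanVarTrend(knots_x=[0.0, 1.0], knots_y=[0.5, 0.9])
        assert trend.lo(-100.0) == pytest.approx(0.5)
        assert trend.lo(+100.0) == pytest.approx(0.9)

    def test_duplicate_knots_collapsed_by_averaging(self):
        trend = MeanVarTrend(knots_x=[1.0, 1.0, 2.0], knots_y=[0.4, 0.6, 1.0])
        assert trend.lo(1.0) == pytest.approx(0.5)


class TestFittedLogCount:
    def test_offsets_cancel(self, design33):
        fit = vl.fit_genewise(np.full((2, 6), 3.0), design33)
        lam = vl.fitted_log_count(fit, np.full(6, 1e6 - 1))
        assert np.allclose(lam, fit.mu)

    def test_depth_ratio_shifts_position(self, design33):
        fit = vl.fit_genewise(np.full((1, 6), 3.0), design33)
        lam_big = vl.fitted_log_count(fit, np.full(6, 2e6))
        lam_small = vl.fitted_log_count(fit, np.full(6, 2e5))
        assert np.allclose(
            lam_big - lam_small, np.log2((2e6 + 1) / (2e5 + 1)), atol=1e-12
        )


class TestVoomWeights:
    def test_constant_trend_gives_constant_weights(self, small_sim, design33):
        cm, _ = small_sim
        vr = vl.voom(cm, design33)
        flat = MeanVarTrend(knots_x=[0.0, 1.0], knots_y=[0.5, 0.5])
        w = flat.lo(vr.fitted_logcount) ** -4
        assert np.allclose(w, 16.0)

    def test_weights_identity_reconstructable(self, small_voom):
        """w = lo(lambda_hat)^-4 holds bit-exactly from the stored knots."""
        vr, _, _ = small_voom
        rebuilt = MeanVarTrend(vr.trend.knots_x, vr.trend.knots_y)
        assert np.array_equal(rebuilt.lo(vr.fitted_logcount) ** -4, vr.weights)

    def test_weights_positive_finite(self, small_voom):
        vr, _, _ = small_voom
        assert np.all(np.isfinite(vr.weights)) and np.all(vr.weights > 0)

    def test_equal_libsizes_give_genewise_constant_weights(self, design33):
        """With equal library sizes and an intercept-only design all
        observations of a gene sit at one point on the trend."""
        cfg = vl.NBSimConfig(n_genes=500, n_de_per_group=0, seed=5)
        cm, _ = vl.simulate(cfg)
        cm = vl.filter_by_total(cm, 10)
        # force exactly equal library sizes (column sums fluctuate around 11M)
        cm = vl.CountMatrix(cm.gene_ids, cm.sample_ids, cm.counts,
                            lib_sizes=np.full(6, 11e6))
        X = DesignMatrix(np.ones((6, 1)), ["mu"])
        vr = vl.voom(cm, X)
        assert np.allclose(vr.weights, vr.weights[:, [0]])

    def test_common_libsize_scaling_shifts_trend_positions(self, small_sim, design33):
        cm, _ = small_sim
        vr = vl.voom(cm, design33)
        scaled = vl.CountMatrix(
            cm.gene_ids, cm.sample_ids, cm.counts, lib_sizes=cm.lib_sizes * 4
        )
        vr2 = vl.voom(scaled, design33)
        shift = vr2.fitted_logcount - vr.fitted_logcount
        # lambda_hat shifts by ~log2(4) uniformly; within-gene weight ranking kept
        assert np.allclose(shift, shift.flat[0], atol=1e-6)
        r1 = np.argsort(vr.weights, axis=1)
        r2 = np.argsort(vr2.weights, axis=1)
        frac_same = np.mean(np.all(r1 == r2, axis=1))
        assert frac_same > 0.95

    def test_trend_decreases_then_flattens(self, small_voom):
        """Predicted sqrt-sd falls with count in the technical regime and
        levels off at high abundance."""
        vr, _, _ = small_voom
        lo = vr.trend.lo
        lows = np.linspace(vr.trend.knots_x.min(), vr.trend.knots_x.min() + 2, 10)
        highs = np.linspace(vr.trend.knots_x.max() - 2, vr.trend.knots_x.max(), 10)
        assert lo(lows).mean() > lo(highs).mean()
        # flat region: relative variation of the top quartile of the trend
        top = lo(np.linspace(vr.trend.knots_x.max() - 3, vr.trend.knots_x.max(), 30))
        assert np.ptp(top) / top.mean() < 0.35


class TestPriorTrend:
    def test_constant_variances_give_constant_trend(self):
        rng = np.random.default_rng(0)
        cov = rng.uniform(0, 10, 300)
        s2 = np.full(300, 0.7)
        out = vl.prior_trend(s2, cov)
        assert np.allclose(out, 0.7, rtol=1e-6)

    def test_exp_linear_recovered(self):
        rng = np.random.default_rng(1)
        cov = np.sort(rng.uniform(0, 10, 500))
        s2 = np.exp(0.3 - 0.1 * cov)
        out = vl.prior_trend(s2, cov)
        assert np.allclose(np.log(out), 0.3 - 0.1 * cov, atol=1e-6)

    def test_tracks_empirical_smoother_on_simulated_variances(self):
        """Spline-vs-smoother oracle: on chi-square scattered variances with a
        smooth trend, the spline stays inside a tolerance band of a lowess fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        cov = np.sort(rng.uniform(0, 10, 2000))
        true = np.exp(1.0 - 0.25 * cov + 0.01 * cov**2)
        d = 4
        s2 = true * rng.chisquare(d, 2000) / d
        out = vl.prior_trend(s2, cov, df=d)
        smooth = sm.nonparametric.lowess(
            np.log(s2), cov, frac=0.4, it=2, return_sorted=False
        )
        # lowess estimates E[log s2] = log(true) + digamma(d/2) - log(d/2)
        from scipy.special import digamma

        offset = digamma(d / 2) - np.log(d / 2)
        interior = (cov > 1) & (cov < 9)
        assert np.allclose(
            np.log(out)[interior], (smooth - offset)[interior], atol=0.25
        )

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            vl.prior_trend(np.ones(3), np.arange(3.0))


def test_voom_agrees_with_trend_variant_for_equal_sizes(small_sim, design33):
    """Observation weights collapse toward gene-level weights when depths are
    equal, so the two pipelines rank genes nearly identically."""
    from scipy.stats import spearmanr

    cm, _ = small_sim
    p_voom, _ = vl.run_pipeline(cm, design33, "voom")
    p_trend, _ = vl.run_pipeline(cm, design33, "limma_trend")
    rho = spearmanr(p_voom, p_trend).statistic
    assert rho > 0.95
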