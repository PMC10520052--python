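"""Distribution fitting, Monte Carlo propagation and sensitivity analysis."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from ecigrisk.probabilistic import (
    FAMILIES,
    FittedDistribution,
    anderson_darling,
    exceedance_probability,
    fit_distribution,
    fit_family,
    monte_carlo,
    point_mass,
    sensitivity,
    summarize_draws,
)


class TestAndersonDarling:
    def test_matches_direct_formula_on_fixed_sample(self):
        # independent oracle: textbook A2 computed term by term
        x = np.array([0.31, 0.45, 0.62, 0.77, 0.91, 1.05, 1.33, 1.58, 1.92, 2.54])
        cdf = stats.lognorm(0.5, scale=1.0).cdf
        n = len(x)
        xs = np.sort(x)
        total = 0.0
        for i in range(1, n + 1):
            total += (2 * i - 1) * (
                math.log(cdf(xs[i - 1])) + math.log(1 - cdf(xs[n - i]))
            )
        expected = -n - total / n
        assert anderson_darling(x, cdf) == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_scipy_for_normal_samples(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2.0, 1.5, 200)
        # scipy's normality AD uses the ddof=1 scale estimate
        ours = anderson_darling(x, stats.norm(x.mean(), x.std(ddof=1)).cdf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reference = stats.anderson(x, "norm").statistic
        assert ours == pytest.approx(reference, rel=1e-6)


class TestFitting:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(12)
        x = rng.lognormal(0.0, 1.0, 1000)
        fd = fit_distribution(x, "conc")
        assert fd.family == "lognormal"
        shape, loc, scale = fd.params
        assert loc == 0
        assert math.log(scale) == pytest.approx(0.0, abs=0.1)  # mu
        assert shape == pytest.approx(1.0, abs=0.1)  # sigma

    def test_all_identical_collapses_to_point_mass(self):
        with pytest.warns(UserWarning, match="point mass"):
            fd = fit_distribution([3.0, 3.0, 3.0, 3.0])
        assert fd.family == "point_mass" and fd.params == (3.0,)
        assert fd.mean() == 3.0

    def test_fewer_than_two_samples_is_hard_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_distribution([1.0])

    def test_small_samples_fall_back_to_empirical(self):
        fd = fit_distribution([1.0, 2.0, 5.0])
        assert fd.family == "empirical"
        assert fd.mean() == pytest.approx(8.0 / 3)

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 1.0, 500)
        fwd = fit_distribution(x, "v")
        rev = fit_distribution(x[::-1], "v")
        assert fwd.family == rev.family and fwd.params == rev.params

    def test_zero_inflation_weight_matches_zero_fraction(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(0, 0.5, 400)
        x[:100] = 0.0
        params, zero_weight = fit_family(x, "lognormal")
        assert zero_weight == pytest.approx(0.25)
        fd = FittedDistribution("v", "lognormal", params, zero_weight)
        assert fd.cdf(0.0) == pytest.approx(0.25)

    def test_gof_recorded_for_every_candidate(self):
        rng = np.random.default_rng(21)
        fd = fit_distribution(rng.lognormal(0, 1, 300), "v")
        assert set(fd.candidates) >= {"normal", "lognormal", "gamma", "weibull", "uniform"}
        assert all(np.isfinite(g.ad) for g in fd.candidates.values())
        best_ad = min(g.ad for g in fd.candidates.values())
        assert fd.gof.ad == best_ad


class TestMonteCarlo:
    @staticmethod
    def doubling_pipeline(draws):
        return {"out": 2.0 * draws["x"]}

    def test_same_seed_reproduces_bit_for_bit(self):
        fitted = {"x": FittedDistribution("x", "lognormal", (1.0, 0, 1.0))}
        out1, draws1 = monte_carlo(self.doubling_pipeline, fitted, 2000, seed=42)
        out2, draws2 = monte_carlo(self.doubling_pipeline, fitted, 2000, seed=42)
        assert np.array_equal(out1["out"], out2["out"])
        assert np.array_equal(draws1["x"], draws2["x"])
        out3, _ = monte_carlo(self.doubling_pipeline, fitted, 2000, seed=43)
        assert not np.array_equal(out1["out"], out3["out"])

    def test_point_mass_collapses_to_deterministic(self):
        fitted = {"x": point_mass(1.5, "x")}
        out, _ = monte_carlo(self.doubling_pipeline, fitted, 1000, seed=0)
        assert np.all(out["out"] == 3.0)
        dist = summarize_draws("out", out["out"], threshold=1.0, seed=0)
        assert all(v == 3.0 for v in dist.percentiles.values())
        assert dist.exceedance == 1.0

    def test_negative_normal_draws_truncated_at_zero(self):
        fitted = {"x": FittedDistribution("x", "normal", (0.0, 1.0))}
        _, draws = monte_carlo(self.doubling_pipeline, fitted, 2000, seed=1)
        assert draws["x"].min() == 0.0  # about half the draws truncated

    def test_small_iteration_count_warns(self):
        fitted = {"x": point_mass(1.0)}
        with pytest.warns(UserWarning, match="unstable"):
            monte_carlo(self.doubling_pipeline, fitted, 100, seed=0)

    def test_mc_mean_converges_to_analytic_mean(self):
        # linear risk: MC mean -> k * E[X] within 3 standard errors
        mu, sig, k, n = -1.0, 0.8, 5.0, 10_000
        fitted = {"x": FittedDistribution("x", "lognormal", (sig, 0, math.exp(mu)))}
        out, _ = monte_carlo(lambda d: {"risk": k * d["x"]}, fitted, n, seed=4)
        analytic = k * math.exp(mu + sig**2 / 2)
        analytic_sd = analytic * math.sqrt(math.exp(sig**2) - 1)
        assert abs(out["risk"].mean() - analytic) < 3 * analytic_sd / math.sqrt(n)


class TestExceedance:
    def test_degenerate_cases(self):
        draws = np.array([2.0, 3.0, 4.0])
        assert exceedance_probability(draws, 1.0) == (1.0, 0.0)
        assert exceedance_probability(draws, np.inf) == (0.0, 1.0)

    def test_uniform_half_exceedance(self):
        rng = np.random.default_rng(8)
        draws = rng.uniform(0, 2, 10_000)
        exc, cert = exceedance_probability(draws, 1.0)
        assert exc == pytest.approx(0.5, abs=0.015)  # 3 binomial SEs
        assert exc + cert == 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        draws = rng.lognormal(0, 1, 5000)
        excs = [exceedance_probability(draws, t)[0] for t in (0.1, 0.5, 1, 2, 10)]
        assert excs == sorted(excs, reverse=True)

    def test_percentiles_non_decreasing(self):
        rng = np.random.default_rng(6)
        dist = summarize_draws("t", rng.lognormal(0, 1, 5000), 1.0, seed=6)
        pct = [dist.percentiles[p] for p in sorted(dist.percentiles)]
        assert pct == sorted(pct)


class TestSensitivity:
    def test_single_varying_input_gets_everything(self):
        rng = np.random.default_rng(13)
        x = rng.lognormal(0, 1, 2000)
        report = sensitivity({"x": x, "const": np.ones(2000)}, x)
        assert report.contributions["x"] == pytest.approx(100.0)
        assert report.contributions["const"] == 0.0

    def test_constant_output_warns_and_zeroes(self):
        rng = np.random.default_rng(14)
        with pytest.warns(UserWarning, match="constant"):
            report = sensitivity({"x": rng.random(1500)}, np.ones(1500))
        assert all(v == 0.0 for v in report.contributions.values())

    def test_product_of_lognormals_splits_by_log_variance(self):
        # X with twice the log-sd of Y should take ~80 % of the variance
        rng = np.random.default_rng(15)
        n = 10_000
        x = rng.lognormal(0, 0.8, n)
        y = rng.lognormal(0, 0.4, n)
        out = x * y
        report = sensitivity({"x": x, "y": y}, out)

        # brute-force oracle: squared rank correlations computed directly
        def rank_r2(a, b):
            ra, rb = stats.rankdata(a), stats.rankdata(b)
            return float(np.corrcoef(ra, rb)[0, 1] ** 2)

        r2x, r2y = rank_r2(x, out), rank_r2(y, out)
        assert report.contributions["x"] == pytest.approx(
            100 * r2x / (r2x + r2y), abs=1e-6
        )
        assert report.contributions["x"] == pytest.approx(80.0, abs=3.0)
        assert report.contributions["y"] == pytest.approx(20.0, abs=3.0)
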