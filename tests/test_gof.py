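"""Goodness-of-fit statistics, their oracles, and the population protocol."""

import numpy as np
import pytest
from scipy import integrate, stats

import burstfit as bf
from burstfit import FitConfig

THETA = bf.ModelParams(0.02, 30.0, 1.45, 1e-4)


def brute_force_ks(x, cdf):
    """O(n^2) sup-distance evaluation checking every step edge."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    best = 0.0
    for i, xi in enumerate(x):
        fi = float(cdf(np.array([xi]))[0] if np.ndim(cdf(xi)) else cdf(xi))
        for ecdf_val in ((i + 1) / n, i / n):
            best = max(best, abs(ecdf_val - fi))
    return best


class TestKsStatistic:
    def test_single_observation_at_median(self):
        d = bf.ks_statistic(np.array([np.log(2) * 1000.0]),
                            lambda x: 1 - np.exp(-x / 1000.0))
        assert d == pytest.approx(0.5, rel=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 13))
            x = rng.uniform(0, 1, size=n)
            d = bf.ks_statistic(x, lambda v: np.clip(v, 0, 1))
            assert d == pytest.approx(
                brute_force_ks(x, lambda v: min(max(v, 0.0), 1.0)), abs=1e-15
            )

    def test_uniform_draws_concentrate(self, rng):
        x = rng.uniform(0, 1, size=10_000)
        assert bf.ks_statistic(x, lambda v: np.clip(v, 0, 1)) < 0.025

    def test_non_monotone_cdf_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            bf.ks_statistic(np.array([1.0, 2.0, 3.0]), lambda v: np.cos(v))

    def test_probability_integral_transform_invariance(self, rng):
        """KS is invariant under a strictly monotone transform applied to
        both the data and the model."""
        x = rng.exponential(100.0, size=200)
        d1 = bf.ks_statistic(x, lambda v: 1 - np.exp(-v / 100.0))
        y = np.log1p(x)  # monotone transform; model transformed alike
        d2 = bf.ks_statistic(y, lambda v: 1 - np.exp(-np.expm1(v) / 100.0))
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestKsTest:
    def test_critical_value_near_asymptotic_form(self):
        """The implied 5% critical D at n=100 is ~1.358/sqrt(n) and shrinks
        with n."""
        def critical_d(n):
            from scipy.optimize import brentq
            from burstfit.gof import _ks_p_value
            return brentq(lambda d: _ks_p_value(d, n) - 0.05, 1e-4, 0.99)

        assert critical_d(100) == pytest.approx(1.358 / 10.0, abs=0.004)
        assert critical_d(400) < critical_d(100) < critical_d(25)

    def test_power_against_exponential_on_bursty_data(self):
        rejected = 0
        for seed in range(20):
            tau = bf.sample_interevent(THETA, 500, seed=seed).durations
            expo = bf.fit_baseline(tau, "exponential")
            if not bf.ks_test(tau, expo).passed:
                rejected += 1
        assert rejected == 20

    def test_bootstrap_p_value_reported(self):
        tau = bf.sample_interevent(THETA, 150, seed=5).durations
        expo = bf.fit_baseline(tau, "exponential")
        res = bf.ks_test(tau, expo, bootstrap=19)
        assert res.p_value_bootstrap is not None
        assert 0.0 < res.p_value_bootstrap <= 1.0


class TestCvm:
    def test_single_observation_at_median(self):
        res = bf.cvm_test(np.array([np.log(2.0)]),
                          bf.BaselineParams(family="exponential", rate=1.0))
        assert res.statistic == pytest.approx(1.0 / 12.0, rel=1e-9)
        assert res.low_power

    def test_matches_quadrature_oracle_and_scipy(self, rng):
        """n*int (F_n - F)^2 dF against numeric integration (uniform F),
        and against scipy's independent implementation."""
        from burstfit.gof import cvm_statistic

        for _ in range(20):
            n = int(rng.integers(2, 10))
            x = np.sort(rng.uniform(0, 1, size=n))

            def integrand(v):
                return (np.searchsorted(x, v, side="right") / n - v) ** 2

            oracle, _ = integrate.quad(integrand, 0.0, 1.0,
                                       points=list(x), limit=200)
            w = cvm_statistic(x, lambda v: np.clip(v, 0, 1))
            assert w == pytest.approx(n * oracle, abs=1e-10)
            sp = stats.cramervonmises(x, lambda v: np.clip(v, 0, 1))
            assert w == pytest.approx(sp.statistic, abs=1e-12)

    def test_uniform_draws_below_asymptotic_critical_point(self, rng):
        below = sum(
            stats.cramervonmises(
                rng.uniform(0, 1, 2000), lambda v: np.clip(v, 0, 1)
            ).statistic < 0.461
            for _ in range(40)
        )
        assert below >= 34  # ~95% expected


class TestChiSquare:
    def test_zero_statistic_on_exact_quantile_data(self):
        """Observations placed at model quantiles give equal bin counts."""
        rate = 0.01
        n, k = 50, 10
        u = (np.arange(n) + 0.5) / n
        tau = -np.log1p(-u) / rate
        res = bf.chi_square_test(
            tau, bf.BaselineParams(family="exponential", rate=rate)
        )
        assert res.statistic == 0.0
        assert res.dof == k - 1 - 1

    def test_requires_enough_bins(self):
        tau = bf.sample_interevent(THETA, 60, seed=3).durations
        # k = 12 bins, 4 fitted params -> dof 7: fine; force failure via n<50
        with pytest.raises(ValueError):
            bf.chi_square_test(tau[:40], THETA)

    def test_power_against_exponential(self):
        exceed = 0
        for seed in range(20):
            tau = bf.sample_interevent(THETA, 1000, seed=100 + seed).durations
            expo = bf.fit_baseline(tau, "exponential")
            if not bf.chi_square_test(tau, expo).passed:
                exceed += 1
        assert exceed == 20

    def test_calibrated_after_refit(self):
        """Multiscale-simulated data tested against its own fit passes at 5%
        in at least 90% of replicates (slight anti-conservatism from fitting
        is expected but small)."""
        passed = 0
        n_rep = 60
        for seed in range(n_rep):
            tau = bf.sample_interevent(THETA, 1000, seed=500 + seed).durations
            theta_hat = bf.fit_multiscale(tau, FitConfig(seed=seed)).theta_hat
            if bf.chi_square_test(tau, theta_hat).passed:
                passed += 1
        assert passed / n_rep >= 0.90


class TestEvaluatePopulation:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        return bf.sample_population(bf.PopulationConfig(n_users=8, seed=42))

    def test_single_user_averages_are_that_user(self, small_cohort):
        member = small_cohort[0]
        summ = bf.evaluate_population([member], model_families=("exponential",))
        expo = bf.fit_baseline(member.series, "exponential")
        d = bf.ks_statistic(member.series, expo.dist().cdf)
        assert summ.table.loc["exponential", "ks_stat"] == pytest.approx(d)
        assert summ.n_users == 1

    def test_permutation_invariance(self, small_cohort):
        fams = ("multiscale", "exponential")
        a = bf.evaluate_population(small_cohort, model_families=fams)
        b = bf.evaluate_population(small_cohort[::-1], model_families=fams)
        assert np.allclose(a.table.values, b.table.values)

    def test_pass_rates_monotone_in_level(self, small_cohort):
        s5 = bf.evaluate_population(small_cohort, significance_level=0.05)
        s1 = bf.evaluate_population(small_cohort, significance_level=0.01)
        rates5 = s5.table[["ks_rate", "chi2_rate", "cvm_rate"]].values
        rates1 = s1.table[["ks_rate", "chi2_rate", "cvm_rate"]].values
        assert np.all((rates5 >= 0) & (rates5 <= 1))
        assert np.all(rates1 >= rates5 - 1e-12)

    def test_activity_filter_excludes_short_series(self, small_cohort):
        short = bf.InterEventSeries(durations=np.ones(50), individual_id="tiny")
        summ = bf.evaluate_population(
            list(small_cohort) + [short], model_families=("exponential",)
        )
        assert summ.n_excluded["inactive"] == 1
        assert summ.n_users == len(small_cohort)


class TestCropCurve:
    @pytest.fixture(scope="class")
    def cohort(self):
        return bf.sample_population(bf.PopulationConfig(n_users=8, seed=42))

    def test_zero_fraction_matches_population_mean_p(self, cohort):
        summ = bf.evaluate_population(cohort, model_families=("pareto",))
        curve = bf.crop_curve(cohort, "pareto", [0.0])
        assert curve.table.loc[0, "mean_p_value"] == pytest.approx(
            summ.mean_p_values.loc["pareto", "ks"], rel=1e-9
        )

    def test_fraction_bounds_enforced(self, cohort):
        with pytest.raises(ValueError):
            bf.crop_curve(cohort, "pareto", [0.95])
        with pytest.raises(ValueError):
            bf.crop_curve(cohort, "multiscale", [0.1])


class TestLogBinnedDensity:
    def test_tracks_true_density(self, rng):
        x = rng.lognormal(3.0, 1.0, size=50_000)
        centers, dens = bf.log_binned_density(x, bins_per_decade=10)
        true = stats.lognorm(1.0, scale=np.exp(3.0)).pdf(centers)
        mid = (centers > np.exp(2.0)) & (centers < np.exp(4.0))
        assert np.allclose(dens[mid], true[mid], rtol=0.15)
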