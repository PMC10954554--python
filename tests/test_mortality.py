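import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odontolife.data_model import AgeDataset, GompertzParams, ValidationError
from odontolife.mortality import (
    age_error_kernel,
    expected_age_distribution,
    fit_juvenile_survival,
    fit_mortality,
    gompertz_survivorship,
    ordinary_max_lifespan,
    predict_survival_to_maturity,
    siler_survivorship,
    survival_and_expectancy_at_age,
)
from odontolife.synthetic import AgeSimConfig, simulate_age_dataset


class TestSurvivorship:
    def test_identity_at_from_age(self):
        assert gompertz_survivorship(10.0, GompertzParams(0.05, 0.1), from_age=10.0) == 1.0

    def test_closed_form_value(self):
        # exp(-(0.05/0.1)(e^{0.1*10}-1)) = exp(-0.5(e-1))
        got = gompertz_survivorship(10.0, GompertzParams(0.05, 0.1))
        assert got == pytest.approx(np.exp(-0.5 * (np.e - 1)), rel=1e-12)

    def test_exponential_limit_at_beta_zero(self):
        got = gompertz_survivorship(10.0, GompertzParams(0.1, 0.0))
        assert got == pytest.approx(np.exp(-1.0), rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(alpha=st.floats(1e-3, 0.5), beta=st.floats(0.0, 0.5))
    def test_non_increasing_in_age(self, alpha, beta):
        ages = np.linspace(0, 60, 40)
        s = gompertz_survivorship(ages, GompertzParams(alpha, beta))
        assert np.all(np.diff(s) <= 1e-15)
        # survivorship may underflow to exactly 0 at extreme ages
        assert np.all((s >= 0) & (s <= 1.0))


class TestExpectedAgeDistribution:
    def _exp_halving(self, **kw):
        # survivorship (1, 1/2, 1/4) over three 1-yr bins
        return expected_age_distribution(GompertzParams(np.log(2), 0.0), 0.0, 2.0,
                                         age_error=False, **kw)

    def test_plain_normalization(self):
        assert np.allclose(self._exp_halving().theta, [4 / 7, 2 / 7, 1 / 7])

    def test_bias_window_multiplier(self):
        e = self._exp_halving(s=1.0, bias_window=(2.0, 2.0))
        assert np.allclose(e.theta, [0.5, 0.25, 0.25])

    def test_population_growth_discount(self):
        e = self._exp_halving(rho=0.5)
        expect = np.array([1.0, 0.25, 0.0625])
        assert np.allclose(e.theta, expect / expect.sum())

    def test_theta_normalizes_and_kernel_rows_stochastic(self):
        e = expected_age_distribution(GompertzParams(0.03, 0.12), 8.0, 90.0,
                                      rho=0.01, s=0.7, bias_window=(20.0, 40.0), B=2.0)
        assert e.theta.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(e.error_kernel.sum(axis=1), 1.0)
        assert np.all(np.diff(e.L) <= 1e-15)

    def test_shrinking_population_too_fast_rejected(self):
        with pytest.raises(ValueError):
            expected_age_distribution(GompertzParams(0.05, 0.1), 10.0, 50.0, rho=1.0)


class TestOrdinaryMaxLifespan:
    def test_exponential_closed_form(self):
        # constant hazard: 90% of person-years lived by maturity + ln(10)/alpha
        z = ordinary_max_lifespan(GompertzParams(0.1, 0.0), 10.0)
        assert abs(z - (10.0 + np.log(10) / 0.1)) <= 1.0

    def test_monotone_in_quantile(self):
        p = GompertzParams(0.05, 0.08)
        assert ordinary_max_lifespan(p, 10.0, q=0.99) > ordinary_max_lifespan(p, 10.0, q=0.90)

    def test_matches_integration_oracle(self):
        p = GompertzParams(0.02, 0.15)
        maturity = 10.0
        # dense trapezoidal oracle
        t = np.linspace(0, 150, 15001)
        l = gompertz_survivorship(t, p)
        cum = np.concatenate([[0], np.cumsum((l[1:] + l[:-1]) / 2 * np.diff(t))])
        z_oracle = maturity + t[np.searchsorted(cum / cum[-1], 0.9)]
        z = ordinary_max_lifespan(p, maturity)
        assert abs(z - z_oracle) <= 1.0


class TestSurvivalAndExpectancy:
    def test_memoryless_expectancy(self):
        for M in (10.0, 25.0):
            l, e = survival_and_expectancy_at_age(GompertzParams(0.1, 0.0), M, 10.0)
            assert abs(e - 10.0) < 0.5

    def test_survival_is_one_at_maturity(self):
        l, _ = survival_and_expectancy_at_age(GompertzParams(0.05, 0.1), 10.0, 10.0)
        assert l == 1.0

    def test_expectancy_decreases_with_age_under_senescence(self):
        p = GompertzParams(0.02, 0.12)
        es = [survival_and_expectancy_at_age(p, M, 10.0)[1] for M in (10.0, 20.0, 30.0)]
        assert es[0] > es[1] > es[2]


class TestFit:
    def test_parameter_recovery_plain(self):
        # loose 3-sd bound: catches gross estimation bugs on a single
        # replicate; interval calibration is checked over many replicates in
        # the acceptance suite
        ds, truth = simulate_age_dataset(AgeSimConfig(n=1000, alpha=0.05, beta=0.1, seed=21))
        post = fit_mortality([ds], 10.0, seed=22, age_error=False)
        for p in ("alpha", "beta"):
            err = abs(post.draws[p].mean() - truth[p])
            assert err < 3 * post.draws[p].std(), p
        assert post.converged

    def test_pooling_two_identical_datasets_matches_merged(self):
        cfg = AgeSimConfig(n=800, seed=30)
        ds, _ = simulate_age_dataset(cfg)
        ds2 = AgeDataset("d2", ds.species, ds.sex, ds.population_id, list(ds.records),
                         growth_prior=ds.growth_prior)
        merged = AgeDataset("m", ds.species, ds.sex, ds.population_id,
                            [(a, 2 * c) for a, c in ds.records],
                            growth_prior=ds.growth_prior)
        p2 = fit_mortality([ds, ds2], 10.0, seed=31, age_error=False)
        pm = fit_mortality([merged], 10.0, seed=32, age_error=False)
        for p in ("alpha", "beta"):
            lo2, hi2 = np.quantile(p2.draws[p], [0.025, 0.975])
            lom, him = np.quantile(pm.draws[p], [0.025, 0.975])
            # 95% intervals overlap substantially
            assert max(lo2, lom) < min(hi2, him)
            assert abs(p2.draws[p].mean() - pm.draws[p].mean()) < p2.draws[p].std()

    def test_filter_failure_is_an_error(self):
        tiny = AgeDataset("t", "sp", "female", "p", [(15.0, 5)])
        with pytest.raises(ValidationError, match="inclusion"):
            fit_mortality([tiny], 10.0)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            fit_mortality([], 10.0)

    def test_error_kernel_on_error_free_data_is_mild(self):
        ds, truth = simulate_age_dataset(AgeSimConfig(n=1000, seed=40))
        p_off = fit_mortality([ds], 10.0, seed=41, age_error=False)
        p_on = fit_mortality([ds], 10.0, seed=41, age_error=True)
        for p in ("alpha", "beta"):
            shift = abs(p_on.draws[p].mean() - p_off.draws[p].mean())
            assert shift < p_off.draws[p].std(), p


class TestErrorKernel:
    def test_rows_are_distributions_and_identity_when_disabled(self):
        ages = np.arange(10.0, 60.0)
        K = age_error_kernel(ages, B=2.0)
        assert np.allclose(K.sum(axis=1), 1.0)
        assert np.all(K >= 0)
        assert np.array_equal(age_error_kernel(ages, enabled=False), np.eye(len(ages)))

    def test_error_grows_with_age(self):
        ages = np.arange(0.0, 100.0)
        K = age_error_kernel(ages)
        # mass retained on the true age shrinks as ages (and sds) grow
        assert K[10, 10] > K[80, 80]


class TestJuvenile:
    @staticmethod
    def _bathtub_dataset(seed, n=2000, a1=0.4, b1=0.6, a2=0.01, a3=0.01, b3=0.12):
        rng = np.random.default_rng(seed)
        ages = np.arange(0.0, 121.0)
        S = siler_survivorship(ages, a1, b1, a2, a3, b3)
        counts = rng.multinomial(n, S / S.sum())
        recs = [(float(a), int(c)) for a, c in zip(ages, counts) if c > 0]
        return AgeDataset(f"juv{seed}", f"sp{seed}", "female", "p1", recs)

    def test_survival_to_maturity_recovery(self):
        ds = self._bathtub_dataset(2)
        truth = siler_survivorship(10.0, 0.4, 0.6, 0.01, 0.01, 0.12)
        post = fit_juvenile_survival([ds], 10.0, seed=1)
        sv = post.survival_draws[ds.species]
        assert abs(sv.mean() - truth) < 2 * sv.std()

    def test_no_juvenile_hazard_matches_gompertz_only(self):
        # pure senescent mortality: survival to maturity should be near the
        # Gompertz-only prediction
        rng = np.random.default_rng(5)
        ages = np.arange(0.0, 121.0)
        S = gompertz_survivorship(ages, GompertzParams(0.02, 0.1))
        counts = rng.multinomial(3000, S / S.sum())
        recs = [(float(a), int(c)) for a, c in zip(ages, counts) if c > 0]
        ds = AgeDataset("nojuv", "spX", "female", "p1", recs)
        post = fit_juvenile_survival([ds], 10.0, seed=2)
        sv = post.survival_draws["spX"]
        truth = gompertz_survivorship(10.0, GompertzParams(0.02, 0.1))
        assert abs(sv.mean() - truth) < max(3 * sv.std(), 0.05)

    def test_imputation_interpolates_training_range(self):
        datasets, mats = [], {}
        for k, m in enumerate([6.0, 8.0, 10.0, 12.0, 14.0]):
            ds = self._bathtub_dataset(10 + k, n=1500)
            datasets.append(ds)
            mats[ds.species] = m
        post = fit_juvenile_survival(datasets, mats, seed=3, n_steps=500, n_burn=600)
        assert post.regression_draws is not None
        pred = predict_survival_to_maturity(post, 10.0, rng=np.random.default_rng(0))
        lo = min(v.mean() for v in post.survival_draws.values())
        hi = max(v.mean() for v in post.survival_draws.values())
        margin = 2 * max(v.std() for v in post.survival_draws.values()) + 0.1
        assert lo - margin < pred.mean() < hi + margin

    def test_juvenile_filter_enforced(self):
        few = AgeDataset("few", "sp", "female", "p1", [(2.0, 50), (30.0, 60)])
        with pytest.raises(ValidationError, match="juvenile"):
            fit_juvenile_survival([few], 10.0)
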