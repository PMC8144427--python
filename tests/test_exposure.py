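import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import vitdpower as vp
from vitdpower._calendar import WEEKS_PER_YEAR, date_to_t, weeks_to_years


class TestCalendar:
    @pytest.mark.parametrize(
        "date,days_from_march1",
        [("03-01", 0), ("05-01", 61), ("09-01", 184), ("11-01", 245), ("02-28", 364)],
    )
    def test_date_to_model_time(self, date, days_from_march1):
        assert date_to_t(date) == pytest.approx(days_from_march1 / 365)

    def test_month_name_parsing(self):
        assert date_to_t("Sep 1") == date_to_t("09-01") == date_to_t((9, 1))

    def test_weeks_conversion(self):
        assert weeks_to_years(WEEKS_PER_YEAR) == pytest.approx(1.0)


class TestRiskCurveCalibration:
    def test_reference_point_system(self):
        """(a, b) solve the 2x2 calibration system; verified against an
        independent linear solve and by evaluating g at the references."""
        l, u, x_lo, x_hi, att = 1.0, 2.0, 10.0, 70.0, 0.95
        a, b = vp.calibrate_logistic(l, u, x_lo, x_hi, att)
        # independent oracle: a + b*x = logit of the residual risk fraction
        rhs = [math.log((1 - att) / att), math.log(att / (1 - att))]
        a_ref, b_ref = np.linalg.solve([[1.0, x_lo], [1.0, x_hi]], rhs)
        assert (a, b) == pytest.approx((a_ref, b_ref))
        g = vp.RiskCurve(l=l, u=u, x_lo=x_lo, x_hi=x_hi, attainment=att)
        assert g(10.0) == pytest.approx(1.95)
        assert g(70.0) == pytest.approx(1.05)
        assert b > 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        l=st.floats(0, 3), du=st.floats(0.1, 5), x_lo=st.floats(0, 40),
        dx=st.floats(5, 100), att=st.floats(0.55, 0.99),
    )
    def test_midpoint_symmetry_and_bounds(self, l, du, x_lo, dx, att):
        g = vp.RiskCurve(l=l, u=l + du, x_lo=x_lo, x_hi=x_lo + dx, attainment=att)
        assert g((2 * x_lo + dx) / 2) == pytest.approx((2 * l + du) / 2)
        assert g(1e9) == pytest.approx(l, abs=1e-9)
        assert g(-1e9) == pytest.approx(l + du, abs=1e-9)
        x = np.linspace(-50, 150, 101)
        y = np.asarray(g(x))
        assert np.all(np.diff(y) <= 1e-12)  # monotone non-increasing
        assert np.all((y >= l - 1e-12) & (y <= l + du + 1e-12))

    def test_degenerate_constant_curve_flagged(self):
        g = vp.RiskCurve(l=1.5, u=1.5)
        assert g.is_constant
        np.testing.assert_allclose(g(np.array([0.0, 50.0, 100.0])), 1.5)


class TestExposureProcess:
    def test_zero_rate_gives_no_exposures(self):
        silent = vp.SeasonalStepIntensity.constant(0.0)
        assert vp.simulate_exposure_times(silent, (0.0, 1.0), 1).size == 0

    def test_times_sorted_inside_window(self, seasonal_intensity, rng):
        times = vp.simulate_exposure_times(seasonal_intensity, (0.25, 1.75), rng)
        assert np.all(np.diff(times) >= 0)
        assert times.min() > 0.25 and times.max() <= 1.75

    def test_homogeneous_rate_mean_count(self, rng):
        """One exposure per week for a year: mean count = 365/7 (4 MC SE)."""
        weekly = vp.SeasonalStepIntensity.constant(1.0)
        reps = 10_000
        counts = [vp.simulate_exposure_times(weekly, (0.0, 1.0), rng).size for _ in range(reps)]
        expected = WEEKS_PER_YEAR
        se = math.sqrt(expected / reps)
        assert np.mean(counts) == pytest.approx(expected, abs=4 * se)

    def test_seasonal_intensity_integral_and_mean(self, seasonal_intensity, rng):
        """Winter-dominant schedule: 242 days at 1/wk + 123 days at 0.1/wk."""
        expected = 242 / 7 + 0.1 * 123 / 7  # ~36.33 per year
        assert seasonal_intensity.annual_mean_count == pytest.approx(expected)
        assert seasonal_intensity.integral(0.0, 2.0) == pytest.approx(2 * expected)
        reps = 4000
        counts = [
            vp.simulate_exposure_times(seasonal_intensity, (0.5, 1.5), rng).size
            for _ in range(reps)
        ]
        assert np.mean(counts) == pytest.approx(expected, abs=4 * math.sqrt(expected / reps))

    def test_segment_counts_poisson_gof(self, seasonal_intensity, rng):
        """Counts in the high season are Poisson with the segment integral as
        mean (chi-square goodness of fit at alpha = 0.001)."""
        t_sep, t_may = date_to_t("09-01") + 1.0, date_to_t("05-01") + 1.0
        reps = 10_000
        winter = np.empty(reps, dtype=int)
        summer = np.empty(reps, dtype=int)
        for i in range(reps):
            times = vp.simulate_exposure_times(seasonal_intensity, (t_may, t_may + 1.0), rng)
            winter[i] = np.sum(times > t_sep)
            summer[i] = np.sum(times <= t_sep)
        for counts, mean in ((winter, 242 / 7), (summer, 0.1 * 123 / 7)):
            kmax = int(stats.poisson.ppf(0.9999, mean)) + 1
            observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
            expected = stats.poisson.pmf(np.arange(kmax + 1), mean) * reps
            expected[-1] = reps - expected[:-1].sum()
            keep = expected > 5
            chi2 = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
            pval = stats.chi2.sf(chi2, keep.sum() - 1)
            assert pval > 0.001
        # winter/summer counts are independent Poisson: correlation ~ 0
        assert abs(np.corrcoef(winter, summer)[0, 1]) < 0.05

    def test_intensity_validation(self):
        with pytest.raises(ValueError, match="cover the full year"):
            vp.SeasonalStepIntensity([("09-01", "04-30", 1.0)])
        with pytest.raises(ValueError, match="negative"):
            vp.SeasonalStepIntensity([("03-01", "02-28", -1.0)])


class TestInfectionModel:
    def test_probability_reference_values(self):
        model = vp.InfectionModel(p0=0.03, risk=vp.RiskCurve(l=1, u=2))
        assert vp.infection_probability(1e6, model) == pytest.approx(0.03)
        assert vp.infection_probability(-1e6, model) == pytest.approx(0.06)
        model4 = vp.InfectionModel(p0=0.03, risk=vp.RiskCurve(l=1, u=4))
        assert vp.infection_probability(40.0, model4) == pytest.approx(0.075)

    def test_probability_monotone_in_status(self):
        model = vp.InfectionModel(p0=0.03, risk=vp.RiskCurve(l=1, u=4))
        p = vp.infection_probability(np.linspace(0, 120, 200), model)
        assert np.all(np.diff(p) <= 1e-15)

    def test_rejects_probability_above_one(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            vp.InfectionModel(p0=0.5, risk=vp.RiskCurve(l=1, u=4))

    def test_zero_p0_never_infects(self, rng):
        model = vp.InfectionModel(p0=0.0, risk=vp.RiskCurve(l=1, u=2))
        out = vp.simulate_infections(lambda t: np.full_like(t, 30.0), np.linspace(0, 1, 50), model, rng)
        assert not any(o.infected for o in out)

    def test_certain_infection_without_refractory(self, rng):
        model = vp.InfectionModel(p0=1.0, risk=vp.RiskCurve(l=1, u=1), refractory_mean=0.0)
        out = vp.simulate_infections(lambda t: np.full_like(t, 30.0), np.linspace(0, 1, 50), model, rng)
        assert all(o.infected for o in out)

    def test_binomial_oracle_constant_status(self, rng):
        """No refractory, constant status: total infections ~ Binomial(M, p)."""
        model = vp.InfectionModel(p0=0.05, risk=vp.RiskCurve(l=1, u=1), refractory_mean=0.0)
        times = np.linspace(1e-3, 1, 200)
        reps = 2000
        total = sum(
            sum(o.infected for o in vp.simulate_infections(lambda t: np.full_like(t, 50.0), times, model, rng))
            for _ in range(reps)
        )
        m, p = 200, 0.05
        se = math.sqrt(m * p * (1 - p) / reps)
        assert total / reps == pytest.approx(m * p, abs=4 * se)

    def test_refractory_reduces_infections(self):
        model_ref = vp.InfectionModel(p0=0.5, risk=vp.RiskCurve(l=1, u=2), refractory_mean=4.0)
        model_none = vp.InfectionModel(p0=0.5, risk=vp.RiskCurve(l=1, u=2), refractory_mean=0.0)
        times = np.linspace(1e-3, 1, 100)
        status = lambda t: np.full_like(t, 20.0)
        with_ref = sum(
            sum(o.infected for o in vp.simulate_infections(status, times, model_ref, np.random.default_rng(s)))
            for s in range(300)
        )
        without = sum(
            sum(o.infected for o in vp.simulate_infections(status, times, model_none, np.random.default_rng(s)))
            for s in range(300)
        )
        assert with_ref < without

    def test_exposures_recorded_even_when_blocked(self, rng):
        model = vp.InfectionModel(p0=1.0, risk=vp.RiskCurve(l=1, u=1), refractory_mean=26.0)
        times = np.linspace(1e-3, 1, 30)
        out = vp.simulate_infections(lambda t: np.full_like(t, 30.0), times, model, rng)
        assert len(out) == 30 and all(o.exposed for o in out)
        assert 0 < sum(o.infected for o in out) < 30  # some blocked by refractory
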