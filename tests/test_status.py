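import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vitdpower as vp
from vitdpower.status import Cohort, sample_cohort


class TestMomentMatching:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(15, 5, (9.0, 0.6)), (1, 1, (1.0, 1.0)), (50, 5, (100.0, 2.0))],
    )
    def test_gamma_closed_form(self, mean, sd, expected):
        assert vp.gamma_from_moments(mean, sd) == pytest.approx(expected)

    @pytest.mark.parametrize("mean,sd", [(0, 1), (-2, 1), (5, 0), (5, -1)])
    def test_gamma_rejects_nonpositive(self, mean, sd):
        with pytest.raises(ValueError):
            vp.gamma_from_moments(mean, sd)

    @pytest.mark.parametrize(
        "mean,sd,expected", [(0.8, 0.1, (12.0, 3.0)), (0.5, 0.25, (1.5, 1.5))]
    )
    def test_beta_closed_form(self, mean, sd, expected):
        assert vp.beta_from_moments(mean, sd) == pytest.approx(expected)

    def test_beta_rejects_infeasible_moments_naming_constraint(self):
        with pytest.raises(ValueError, match="infeasible"):
            vp.beta_from_moments(0.8, 0.5)  # 0.25 >= 0.8*0.2

    @pytest.mark.parametrize(
        "draw,mean,sd",
        [("gamma", 15.0, 5.0), ("gamma", 50.0, 5.0), ("beta", 0.8, 0.1), ("beta", 0.5, 0.2)],
    )
    def test_moment_recovery_monte_carlo(self, draw, mean, sd, rng):
        """Empirical mean/SD of 1e5 draws match the requested moments (4 MC SE)."""
        n = 100_000
        if draw == "gamma":
            shape, rate = vp.gamma_from_moments(mean, sd)
            x = rng.gamma(shape, 1.0 / rate, n)
        else:
            a, b = vp.beta_from_moments(mean, sd)
            x = rng.beta(a, b, n)
        assert x.mean() == pytest.approx(mean, abs=4 * sd / math.sqrt(n))
        # SE of the SD ~ sd / sqrt(2n) for near-Gaussian sampling noise
        assert x.std(ddof=1) == pytest.approx(sd, abs=6 * sd / math.sqrt(2 * n))


@pytest.fixture(scope="module")
def pop():
    return vp.PopulationStatusSpec(mu_baseline=35.0, sigma_H=5.0, mu_A=15.0, sigma_A=5.0)


class TestSampling:
    def test_degenerate_height_perturbation(self):
        spec = vp.PopulationStatusSpec(mu_baseline=35, sigma_H=0.0, mu_A=15, sigma_A=5)
        profiles = [vp.sample_individual(spec, rng=np.random.default_rng(s)) for s in range(20)]
        assert all(p.H_i == 0.0 for p in profiles)

    def test_amplitude_moment_recovery(self, pop):
        cohort = sample_cohort(100_000, pop, rng=np.random.default_rng(7))
        assert cohort.A.mean() == pytest.approx(15.0, abs=4 * 5 / math.sqrt(100_000))

    def test_large_gamma_concentrates_uptake_at_cap(self, pop):
        spec = vp.FixedDoseSpec(dose_equiv=20.0, mu_omega=0.8, sigma_omega=0.1, gamma=1e6)
        cohort = sample_cohort(500, pop, spec, rng=np.random.default_rng(3))
        assert np.all(cohort.delta <= 20.0 + 1e-12)
        assert cohort.delta.min() > 19.9  # essentially the full dose for everyone

    def test_fixed_dose_fields_and_bounds(self, pop):
        spec = vp.FixedDoseSpec(dose_equiv=20.0, mu_omega=0.8, sigma_omega=0.1)
        p = vp.sample_individual(pop, spec, rng=np.random.default_rng(11))
        assert p.arm == "fixed"
        assert 0.0 <= p.omega_i <= 1.0
        assert 0.0 <= p.delta_i <= 20.0

    def test_concentration_fields(self, pop):
        spec = vp.ConcentrationControlSpec(mu_rho=50.0, sigma_rho=5.0)
        p = vp.sample_individual(pop, spec, rng=np.random.default_rng(11))
        assert p.arm == "concentration" and p.rho_i > 0

    def test_reproducible_under_fixed_state(self, pop):
        spec = vp.FixedDoseSpec(dose_equiv=20.0, mu_omega=0.8, sigma_omega=0.1)
        a = vp.sample_individual(pop, spec, rng=np.random.default_rng(5))
        b = vp.sample_individual(pop, spec, rng=np.random.default_rng(5))
        assert a == b

    def test_covariate_mean(self):
        spec = vp.PopulationStatusSpec(
            mu_baseline=0.0, sigma_H=5, mu_A=15, sigma_A=5, beta=(30.0, 2.0)
        )
        assert spec.mean_for([1.0, 2.5]) == pytest.approx(35.0)
        with pytest.raises(ValueError, match="covariate"):
            spec.mean_for([1.0])
        plain = vp.PopulationStatusSpec(mu_baseline=42.0, sigma_H=5, mu_A=15, sigma_A=5)
        assert plain.mean_for() == 42.0


class TestTrajectories:
    @pytest.mark.parametrize(
        "mu,t,expected", [(50, 0.0, 35.0), (50, 0.5, 65.0), (15, 0.0, 10.0)]
    )
    def test_placebo_cosine_and_floor(self, mu, t, expected):
        pop = vp.PopulationStatusSpec(mu_baseline=mu, sigma_H=5, mu_A=15, sigma_A=5)
        prof = vp.IndividualProfile(mu_i=mu, H_i=0.0, A_i=15.0)
        assert vp.status_placebo(prof, t, pop) == pytest.approx(expected)

    def test_fixed_dose_constant_when_omega_one(self, pop):
        prof = vp.IndividualProfile(mu_i=35, H_i=0, A_i=15, arm="fixed", omega_i=1.0, delta_i=20.0)
        t = np.linspace(0, 2, 101)
        np.testing.assert_allclose(
            vp.status_fixed_dose(prof, t, pop) - vp.status_placebo(prof, t, pop), 20.0
        )

    @pytest.mark.parametrize("t,uplift", [(0.0, 20.0), (0.5, 16.0)])
    def test_fixed_dose_uptake_antiphase(self, pop, t, uplift):
        # full uptake at the March trough, omega-share only at the September peak
        prof = vp.IndividualProfile(mu_i=35, H_i=0, A_i=15, arm="fixed", omega_i=0.8, delta_i=20.0)
        got = vp.status_fixed_dose(prof, t, pop) - vp.status_placebo(prof, t, pop)
        assert got == pytest.approx(uplift)

    def test_concentration_controlled_cases(self):
        pop = vp.PopulationStatusSpec(mu_baseline=50, sigma_H=5, mu_A=15, sigma_A=5)
        t = np.linspace(0, 1, 53)
        low = vp.IndividualProfile(mu_i=50, H_i=0, A_i=15, arm="concentration", rho_i=1e-9)
        np.testing.assert_allclose(
            vp.status_concentration_controlled(low, t, pop), vp.status_placebo(low, t, pop)
        )
        high = vp.IndividualProfile(mu_i=50, H_i=0, A_i=15, arm="concentration", rho_i=80.0)
        np.testing.assert_allclose(vp.status_concentration_controlled(high, t, pop), 80.0)
        mid = vp.IndividualProfile(mu_i=50, H_i=0, A_i=15, arm="concentration", rho_i=45.0)
        assert vp.status_concentration_controlled(mid, 0.0, pop) == pytest.approx(45.0)
        assert vp.status_concentration_controlled(mid, 0.5, pop) == pytest.approx(65.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        mu=st.floats(5, 100), h=st.floats(-15, 15), a=st.floats(0, 40),
        omega=st.floats(0, 1), delta=st.floats(0, 40), rho=st.floats(1, 90),
        t=st.floats(0, 3),
    )
    def test_curve_invariants(self, mu, h, a, omega, delta, rho, t):
        """Ordering, periodicity, floor and uptake bounds hold pointwise."""
        pop = vp.PopulationStatusSpec(mu_baseline=mu, sigma_H=5, mu_A=15, sigma_A=5)
        prof = vp.IndividualProfile(
            mu_i=mu, H_i=h, A_i=a, arm="fixed", omega_i=omega, delta_i=delta, rho_i=rho
        )
        pl = float(vp.status_placebo(prof, t, pop))
        fx = float(vp.status_fixed_dose(prof, t, pop))
        cc = float(vp.status_concentration_controlled(prof, t, pop))
        assert pl >= pop.floor
        assert fx >= pl - 1e-9 and cc >= pl - 1e-9
        assert cc >= rho - 1e-9
        assert delta * omega - 1e-9 <= fx - pl <= delta + 1e-9
        for curve in (vp.status_placebo, vp.status_fixed_dose, vp.status_concentration_controlled):
            assert float(curve(prof, t + 1.0, pop)) == pytest.approx(float(curve(prof, t, pop)))


class TestProfileValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(A_i=-1.0), dict(omega_i=1.5), dict(delta_i=-0.1), dict(rho_i=0.0)],
    )
    def test_invalid_profile_fields(self, kwargs):
        base = dict(mu_i=35.0, H_i=0.0, A_i=10.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            vp.IndividualProfile(**base)

    def test_population_spec_invariants(self):
        with pytest.raises(ValueError):
            vp.PopulationStatusSpec(mu_baseline=35, sigma_H=-1, mu_A=15, sigma_A=5)
        with pytest.raises(ValueError):
            vp.PopulationStatusSpec(mu_baseline=35, sigma_H=5, mu_A=-1, sigma_A=5)
        with pytest.raises(ValueError):
            vp.PopulationStatusSpec(mu_baseline=35, sigma_H=5, mu_A=15, sigma_A=0)
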