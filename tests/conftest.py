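import numpy as np
import pytest

import vitdpower as vp


@pytest.fixture(scope="session")
def seasonal_intensity() -> vp.SeasonalStepIntensity:
    """Winter-dominant exposure schedule: 1/week September-April, 0.1/week May-August."""
    return vp.SeasonalStepIntensity(
        [("09-01", "04-30", 1.0), ("05-01", "08-31", 0.1)]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_design(
    n=400,
    mu=35.0,
    dose=20.0,
    u=2.0,
    intensity=None,
    refractory=2.0,
    start="09-01",
    duration=1.0,
    ratio=1.0,
    scheme="fixed",
    p0=0.03,
    attainment=0.95,
):
    """Trial design at the heterogeneous-cohort study settings, with overrides."""
    if intensity is None:
        intensity = vp.SeasonalStepIntensity([("09-01", "04-30", 1.0), ("05-01", "08-31", 0.1)])
    pop = vp.PopulationStatusSpec(mu_baseline=mu, sigma_H=5.0, mu_A=15.0, sigma_A=5.0)
    if scheme == "fixed":
        scheme_spec = vp.FixedDoseSpec(dose_equiv=dose, mu_omega=0.8, sigma_omega=0.1)
    else:
        scheme_spec = vp.ConcentrationControlSpec(mu_rho=dose, sigma_rho=5.0)
    model = vp.InfectionModel(
        p0=p0, risk=vp.RiskCurve(l=1.0, u=u, attainment=attainment), refractory_mean=refractory
    )
    return vp.TrialDesign(
        n_placebo=n, population=pop, scheme_spec=scheme_spec, intensity=intensity,
        infection=model, start_date=start, duration=duration, ratio_r=ratio,
    )
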