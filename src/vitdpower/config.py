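"""Scenario configuration: schema, loading, and end-to-end runs.

A scenario file (YAML or JSON) collects every parameter of one power
study: the population trajectory model, the supplementation scheme, the
seasonal exposure intensity, the infection mechanism, the trial window,
the design grid (sample sizes x baselines x doses x risk ceilings) and
the Monte-Carlo settings.  Unknown keys are rejected; every default that
fills a gap is logged at INFO level.
"""

from __future__ import annotations

import json
import logging
import math
import time
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .exposure import InfectionModel, RiskCurve, SeasonalStepIntensity
from .power import PowerGrid, power_curve
from .status import ConcentrationControlSpec, FixedDoseSpec, PopulationStatusSpec
from .trial import TrialDesign

__all__ = ["ScenarioConfig", "load_config", "to_yaml", "build_designs", "run_scenario"]

log = logging.getLogger("vitdpower.config")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationConfig(_Strict):
    sigma_H: float = 5.0
    mu_A: float = 15.0
    sigma_A: float = 5.0
    nu: Optional[float] = None  # None -> pi (trough at March 1), logged
    floor: float = 10.0

    @model_validator(mode="after")
    def _check(self):
        PopulationStatusSpec(
            mu_baseline=50.0, sigma_H=self.sigma_H, mu_A=self.mu_A,
            sigma_A=self.sigma_A, nu=self.nu if self.nu is not None else math.pi,
            floor=self.floor,
        )
        return self


class FixedDoseConfig(_Strict):
    mu_omega: float = 0.8
    sigma_omega: float = 0.1
    gamma: float = 50.0

    @model_validator(mode="after")
    def _check(self):
        # beta-moment feasibility: sigma_omega^2 < mu_omega * (1 - mu_omega)
        FixedDoseSpec(
            dose_equiv=1.0, mu_omega=self.mu_omega,
            sigma_omega=self.sigma_omega, gamma=self.gamma,
        )
        return self


class ConcentrationConfig(_Strict):
    sigma_rho: float = 5.0


class IntensitySegmentConfig(_Strict):
    start: str
    end: str
    rate_per_week: float = Field(ge=0)


class RiskConfig(_Strict):
    l: float = 1.0
    x_lo: float = 10.0
    x_hi: float = 70.0
    attainment: float = 0.95

    @model_validator(mode="after")
    def _check(self):
        RiskCurve(l=self.l, u=self.l + 1.0, x_lo=self.x_lo, x_hi=self.x_hi,
                  attainment=self.attainment)
        return self


class InfectionConfig(_Strict):
    p0: float = 0.03
    refractory_mean_weeks: float = 2.0


class TrialConfig(_Strict):
    start: str = "09-01"
    duration_years: float = 1.0
    ratio: float = 1.0


class GridConfig(_Strict):
    n: List[int]
    mu: List[float]
    dose: List[float]  # 25OHD dose equivalent (fixed) or target mean rho (RCCT)
    u: List[float] = [2.0]

    @model_validator(mode="after")
    def _check(self):
        if not (self.n and self.mu and self.dose and self.u):
            raise ValueError("grid axes n, mu, dose, u must all be non-empty")
        return self


class MonteCarloConfig(_Strict):
    n_sims: int = 500
    replicates: int = 5
    n_boot: int = 500
    alpha: float = 0.05
    test: Literal["means", "proportions"] = "means"
    n_jobs: int = 1


class OutputConfig(_Strict):
    dir: str = "results"
    plots: bool = False
    details: bool = False  # also write one record per simulated hypothesis test


class ScenarioConfig(_Strict):
    """Complete parameter set for one power study."""

    name: str
    seed: int = 1
    scheme: Literal["fixed", "concentration"] = "fixed"
    population: PopulationConfig = PopulationConfig()
    fixed_dose: FixedDoseConfig = FixedDoseConfig()
    concentration: ConcentrationConfig = ConcentrationConfig()
    intensity: List[IntensitySegmentConfig]
    risk: RiskConfig = RiskConfig()
    infection: InfectionConfig = InfectionConfig()
    trial: TrialConfig = TrialConfig()
    grid: GridConfig
    mc: MonteCarloConfig = MonteCarloConfig()
    output: OutputConfig = OutputConfig()

    @model_validator(mode="after")
    def _check(self):
        self.build_intensity()  # validates full-year coverage
        for u in self.grid.u:
            InfectionModel(
                p0=self.infection.p0,
                risk=RiskCurve(l=self.risk.l, u=u, x_lo=self.risk.x_lo,
                               x_hi=self.risk.x_hi, attainment=self.risk.attainment),
                refractory_mean=self.infection.refractory_mean_weeks,
            )
        return self

    @property
    def nu(self) -> float:
        return self.population.nu if self.population.nu is not None else math.pi

    def build_population(self, mu: float) -> PopulationStatusSpec:
        return PopulationStatusSpec(
            mu_baseline=mu, sigma_H=self.population.sigma_H, mu_A=self.population.mu_A,
            sigma_A=self.population.sigma_A, nu=self.nu, floor=self.population.floor,
        )

    def build_scheme(self, dose: float):
        if self.scheme == "fixed":
            return FixedDoseSpec(
                dose_equiv=dose, mu_omega=self.fixed_dose.mu_omega,
                sigma_omega=self.fixed_dose.sigma_omega, gamma=self.fixed_dose.gamma,
            )
        return ConcentrationControlSpec(mu_rho=dose, sigma_rho=self.concentration.sigma_rho)

    def build_intensity(self) -> SeasonalStepIntensity:
        return SeasonalStepIntensity(
            [(seg.start, seg.end, seg.rate_per_week) for seg in self.intensity]
        )

    def build_infection(self, u: float) -> InfectionModel:
        return InfectionModel(
            p0=self.infection.p0,
            risk=RiskCurve(l=self.risk.l, u=u, x_lo=self.risk.x_lo,
                           x_hi=self.risk.x_hi, attainment=self.risk.attainment),
            refractory_mean=self.infection.refractory_mean_weeks,
        )

    def build_design(self, n: int, mu: float, dose: float, u: float) -> TrialDesign:
        return TrialDesign(
            n_placebo=n, population=self.build_population(mu),
            scheme_spec=self.build_scheme(dose), intensity=self.build_intensity(),
            infection=self.build_infection(u), start_date=self.trial.start,
            duration=self.trial.duration_years, ratio_r=self.trial.ratio,
        )


def _log_defaults(model: BaseModel, prefix: str = "") -> None:
    for name, finfo in type(model).model_fields.items():
        value = getattr(model, name)
        if name not in model.model_fields_set:
            shown = "pi" if (prefix + name) == "population.nu" and value is None else value
            log.info("config default applied: %s = %r", prefix + name, shown)
        if isinstance(value, BaseModel):
            _log_defaults(value, prefix=f"{prefix}{name}.")


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario file (YAML by default, JSON accepted)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    config = ScenarioConfig.model_validate(data)
    _log_defaults(config)
    return config


def to_yaml(config: ScenarioConfig) -> str:
    """Canonical YAML serialization (round-trips through load)."""
    return yaml.safe_dump(config.model_dump(), sort_keys=True)


def build_designs(config: ScenarioConfig) -> list[TrialDesign]:
    """All grid-cell designs, ordered by (u, dose, mu, n)."""
    return [
        config.build_design(n, mu, dose, u)
        for u in config.grid.u
        for dose in config.grid.dose
        for mu in config.grid.mu
        for n in config.grid.n
    ]


def run_scenario(
    config: ScenarioConfig,
    outdir=None,
    n_sims: Optional[int] = None,
    replicates: Optional[int] = None,
    n_jobs: Optional[int] = None,
    seed: Optional[int] = None,
    plots: Optional[bool] = None,
) -> PowerGrid:
    """Execute the scenario's full power grid and write its outputs.

    Writes a tidy CSV (one row per cell-replicate), a pivoted power table,
    JSON run metadata, and optional power-surface figures.  Keyword
    overrides allow reduced-size reruns without editing the file.
    """
    outdir = Path(outdir if outdir is not None else config.output.dir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_sims = n_sims if n_sims is not None else config.mc.n_sims
    replicates = replicates if replicates is not None else config.mc.replicates
    n_jobs = n_jobs if n_jobs is not None else config.mc.n_jobs
    seed = seed if seed is not None else config.seed
    do_plots = plots if plots is not None else config.output.plots

    start = time.time()
    grid = power_curve(
        build_designs(config), test=config.mc.test, n_sims=n_sims,
        alpha=config.mc.alpha, n_boot=config.mc.n_boot, replicates=replicates,
        seed=seed, n_jobs=n_jobs, collect_tests=config.output.details,
    )
    elapsed = time.time() - start

    tidy_path = outdir / f"{config.name}_power_tidy.csv"
    grid.to_csv(tidy_path)
    if grid.test_records is not None:
        grid.test_records.to_csv(outdir / f"{config.name}_tests.csv", index=False)
    grid.pivot().to_csv(outdir / f"{config.name}_power_pivot.csv")
    metadata = {
        "scenario": config.name,
        "seed": seed,
        "n_sims": n_sims,
        "replicates": replicates,
        "test": config.mc.test,
        "alpha": config.mc.alpha,
        "n_boot": config.mc.n_boot,
        "wall_time_s": round(elapsed, 3),
        "vitdpower_version": __version__,
        "config": config.model_dump(),
    }
    (outdir / f"{config.name}_run_metadata.json").write_text(json.dumps(metadata, indent=2))
    if do_plots:
        from .plotting import plot_power_surface

        plot_power_surface(grid, path=outdir / f"{config.name}_power_surface.png")
    log.info("scenario %s: %d cells x %d replicates in %.1fs -> %s",
             config.name, len(build_designs(config)), replicates, elapsed, outdir)
    return grid
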