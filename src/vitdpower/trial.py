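"""Two-armed trial assembly: cohorts, exposures, infections, counts.

A :class:`TrialDesign` bundles the population trajectory model, the
supplementation scheme, the seasonal exposure intensity, the infection
mechanism and the trial window.  :func:`simulate_trial` produces one trial
realisation — per-participant infection counts for the placebo and
supplement arms — with every participant drawn fresh (i.i.d. cohorts per
realisation) and exposures restricted to the trial window.

The whole chain is vectorised across participants: exposure times are
drawn by conditioning on the Poisson total count and inverting the
cumulative intensity, which for a piecewise-constant rate is exact and
identical in law to thinning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import quad

from ._calendar import date_to_t
from .exposure import InfectionModel, SeasonalStepIntensity
from .status import (
    ConcentrationControlSpec,
    FixedDoseSpec,
    IndividualProfile,
    PopulationStatusSpec,
    _placebo_kernel,
    _uptake_kernel,
    status_concentration_controlled,
    status_fixed_dose,
    status_placebo,
)

__all__ = ["TrialDesign", "TrialRealisation", "simulate_trial", "expected_infections_numeric"]


@dataclass(frozen=True)
class TrialDesign:
    """Complete specification of one simulated two-armed trial.

    The supplement arm has ``floor(ratio_r * n_placebo)`` participants.
    ``start_date`` is a calendar day (t=0 = March 1 convention) and
    ``duration`` is in years.
    """

    n_placebo: int
    population: PopulationStatusSpec
    scheme_spec: "FixedDoseSpec | ConcentrationControlSpec"
    intensity: SeasonalStepIntensity
    infection: InfectionModel
    start_date: "str | tuple[int, int]" = "09-01"
    duration: float = 1.0
    ratio_r: float = 1.0

    def __post_init__(self) -> None:
        if self.n_placebo < 2:
            raise ValueError(f"n_placebo must be >= 2, got {self.n_placebo}")
        if self.n_supp < 2:
            raise ValueError(
                f"supplement arm floor(r*n) = {self.n_supp} must be >= 2"
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def n_supp(self) -> int:
        return math.floor(self.ratio_r * self.n_placebo)

    @property
    def scheme(self) -> Literal["fixed", "concentration"]:
        return "fixed" if isinstance(self.scheme_spec, FixedDoseSpec) else "concentration"

    @property
    def window(self) -> tuple[float, float]:
        t0 = date_to_t(self.start_date)
        return t0, t0 + self.duration


@dataclass
class TrialRealisation:
    """Per-participant infection counts for one simulated trial."""

    counts_placebo: np.ndarray
    counts_supp: np.ndarray

    @property
    def any_placebo(self) -> np.ndarray:
        """Indicator of >= 1 infection, placebo arm."""
        return (self.counts_placebo > 0).astype(int)

    @property
    def any_supp(self) -> np.ndarray:
        return (self.counts_supp > 0).astype(int)

    def to_frame(self) -> pd.DataFrame:
        """One row per participant: arm, infection count."""
        return pd.DataFrame(
            {
                "arm": ["placebo"] * len(self.counts_placebo)
                + ["supplement"] * len(self.counts_supp),
                "count": np.concatenate([self.counts_placebo, self.counts_supp]),
            }
        )


def _refractory_scan(pid, times, durations) -> np.ndarray:
    """Keep-mask over candidate infections sorted by (participant, time).

    Each kept infection opens a refractory window of the pre-drawn length;
    candidates inside the window of the same participant are suppressed.
    """
    keep = [False] * len(pid)
    pid_l, t_l, d_l = pid.tolist(), times.tolist(), durations.tolist()
    last = -1
    blocked_until = -math.inf
    for k in range(len(pid_l)):
        if pid_l[k] != last:
            last = pid_l[k]
            blocked_until = -math.inf
        if t_l[k] > blocked_until:
            keep[k] = True
            blocked_until = t_l[k] + d_l[k]
    return np.asarray(keep, dtype=bool)


def _simulate_counts(design: TrialDesign, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised single-trial simulation; returns (counts_pl, counts_supp)."""
    pop = design.population
    n_pl, n_su = design.n_placebo, design.n_supp
    n_tot = n_pl + n_su

    shape_A, rate_A = pop.amplitude_params()
    H = rng.normal(0.0, pop.sigma_H, n_tot) if pop.sigma_H > 0 else np.zeros(n_tot)
    A = rng.gamma(shape_A, 1.0 / rate_A, n_tot)

    spec = design.scheme_spec
    if isinstance(spec, FixedDoseSpec):
        a_w, b_w = spec.omega_params()
        omega = rng.beta(a_w, b_w, n_su)
        delta = np.broadcast_to(
            np.asarray(spec.uptake_sampler(spec.dose_equiv, spec.gamma, rng, n_su)), (n_su,)
        )
    else:
        shape_r, rate_r = spec.rho_params()
        rho = rng.gamma(shape_r, 1.0 / rate_r, n_su)

    t0, t1 = design.window
    lam_total = design.intensity.integral(t0, t1)
    n_exp = rng.poisson(lam_total, n_tot)
    pid = np.repeat(np.arange(n_tot), n_exp)
    total = pid.size
    if total == 0:
        return np.zeros(n_pl, dtype=np.int64), np.zeros(n_su, dtype=np.int64)

    btimes, bcum = design.intensity.unwrapped_breakpoints(t0, t1)
    t = np.interp(rng.random(total) * lam_total, bcum, btimes)
    order = np.lexsort((t, pid))
    pid, t = pid[order], t[order]

    V = _placebo_kernel(pop.mu_baseline, H[pid], A[pid], t, pop.nu, pop.floor)
    supp = pid >= n_pl
    if isinstance(spec, FixedDoseSpec):
        j = pid[supp] - n_pl
        V[supp] += _uptake_kernel(delta[j], omega[j], t[supp], pop.nu)
    else:
        j = pid[supp] - n_pl
        V[supp] = np.maximum(rho[j], V[supp])

    model = design.infection
    p = model.p0 * model.risk(V)
    cand = rng.random(total) < p

    if model.refractory_mean > 0 and cand.any():
        idx = np.flatnonzero(cand)
        durations = rng.exponential(model.refractory_mean_years, idx.size)
        keep = _refractory_scan(pid[idx], t[idx], durations)
        infected_pid = pid[idx[keep]]
    else:
        infected_pid = pid[cand]

    counts = np.bincount(infected_pid, minlength=n_tot)
    return counts[:n_pl].astype(np.int64), counts[n_pl:].astype(np.int64)


def simulate_trial(
    design: TrialDesign, rng: "np.random.Generator | int | None" = None
) -> TrialRealisation:
    """Simulate one complete trial realisation under the design.

    Placebo participants follow the unsupplemented status curve; supplement
    participants follow the design's scheme.  Reproducible for a fixed
    generator state.
    """
    rng = np.random.default_rng(rng)
    counts_pl, counts_su = _simulate_counts(design, rng)
    return TrialRealisation(counts_placebo=counts_pl, counts_supp=counts_su)


def expected_infections_numeric(
    profile: IndividualProfile, design: TrialDesign, rtol: float = 1e-8
) -> float:
    """Expected infection count for one participant, by quadrature.

    Integrates ``lambda(t) * p0 * g(V(t))`` over the trial window — an
    independent check on the generative chain.  Valid only without a
    refractory period (infections are then a thinned Poisson process whose
    mean is this integral); refuses otherwise.
    """
    model = design.infection
    if model.refractory_mean != 0:
        raise ValueError(
            "quadrature oracle requires refractory_mean = 0; with a "
            "non-susceptible period infection counts are not Poisson"
        )
    pop = design.population
    if profile.arm == "placebo":
        status = lambda t: status_placebo(profile, t, pop)
    elif profile.arm == "fixed":
        status = lambda t: status_fixed_dose(profile, t, pop)
    else:
        status = lambda t: status_concentration_controlled(profile, t, pop)

    if model.p0 == 0:
        return 0.0
    t0, t1 = design.window
    btimes, _ = design.intensity.unwrapped_breakpoints(t0, t1)
    total = 0.0
    for a, b in zip(btimes[:-1], btimes[1:]):
        rate = float(design.intensity.rate(0.5 * (a + b)))
        if rate == 0:
            continue
        integrand = lambda t: model.p0 * float(model.risk(status(t)))
        val, _err = quad(integrand, a, b, epsrel=rtol, limit=200)
        total += rate * val
    return total
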