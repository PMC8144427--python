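"""Individual 25OHD status trajectories.

An individual's vitamin D status (circulating 25OHD, nmol/L) is modelled as
a floored, phase-shifted cosine over the year:

    V_pl(t) = max{ mu_i + H_i + A_i * cos(2*pi*t - nu), floor }

with ``t`` in years and ``t = 0`` at March 1 when the default phase
``nu = pi`` puts the seasonal trough.  Heterogeneity across participants
enters through the individual mean ``mu_i`` (optionally a linear function of
covariates), a Gaussian height perturbation ``H_i`` and a gamma-distributed
seasonal amplitude ``A_i``.

Two supplementation schemes modify this curve:

* fixed dose (RCT): ``V_fix(t) = V_pl(t) + F_i(t)`` where the uptake
  function ``F_i`` oscillates between a floor ``delta_i * omega_i`` and the
  full per-individual dose benefit ``delta_i``, in anti-phase with the
  status curve (more uptake when deficient);
* concentration controlled (RCCT): ``V_dyn(t) = max{rho_i, V_pl(t)}``,
  dosing keeps status above a personal target ``rho_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "PopulationStatusSpec",
    "FixedDoseSpec",
    "ConcentrationControlSpec",
    "IndividualProfile",
    "gamma_from_moments",
    "beta_from_moments",
    "sample_individual",
    "sample_cohort",
    "Cohort",
    "status_placebo",
    "status_fixed_dose",
    "status_concentration_controlled",
]


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape and rate of the gamma distribution with the given mean and SD.

    ``Gamma(shape, rate)`` has mean ``shape/rate`` and variance
    ``shape/rate**2``, so ``shape = (mean/sd)**2`` and ``rate = mean/sd**2``.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError(f"gamma moments require mean > 0 and sd > 0, got ({mean}, {sd})")
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return shape, rate


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters (a, b) of the beta distribution with the given moments.

    Feasible only when ``sd**2 < mean * (1 - mean)``.
    """
    if not 0 < mean < 1:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0:
        raise ValueError(f"beta sd must be positive, got {sd}")
    if sd**2 >= mean * (1 - mean):
        raise ValueError(
            f"infeasible beta moments: sd^2 = {sd**2:g} must be < "
            f"mean*(1-mean) = {mean * (1 - mean):g}"
        )
    total = mean * (1 - mean) / sd**2 - 1
    a = mean * total
    b = (1 - mean) * total
    return a, b


@dataclass(frozen=True)
class PopulationStatusSpec:
    """Population-level parameters of the placebo 25OHD curve.

    Parameters
    ----------
    mu_baseline : float
        Annual mean 25OHD in the population (nmol/L).  Ignored for an
        individual when covariates are supplied.
    sigma_H : float
        SD of the individual height perturbation ``H_i`` (nmol/L).
    mu_A, sigma_A : float
        Mean and SD of the seasonal amplitude ``A_i`` (nmol/L); matched to a
        gamma distribution by moments.
    nu : float
        Phase adjustment in radians; the default ``pi`` places the trough at
        ``t = 0`` (March 1).
    floor : float
        Detectability threshold (nmol/L); the placebo curve never drops
        below it.
    beta : sequence of float, optional
        Covariate coefficients; when given, an individual with covariate
        vector ``x_i`` has mean ``mu_i = x_i @ beta``.
    """

    mu_baseline: float
    sigma_H: float
    mu_A: float
    sigma_A: float
    nu: float = np.pi
    floor: float = 10.0
    beta: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.mu_A < 0:
            raise ValueError(f"mu_A must be >= 0, got {self.mu_A}")
        if self.sigma_A <= 0:
            raise ValueError(f"sigma_A must be > 0, got {self.sigma_A}")
        if self.sigma_H < 0:
            raise ValueError(f"sigma_H must be >= 0, got {self.sigma_H}")
        if self.floor < 0:
            raise ValueError(f"floor must be >= 0, got {self.floor}")
        if self.beta is not None:
            object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))

    def amplitude_params(self) -> tuple[float, float]:
        return gamma_from_moments(self.mu_A, self.sigma_A)

    def mean_for(self, x: Optional[Sequence[float]] = None) -> float:
        """Individual mean mu_i: x @ beta when covariates are used."""
        if self.beta is None:
            if x is not None:
                raise ValueError("covariates supplied but spec has no beta coefficients")
            return self.mu_baseline
        if x is None:
            raise ValueError("spec has beta coefficients; a covariate vector is required")
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.beta),):
            raise ValueError(
                f"covariate vector length {x.shape} does not match beta length {len(self.beta)}"
            )
        return float(x @ np.asarray(self.beta))


def _default_uptake_sampler(
    dose_equiv: float, gamma: float, rng: np.random.Generator, size: Optional[int] = None
):
    """Per-individual dose benefit delta_i = dose_equiv * Beta(gamma, 1).

    Capped at the administered dose; large ``gamma`` concentrates the uptake
    at the cap (Beta(gamma, 1) has mean gamma/(gamma+1)).
    """
    if dose_equiv == 0:
        return 0.0 if size is None else np.zeros(size)
    return dose_equiv * rng.beta(gamma, 1.0, size=size)


@dataclass(frozen=True)
class FixedDoseSpec:
    """Fixed daily-dose supplementation scheme (conventional RCT arm).

    ``dose_equiv`` is the 25OHD increase (nmol/L) the administered dose is
    equivalent to; it caps the individual benefit ``delta_i``.  ``mu_omega``
    and ``sigma_omega`` are the beta-matched moments of the always-utilised
    proportion ``omega_i``; ``gamma`` concentrates ``delta_i`` near the cap.
    """

    dose_equiv: float
    mu_omega: float
    sigma_omega: float
    gamma: float = 50.0
    uptake_sampler: Callable = field(default=_default_uptake_sampler, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.dose_equiv < 0:
            raise ValueError(f"dose_equiv must be >= 0, got {self.dose_equiv}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        beta_from_moments(self.mu_omega, self.sigma_omega)  # validates feasibility

    def omega_params(self) -> tuple[float, float]:
        return beta_from_moments(self.mu_omega, self.sigma_omega)


@dataclass(frozen=True)
class ConcentrationControlSpec:
    """Concentration-controlled scheme (RCCT): status kept above a personal
    threshold ``rho_i ~ Gamma`` with the given mean and SD (nmol/L)."""

    mu_rho: float
    sigma_rho: float

    def __post_init__(self) -> None:
        if self.mu_rho <= 0 or self.sigma_rho <= 0:
            raise ValueError(
                f"rho moments must be positive, got ({self.mu_rho}, {self.sigma_rho})"
            )

    def rho_params(self) -> tuple[float, float]:
        return gamma_from_moments(self.mu_rho, self.sigma_rho)


Arm = Literal["placebo", "fixed", "concentration"]


@dataclass(frozen=True)
class IndividualProfile:
    """One participant's realised trajectory parameters."""

    mu_i: float
    H_i: float
    A_i: float
    arm: Arm = "placebo"
    omega_i: Optional[float] = None
    delta_i: Optional[float] = None
    rho_i: Optional[float] = None

    def __post_init__(self) -> None:
        if self.A_i < 0:
            raise ValueError(f"A_i must be >= 0, got {self.A_i}")
        if self.omega_i is not None and not 0 <= self.omega_i <= 1:
            raise ValueError(f"omega_i must lie in [0, 1], got {self.omega_i}")
        if self.delta_i is not None and self.delta_i < 0:
            raise ValueError(f"delta_i must be >= 0, got {self.delta_i}")
        if self.rho_i is not None and self.rho_i <= 0:
            raise ValueError(f"rho_i must be > 0, got {self.rho_i}")


def sample_individual(
    pop: PopulationStatusSpec,
    scheme_spec: "FixedDoseSpec | ConcentrationControlSpec | None" = None,
    rng: "np.random.Generator | int | None" = None,
    x: Optional[Sequence[float]] = None,
) -> IndividualProfile:
    """Draw one participant's trajectory parameters.

    ``A_i ~ Gamma`` and ``H_i ~ N(0, sigma_H^2)`` always; scheme-specific
    parameters (``omega_i``, ``delta_i`` for a fixed dose; ``rho_i`` for
    concentration control) are drawn when the matching spec is given.
    """
    rng = np.random.default_rng(rng)
    shape_A, rate_A = pop.amplitude_params()
    mu_i = pop.mean_for(x)
    H_i = float(rng.normal(0.0, pop.sigma_H)) if pop.sigma_H > 0 else 0.0
    A_i = float(rng.gamma(shape_A, 1.0 / rate_A))
    if scheme_spec is None:
        return IndividualProfile(mu_i=mu_i, H_i=H_i, A_i=A_i, arm="placebo")
    if isinstance(scheme_spec, FixedDoseSpec):
        a_w, b_w = scheme_spec.omega_params()
        omega_i = float(rng.beta(a_w, b_w))
        delta_i = float(
            scheme_spec.uptake_sampler(scheme_spec.dose_equiv, scheme_spec.gamma, rng)
        )
        return IndividualProfile(
            mu_i=mu_i, H_i=H_i, A_i=A_i, arm="fixed", omega_i=omega_i, delta_i=delta_i
        )
    if isinstance(scheme_spec, ConcentrationControlSpec):
        shape_r, rate_r = scheme_spec.rho_params()
        rho_i = float(rng.gamma(shape_r, 1.0 / rate_r))
        return IndividualProfile(mu_i=mu_i, H_i=H_i, A_i=A_i, arm="concentration", rho_i=rho_i)
    raise TypeError(f"unknown scheme spec: {type(scheme_spec).__name__}")


@dataclass
class Cohort:
    """Vectorised trajectory parameters for a group of participants."""

    mu: np.ndarray
    H: np.ndarray
    A: np.ndarray
    arm: Arm
    omega: Optional[np.ndarray] = None
    delta: Optional[np.ndarray] = None
    rho: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.H.shape[0]


def sample_cohort(
    n: int,
    pop: PopulationStatusSpec,
    scheme_spec: "FixedDoseSpec | ConcentrationControlSpec | None" = None,
    rng: "np.random.Generator | int | None" = None,
) -> Cohort:
    """Draw ``n`` i.i.d. participants as arrays (fast path of sample_individual)."""
    rng = np.random.default_rng(rng)
    shape_A, rate_A = pop.amplitude_params()
    mu = np.full(n, pop.mu_baseline)
    H = rng.normal(0.0, pop.sigma_H, n) if pop.sigma_H > 0 else np.zeros(n)
    A = rng.gamma(shape_A, 1.0 / rate_A, n)
    if scheme_spec is None:
        return Cohort(mu=mu, H=H, A=A, arm="placebo")
    if isinstance(scheme_spec, FixedDoseSpec):
        a_w, b_w = scheme_spec.omega_params()
        omega = rng.beta(a_w, b_w, n)
        delta = np.broadcast_to(
            scheme_spec.uptake_sampler(scheme_spec.dose_equiv, scheme_spec.gamma, rng, n), (n,)
        )
        return Cohort(mu=mu, H=H, A=A, arm="fixed", omega=omega, delta=delta)
    if isinstance(scheme_spec, ConcentrationControlSpec):
        shape_r, rate_r = scheme_spec.rho_params()
        rho = rng.gamma(shape_r, 1.0 / rate_r, n)
        return Cohort(mu=mu, H=H, A=A, arm="concentration", rho=rho)
    raise TypeError(f"unknown scheme spec: {type(scheme_spec).__name__}")


# ---------------------------------------------------------------------------
# trajectory evaluation (pure functions of (parameters, t); broadcast over t
# and over individuals)

def _placebo_kernel(mu, H, A, t, nu, floor):
    return np.maximum(mu + H + A * np.cos(2 * np.pi * np.asarray(t, dtype=float) - nu), floor)


def _uptake_kernel(delta, omega, t, nu):
    t = np.asarray(t, dtype=float)
    swing = 0.5 * (1.0 + np.sin(2 * np.pi * t - np.pi / 2.0 - nu))
    return delta * (omega + (1.0 - omega) * swing)


def status_placebo(profile: IndividualProfile, t, pop: PopulationStatusSpec):
    """Placebo (unsupplemented) 25OHD status at time ``t`` (years)."""
    return _placebo_kernel(profile.mu_i, profile.H_i, profile.A_i, t, pop.nu, pop.floor)


def status_fixed_dose(profile: IndividualProfile, t, pop: PopulationStatusSpec):
    """Fixed-dose status: placebo curve plus the seasonal uptake ``F_i(t)``.

    ``F_i(t) = delta_i * [omega_i + (1 - omega_i) * (1 + sin(2*pi*t - pi/2 - nu))/2]``
    lies in ``[delta_i * omega_i, delta_i]`` and peaks where the placebo curve
    is lowest (anti-phase uptake).
    """
    if profile.omega_i is None or profile.delta_i is None:
        raise ValueError("profile has no fixed-dose parameters (omega_i, delta_i)")
    return status_placebo(profile, t, pop) + _uptake_kernel(
        profile.delta_i, profile.omega_i, t, pop.nu
    )


def status_concentration_controlled(profile: IndividualProfile, t, pop: PopulationStatusSpec):
    """Concentration-controlled status: placebo curve held above ``rho_i``."""
    if profile.rho_i is None:
        raise ValueError("profile has no concentration-control parameter (rho_i)")
    return np.maximum(profile.rho_i, status_placebo(profile, t, pop))
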