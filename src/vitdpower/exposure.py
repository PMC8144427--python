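"""Exposure processes and the status -> infection risk model.

Exposures to infection arrive as a (non-)homogeneous Poisson process whose
rate is a piecewise-constant function of the calendar (e.g. 1 expected
exposure per week September through April, 0.1 per week May through August
for a winter-seasonal respiratory infection).

Given status ``x`` (25OHD, nmol/L) at the moment of exposure, the
probability of developing infection is ``p0 * g(x)`` where ``p0`` is the
per-exposure infection probability of a fully vitamin-D-sufficient
individual and ``g`` is a monotone non-increasing generalised logistic
relative-risk curve

    g(x) = l + (u - l) / (1 + exp(a + b*x)),

calibrated so that the steepest change falls between two reference status
points (defaults 10 and 70 nmol/L).  After an infection an exponentially
distributed non-susceptible (refractory) period may block further
infections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.special import expit

from ._calendar import WEEKS_PER_YEAR, date_to_t, date_to_t_end, weeks_to_years

__all__ = [
    "SeasonalStepIntensity",
    "RiskCurve",
    "InfectionModel",
    "calibrate_logistic",
    "simulate_exposure_times",
    "infection_probability",
    "simulate_infections",
    "ExposureOutcome",
]

_DAY = 1.0 / 365.0  # tolerance for "covers the year" checks


class SeasonalStepIntensity:
    """Piecewise-constant exposure intensity over the calendar year.

    Built from inclusive calendar-date segments with rates in exposures per
    week; internally a periodic step function ``lambda(t)`` in per-year
    units (rate/week * 365/7) on model time ``t`` (years, t=0 = March 1).
    Segments must tile the full year without overlap.
    """

    def __init__(self, segments: Sequence[tuple]):
        pieces: list[tuple[float, float, float]] = []  # (t_start, t_end, rate/yr)
        for start, end, rate_per_week in segments:
            if rate_per_week < 0:
                raise ValueError(f"negative exposure rate: {rate_per_week}")
            ts = date_to_t(start)
            te = date_to_t_end(end)
            rate_yr = rate_per_week * WEEKS_PER_YEAR
            if te > ts:
                pieces.append((ts, te, rate_yr))
            else:  # wraps through t = 0 (e.g. September..April)
                pieces.append((ts, 1.0, rate_yr))
                if te > 0:
                    pieces.append((0.0, te, rate_yr))
        pieces.sort()
        covered = sum(te - ts for ts, te, _ in pieces)
        if abs(covered - 1.0) > 0.5 * _DAY:
            raise ValueError(
                f"intensity segments must cover the full year exactly once; "
                f"covered {covered * 365:.1f} of 365 days"
            )
        cursor = 0.0
        for ts, te, _ in pieces:
            if abs(ts - cursor) > 0.5 * _DAY:
                raise ValueError("intensity segments overlap or leave a gap")
            cursor = te
        self._bounds = np.array([p[0] for p in pieces] + [1.0])
        self._rates = np.array([p[2] for p in pieces])
        self._piece_mass = self._rates * np.diff(self._bounds)
        self._cum = np.concatenate([[0.0], np.cumsum(self._piece_mass)])

    @classmethod
    def constant(cls, rate_per_week: float) -> "SeasonalStepIntensity":
        return cls([("03-01", "02-28", rate_per_week)])

    @property
    def annual_mean_count(self) -> float:
        """Expected exposures per year, integral of lambda over one period."""
        return float(self._cum[-1])

    @property
    def max_rate(self) -> float:
        """Largest per-year rate (thinning envelope)."""
        return float(self._rates.max())

    def rate(self, t):
        """lambda(t) in per-year units; periodic with period 1."""
        frac = np.mod(np.asarray(t, dtype=float), 1.0)
        idx = np.clip(np.searchsorted(self._bounds, frac, side="right") - 1, 0, len(self._rates) - 1)
        return self._rates[idx]

    def integral(self, t_start: float, t_end: float) -> float:
        """Expected exposure count over (t_start, t_end]."""
        if t_end < t_start:
            raise ValueError("t_end must be >= t_start")
        return self._cum_from_zero(t_end) - self._cum_from_zero(t_start)

    def _cum_from_zero(self, t: float) -> float:
        full, frac = divmod(t, 1.0)
        part = float(np.interp(frac, self._bounds, self._cum))
        return full * float(self._cum[-1]) + part

    def unwrapped_breakpoints(self, t_start: float, t_end: float):
        """Breakpoints and cumulative intensity over a window (for inverse-CDF
        sampling); returns (times, cum) with cum[0]=0, cum[-1]=integral."""
        k0 = math.floor(t_start)
        k1 = math.ceil(t_end)
        times = [t_start]
        for year in range(int(k0), int(k1)):
            for b in self._bounds[:-1]:
                tb = year + float(b)
                if t_start < tb < t_end:
                    times.append(tb)
        times.append(t_end)
        times = np.array(sorted(set(times)))
        cum = np.array([self._cum_from_zero(t) for t in times])
        return times, cum - cum[0]


def calibrate_logistic(
    l: float, u: float, x_lo: float = 10.0, x_hi: float = 70.0, attainment: float = 0.95
) -> tuple[float, float]:
    """Coefficients (a, b) of the generalised logistic risk curve.

    Solves ``g(x_lo) = l + attainment*(u-l)`` and
    ``g(x_hi) = l + (1-attainment)*(u-l)``: the curve attains the stated
    fraction of its range at the lower reference point and the complementary
    fraction at the upper one, so the steepest decline lies between them.
    """
    if u < l:
        raise ValueError(f"risk bounds need u >= l, got l={l}, u={u}")
    if x_lo >= x_hi:
        raise ValueError(f"reference points need x_lo < x_hi, got {x_lo}, {x_hi}")
    if not 0.5 < attainment < 1.0:
        raise ValueError(f"attainment must lie in (0.5, 1), got {attainment}")
    if u == l:
        return math.nan, 0.0  # constant curve g == l; b undefined
    c = math.log(attainment / (1.0 - attainment))
    b = 2.0 * c / (x_hi - x_lo)
    a = -c - b * x_lo
    return a, b


@dataclass(frozen=True)
class RiskCurve:
    """Generalised logistic relative-risk scaling of infection with status.

    ``l`` and ``u`` are the relative risks of a fully sufficient and a fully
    insufficient individual; ``u - l`` is how much more likely infection is
    at complete insufficiency.  ``x_lo``/``x_hi`` are the reference status
    points between which the steepest change occurs.
    """

    l: float = 1.0
    u: float = 2.0
    x_lo: float = 10.0
    x_hi: float = 70.0
    attainment: float = 0.95

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError(f"l must be >= 0, got {self.l}")
        a, b = calibrate_logistic(self.l, self.u, self.x_lo, self.x_hi, self.attainment)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def is_constant(self) -> bool:
        return self.u == self.l

    def __call__(self, x):
        """Relative risk g(x) at status x (nmol/L); vectorised."""
        if self.is_constant:
            return np.full_like(np.asarray(x, dtype=float), self.l)
        x = np.asarray(x, dtype=float)
        return self.l + (self.u - self.l) * expit(-(self.a + self.b * x))


@dataclass(frozen=True)
class InfectionModel:
    """Per-exposure infection mechanism: p0 * g(status), with an optional
    exponential non-susceptible period after each infection."""

    p0: float
    risk: RiskCurve
    refractory_mean: float = 2.0  # weeks; 0 disables

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must lie in [0, 1], got {self.p0}")
        if self.p0 * self.risk.u > 1.0 + 1e-12:
            raise ValueError(
                f"p0 * u = {self.p0 * self.risk.u:g} exceeds 1; infection "
                "probability must stay a probability at full insufficiency"
            )
        if self.refractory_mean < 0:
            raise ValueError(f"refractory_mean must be >= 0, got {self.refractory_mean}")

    @property
    def refractory_mean_years(self) -> float:
        return weeks_to_years(self.refractory_mean)


def infection_probability(status, model: InfectionModel):
    """Probability of infection upon one exposure at the given status."""
    return model.p0 * model.risk(status)


def simulate_exposure_times(
    intensity: SeasonalStepIntensity,
    window: tuple[float, float],
    rng: "np.random.Generator | int | None" = None,
) -> np.ndarray:
    """Exposure times in (t_start, t_end] from the NHPP, by thinning.

    Candidate events are drawn from a homogeneous process at the maximum
    segment rate and kept with probability ``lambda(t)/lambda_max`` —
    exact for piecewise-constant intensities.
    """
    t_start, t_end = window
    if t_start >= t_end:
        raise ValueError(f"window must satisfy t_start < t_end, got {window}")
    rng = np.random.default_rng(rng)
    lam_max = intensity.max_rate
    if lam_max == 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * (t_end - t_start))
    times = np.sort(t_start + (t_end - t_start) * rng.random(n_cand))
    keep = rng.random(n_cand) < intensity.rate(times) / lam_max
    return times[keep]


class ExposureOutcome(NamedTuple):
    time: float
    exposed: bool
    infected: bool


def _refractory_filter(
    times: Sequence[float], candidate: Sequence[bool], durations: Sequence[float]
) -> list[bool]:
    """Sequentially suppress candidate infections inside refractory windows.

    ``durations`` supplies one pre-drawn exponential length per candidate;
    a draw is consumed only when its candidate becomes an actual infection.
    """
    infected = []
    blocked_until = -math.inf
    d_iter = iter(durations)
    for t, cand in zip(times, candidate):
        if cand:
            dur = next(d_iter)
            if t > blocked_until:
                infected.append(True)
                blocked_until = t + dur
            else:
                infected.append(False)
        else:
            infected.append(False)
    return infected


def simulate_infections(
    status_fn: Callable,
    exposure_times: Sequence[float],
    model: InfectionModel,
    rng: "np.random.Generator | int | None" = None,
) -> list[ExposureOutcome]:
    """Bernoulli infection outcomes at each exposure, given the status curve.

    Exposures are environmental events and are always recorded; a
    refractory window only blocks the infection outcome.
    """
    rng = np.random.default_rng(rng)
    times = np.asarray(exposure_times, dtype=float)
    if times.size == 0:
        return []
    if np.any(np.diff(times) < 0):
        raise ValueError("exposure times must be sorted")
    p = infection_probability(status_fn(times), model)
    candidate = rng.random(times.size) < p
    if model.refractory_mean > 0:
        durations = rng.exponential(model.refractory_mean_years, int(candidate.sum()))
        infected = _refractory_filter(times.tolist(), candidate.tolist(), durations.tolist())
    else:
        infected = candidate.tolist()
    return [ExposureOutcome(float(t), True, bool(i)) for t, i in zip(times, infected)]
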