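"""Monte-Carlo power estimation over trial design grids.

Power is estimated as the proportion of ``N`` independently simulated
trials whose bootstrap test rejects the null of no supplementation
benefit; the Monte-Carlo standard error is ``sqrt(p*(1-p)/N)`` and
precision improves as ``O(N^{-1/2})``.  Every trial realisation consumes
its own deterministically derived random sub-stream, so a fixed master
seed gives identical results regardless of how many workers run the
simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .inference import bootstrap_test_means, bootstrap_test_proportions
from .status import FixedDoseSpec
from .trial import TrialDesign, _simulate_counts

__all__ = ["PowerEstimate", "PowerGrid", "estimate_power", "power_curve", "required_sample_size"]


def _design_cell(design: TrialDesign) -> dict:
    """Identifying coordinates of a design in a power grid."""
    spec = design.scheme_spec
    dose = spec.dose_equiv if isinstance(spec, FixedDoseSpec) else spec.mu_rho
    return {
        "n": design.n_placebo,
        "mu": design.population.mu_baseline,
        "dose": dose,
        "u": design.infection.risk.u,
        "scheme": design.scheme,
        "start_date": str(design.start_date),
        "duration": design.duration,
    }


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection proportion for one design cell with its Monte-Carlo error."""

    power: float
    n_sims: int
    n_rejections: int
    alpha: float
    test: str
    cell: dict = field(default_factory=dict)
    tests: Optional[tuple] = field(default=None, repr=False, compare=False)

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.power * (1.0 - self.power) / self.n_sims)


def _run_batch(design: TrialDesign, test: str, alpha: float, n_boot: int, states, collect=False):
    """Simulate and test a batch of trial realisations.

    Returns (number of rejections, per-trial TestResults or None).
    """
    rejections = 0
    details = [] if collect else None
    for state in states:
        rng = np.random.default_rng(state)
        counts_pl, counts_su = _simulate_counts(design, rng)
        if test == "means":
            result = bootstrap_test_means(counts_pl, counts_su, alpha=alpha, n_boot=n_boot, rng=rng)
        else:
            result = bootstrap_test_proportions(
                counts_pl, counts_su, alpha=alpha, n_boot=n_boot, rng=rng
            )
        rejections += int(result.reject)
        if collect:
            details.append(result)
    return rejections, details


def estimate_power(
    design: TrialDesign,
    test: str = "means",
    n_sims: int = 500,
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: "int | np.random.SeedSequence | None" = None,
    n_jobs: int = 1,
    collect_tests: bool = False,
) -> PowerEstimate:
    """Monte-Carlo power of the chosen comparison under a trial design.

    Simulates ``n_sims`` independent trials (each with a fresh cohort) and
    applies the one-sided bootstrap test to each; the design embodies the
    alternative whenever it carries a real supplementation effect, and a
    zero-dose design estimates the size of the test instead.  With
    ``collect_tests`` the per-trial :class:`TestResult` records are kept.
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    if test not in ("means", "proportions"):
        raise ValueError(f"test must be 'means' or 'proportions', got {test!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    if n_jobs == 1:
        rejections, details = _run_batch(design, test, alpha, n_boot, children, collect_tests)
    else:
        batches = np.array_split(np.arange(n_sims), max(1, min(n_jobs * 4, n_sims)))
        parts = Parallel(n_jobs=n_jobs)(
            delayed(_run_batch)(
                design, test, alpha, n_boot, [children[i] for i in batch], collect_tests
            )
            for batch in batches
            if batch.size
        )
        rejections = int(sum(p[0] for p in parts))
        details = [r for p in parts for r in (p[1] or [])] if collect_tests else None
    power = rejections / n_sims
    return PowerEstimate(
        power=power, n_sims=n_sims, n_rejections=rejections, alpha=alpha, test=test,
        cell=_design_cell(design), tests=tuple(details) if details is not None else None,
    )


@dataclass
class PowerGrid:
    """Tidy collection of power estimates over design cells and replicates.

    ``records`` has one row per (cell, replicate): the cell coordinates,
    the replicate index and the estimate.  Replicate-averaged summaries and
    a pivoted layout (n by baseline) are derived views.
    """

    records: pd.DataFrame
    test_records: Optional[pd.DataFrame] = None

    _CELL_KEYS = ["n", "mu", "dose", "u", "scheme", "start_date", "duration"]

    @classmethod
    def from_estimates(cls, estimates: Iterable[tuple[int, PowerEstimate]]) -> "PowerGrid":
        rows = []
        test_rows = []
        for replicate, est in estimates:
            row = dict(est.cell)
            row.update(
                replicate=replicate, power=est.power, n_sims=est.n_sims,
                n_rejections=est.n_rejections, mc_se=est.mc_se, alpha=est.alpha,
                test=est.test,
            )
            rows.append(row)
            if est.tests is not None:
                for sim, tr in enumerate(est.tests):
                    trow = dict(est.cell)
                    trow.update(replicate=replicate, sim=sim, **tr.to_record())
                    test_rows.append(trow)
        if not rows:
            raise ValueError("no power estimates supplied")
        return cls(
            records=pd.DataFrame(rows),
            test_records=pd.DataFrame(test_rows) if test_rows else None,
        )

    def averaged(self) -> pd.DataFrame:
        """Replicate-averaged power per design cell."""
        grouped = (
            self.records.groupby(self._CELL_KEYS, as_index=False)
            .agg(power=("power", "mean"), replicates=("power", "size"), n_sims=("n_sims", "sum"))
        )
        grouped["mc_se"] = np.sqrt(grouped["power"] * (1 - grouped["power"]) / grouped["n_sims"])
        return grouped

    def pivot(self, value: str = "power") -> pd.DataFrame:
        """Replicate-averaged power, sample size by baseline (one block per
        dose/u combination when several are present)."""
        avg = self.averaged()
        return avg.pivot_table(index="n", columns=["dose", "u", "mu"], values=value)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PowerGrid":
        return cls(records=pd.read_csv(path))


def power_curve(
    designs: Sequence[TrialDesign],
    test: str = "means",
    n_sims: int = 500,
    alpha: float = 0.05,
    n_boot: int = 500,
    replicates: int = 1,
    seed: "int | np.random.SeedSequence | None" = None,
    n_jobs: int = 1,
    collect_tests: bool = False,
) -> PowerGrid:
    """Power over a sequence of designs (e.g. a grid of sample sizes).

    Each design cell is estimated ``replicates`` times independently to
    expose the Monte-Carlo error; sub-streams are derived from the master
    seed so the grid is reproducible and worker-count invariant.
    """
    designs = list(designs)
    if not designs:
        raise ValueError("designs must be non-empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(len(designs) * replicates)
    estimates = []
    k = 0
    for design in designs:
        for rep in range(replicates):
            est = estimate_power(
                design, test=test, n_sims=n_sims, alpha=alpha, n_boot=n_boot,
                seed=cell_seeds[k], n_jobs=n_jobs, collect_tests=collect_tests,
            )
            estimates.append((rep, est))
            k += 1
    return PowerGrid.from_estimates(estimates)


def required_sample_size(grid: PowerGrid, target: float = 0.80) -> Optional[int]:
    """Smallest per-arm sample size on the grid reaching the target power.

    Uses replicate-averaged power per ``n``; returns ``None`` when the
    target is not reached anywhere on the grid.  The grid must hold a
    single design cell per ``n`` (one baseline/dose/u combination).
    """
    avg = grid.averaged()
    if avg.empty:
        raise ValueError("empty power grid")
    non_n = [k for k in ["mu", "dose", "u", "scheme"] if avg[k].nunique() > 1]
    if non_n:
        raise ValueError(
            f"grid varies along {non_n}; filter to one design cell per n first"
        )
    avg = avg.sort_values("n")
    hit = avg[avg["power"] >= target]
    if hit.empty:
        return None
    return int(hit["n"].iloc[0])
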