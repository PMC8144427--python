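"""Non-parametric bootstrap two-sample tests for trial comparisons.

Two one-sided comparisons of the placebo arm against the supplement arm
are supported, matching the two natural trial endpoints:

* difference in the per-participant expected number of infections
  (``H0: mu_pl <= mu_supp`` vs ``HA: mu_pl > mu_supp``), and
* difference in the propensity to contract at least one infection
  (``H0: theta_pl <= theta_supp`` vs ``HA: theta_pl > theta_supp``).

Both use the shift-to-null percentile bootstrap: each arm is resampled
with replacement, and the observed difference ``D`` is compared with the
null distribution of the centred bootstrap differences ``D*_b - D``.  The
p-value uses the finite-resampling convention ``(1 + k) / (B + 1)`` so it
is never exactly zero.  A studentized variant is available behind a flag.

For integer count data the resample is drawn as a multinomial over the
empirical value distribution, which is exactly equivalent in law to index
resampling and much faster for large arms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

__all__ = [
    "TestResult",
    "bootstrap_test_means",
    "bootstrap_test_proportions",
    "implied_effect_size",
]

_FAST_PATH_MAX_LEVELS = 128


@dataclass(frozen=True)
class TestResult:
    """Outcome of one bootstrap hypothesis test (one-sided, placebo - supplement)."""

    statistic: float
    p_value: float
    reject: bool
    n_boot: int
    alpha: float
    effect_size: Optional[float]
    comparison: str
    degenerate: bool = False

    def to_record(self) -> dict:
        """Flat dict for CSV/JSON serialization."""
        return asdict(self)


def implied_effect_size(counts_pl, counts_supp) -> float:
    """Standardized mean difference (Cohen's d) between the arms.

    ``(mean_pl - mean_supp) / s_pooled`` with the usual pooled SD.  Returns
    NaN (undefined) when the pooled SD is zero.
    """
    x = np.asarray(counts_pl, dtype=float)
    y = np.asarray(counts_supp, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("effect size needs at least two observations per arm")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def _bootstrap_moments(x: np.ndarray, n_boot: int, rng: np.random.Generator, want_var: bool):
    """Bootstrap resample means (and variances) for one sample.

    Integer data with few distinct values goes through the multinomial fast
    path; anything else through plain index resampling.
    """
    n = x.size
    if np.issubdtype(x.dtype, np.integer):
        vals, cnts = np.unique(x, return_counts=True)
        if vals.size <= _FAST_PATH_MAX_LEVELS:
            w = rng.multinomial(n, cnts / cnts.sum(), size=n_boot)
            means = (w @ vals) / n
            if not want_var:
                return means, None
            m2 = (w @ (vals.astype(float) ** 2)) / n
            var = np.maximum(m2 - means**2, 0.0) * n / (n - 1)
            return means, var
    idx = rng.integers(0, n, size=(n_boot, n))
    resamples = x[idx]
    means = resamples.mean(axis=1)
    var = resamples.var(axis=1, ddof=1) if want_var else None
    return means, var


def _bootstrap_one_sided(
    x, y, alpha, n_boot, rng, comparison, studentized=False
) -> TestResult:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have length >= 2")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    rng = np.random.default_rng(rng)

    D = float(x.mean() - y.mean())
    vx, vy = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    effect = implied_effect_size(x, y)

    if vx == 0.0 and vy == 0.0 and D == 0.0:
        # no variation and no observed difference: no evidence against H0
        return TestResult(
            statistic=D, p_value=1.0, reject=False, n_boot=n_boot, alpha=alpha,
            effect_size=effect, comparison=comparison, degenerate=True,
        )

    mx, sx = _bootstrap_moments(x, n_boot, rng, want_var=studentized)
    my, sy = _bootstrap_moments(y, n_boot, rng, want_var=studentized)
    null_diffs = (mx - my) - D  # centred at the null of no difference

    if studentized:
        se = np.sqrt(vx / x.size + vy / y.size)
        if se == 0:
            raise ValueError("studentized test undefined: zero variance in both arms")
        se_b = np.sqrt(sx / x.size + sy / y.size)
        se_b = np.where(se_b == 0, np.inf, se_b)
        k = int(np.sum(null_diffs / se_b >= D / se))
    else:
        k = int(np.sum(null_diffs >= D))
    p_value = (1 + k) / (n_boot + 1)
    return TestResult(
        statistic=D, p_value=p_value, reject=p_value <= alpha, n_boot=n_boot,
        alpha=alpha, effect_size=effect, comparison=comparison,
    )


def bootstrap_test_means(
    counts_pl,
    counts_supp,
    alpha: float = 0.05,
    n_boot: int = 500,
    rng: "np.random.Generator | int | None" = None,
    studentized: bool = False,
) -> TestResult:
    """One-sided bootstrap test of ``H0: mu_pl <= mu_supp`` on infection counts.

    ``statistic`` is the observed mean difference (placebo - supplement);
    rejection at ``p_value <= alpha``.
    """
    return _bootstrap_one_sided(
        counts_pl, counts_supp, alpha, n_boot, rng, "means", studentized=studentized
    )


def bootstrap_test_proportions(
    any_pl,
    any_supp,
    alpha: float = 0.05,
    n_boot: int = 500,
    rng: "np.random.Generator | int | None" = None,
    studentized: bool = False,
) -> TestResult:
    """One-sided bootstrap test of ``H0: theta_pl <= theta_supp``.

    Inputs are per-participant indicators of at least one infection (raw
    counts are accepted and thresholded at >= 1); the statistic is the
    difference in proportions.
    """
    x = (np.asarray(any_pl) > 0).astype(np.int64)
    y = (np.asarray(any_supp) > 0).astype(np.int64)
    return _bootstrap_one_sided(x, y, alpha, n_boot, rng, "proportions", studentized=studentized)
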