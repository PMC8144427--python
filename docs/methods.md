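# Methods

This note documents the generative model behind `vitdpower`, the
conventions and defaults it adopts where several reasonable choices exist,
and what its simulations can and cannot say about real trials.

## Status trajectories

An individual's circulating 25OHD (nmol/L) is modelled as a floored,
phase-shifted cosine of time in years,
`V_pl(t) = max{mu_i + H_i + A_i cos(2 pi t - nu), floor}`. The model
captures the dominant, UVB-driven seasonal cycle and between-person
heterogeneity; it deliberately ignores short-term excursions (sun holidays,
illness) and long-term trends. Conventions:

* **Time origin.** `t = 0` is March 1 and `nu = pi` by default, putting the
  seasonal trough at the start of March and the peak at the start of
  September (northern-hemisphere schedule with a ~2-month lag behind peak
  UVB). Calendar dates map to `t` by day-of-year offset from March 1 on a
  fixed 365-day year; weeks convert at 365/7 per year everywhere.
* **Heterogeneity.** `H_i ~ N(0, sigma_H^2)` perturbs the annual mean;
  `A_i ~ Gamma` is moment-matched (`shape = (mean/sd)^2`,
  `rate = mean/sd^2`) so users think in means and SDs, not shape/rate.
* **Floor.** The 10 nmol/L detectability floor applies to the placebo curve
  only; supplementation is added to (fixed dose) or maxed with (RCCT) the
  floored curve. No upper physiological clip is applied.
* **Covariates.** `mu_i = x_i' beta` is supported for planning with known
  group effects; the scalar population mean is the default.

## Supplementation schemes

**Fixed dose.** `V_fix = V_pl + F_i` with
`F_i(t) = delta_i [omega_i + (1 - omega_i)(1 + sin(2 pi t - pi/2 - nu))/2]`.
`omega_i ~ Beta` (moment-matched; infeasible moment pairs with
`sd^2 >= mean(1-mean)` are rejected with the constraint named) is the
always-utilised share of the dose benefit; the remainder follows a
complementary seasonal wave so uptake peaks when status is lowest.
`delta_i` is the individual 25OHD-equivalent benefit of the administered
dose, capped at the dose equivalent. Its sampler is pluggable; the default
draws `delta_i = dose_equiv * Beta(gamma, 1)`, a single-parameter family on
(0, dose] whose mass concentrates at the cap as `gamma` grows. The default
`gamma = 50` encodes "little variability in derived uptake" (mean uptake
~98% of the cap, SD ~2%).

**Concentration controlled.** `V_dyn = max{rho_i, V_pl}` with
`rho_i ~ Gamma` moment-matched to a target mean and SD. This idealises a
monitored, responsive dosing scheme; adherence and measurement error are
not modelled.

## Exposure and infection

Exposures follow a non-homogeneous Poisson process with piecewise-constant
calendar intensity given in exposures/week (internally scaled by 365/7 to
per-year). Segments must tile the year exactly; the winter-respiratory
default is 1/week September–April and 0.1/week May–August (expected
242/7 + 0.1 x 123/7 ≈ 36.3 exposures/year).

The scalar sampler draws by thinning against the maximum segment rate —
exact for step intensities. The vectorised trial engine instead draws the
Poisson total count over the window and places times by inverting the
cumulative intensity; for a step intensity the two constructions have
identical law, and both are tested against Poisson segment-count oracles.

Infection upon exposure at status `x` occurs with probability `p0 g(x)`,
`g(x) = l + (u-l)/(1 + exp(a + b x))` non-increasing in `x`. The
calibration convention fixes the fraction of the risk range attained at the
reference points: `g(x_lo) = l + c (u-l)` and `g(x_hi) = l + (1-c)(u-l)`
with attainment `c = 0.95` by default at `x_lo = 10`, `x_hi = 70` nmol/L.
The attainment fraction is a genuine free convention — any `c` in (0.5, 1)
yields a curve "steepest between the reference points" — and it materially
affects effect sizes, so it is exposed as a config knob. Constructors
reject `p0 u > 1`.

After each infection an exponential non-susceptible window (default mean
2 weeks) blocks further infections; exposures during the window are still
recorded as exposures. Only infections are suppressed — an alternative
reading would discard the exposures themselves, which is observationally
equivalent for count endpoints.

## Trial engine

A trial design fixes both arm sizes (`n_supp = floor(r * n_pl)`), the
calendar window, and all model components. Every simulated trial draws a
fresh i.i.d. cohort, simulates exposures only inside the window, and
returns per-participant infection counts. The chain is fully vectorised
across participants; the refractory suppression is the only sequential
step and operates on candidate infections only. One n=1000-per-arm 1-year
trial simulates in ~25 ms.

`expected_infections_numeric` integrates `lambda(t) p0 g(V(t))` by
adaptive quadrature as an independent oracle for the generative chain; it
is valid only without a refractory period (infection events are then a
thinned Poisson process) and refuses otherwise.

The default start date for 1-year designs is September 1 (season onset);
any full-year window gives the same distribution because every component
is periodic with period one year, so the choice only matters for
sub-year trials.

## Hypothesis tests

Both endpoints — per-participant infection counts (mean comparison) and
the indicator of at least one infection (propensity comparison) — use a
one-sided, shift-to-null percentile bootstrap: each arm is resampled with
replacement `B` times (default 500) and the observed difference `D` is
referred to the centred bootstrap differences `D*_b - D`. The p-value uses
the finite-resampling convention `(1 + #{D*_b - D >= D}) / (B + 1)`, which
is never exactly zero (so a level of 0 never rejects) and is
conservatively biased by at most `1/(B+1)`. Ties at the boundary reject
(`p <= alpha`). A studentized variant is available behind a flag for
sensitivity analysis. For integer counts the resample is drawn as a
multinomial over the empirical value distribution — exactly the same law
as index resampling, and far faster at trial-arm sizes. Degenerate inputs
(no variation, no observed difference) return `p = 1` and are flagged.
Cohen's d with the pooled SD is returned as the implied effect size
by-product (NaN when the pooled SD is zero).

Simulated type-I error of both tests under exchangeable nulls is ~0.05
(checked in the suite at 0.05 +/- 0.02), and a zero-dose design estimates
power ~ alpha, confirming the rejection rate measures the design rather
than test miscalibration.

## Power estimation

Power is the rejection proportion over `N` independent trial realisations
(default 500, replicated 5 times to expose Monte-Carlo error; MC standard
error `sqrt(p(1-p)/N)`). Each realisation consumes a dedicated
`SeedSequence`-derived sub-stream, so results are identical for any worker
count and reproducible from one master seed. Replicate-averaged powers
feed the required-sample-size lookup, which returns the smallest grid `n`
at or above the target and `None` when the target is not reached;
monotonicity in `n` is not enforced (sampling noise is allowed to show).

### Choice of comparison for the bundled 1-year study reproduction

The package supports both comparisons, and `estimate_power` defaults to
the means test. The bundled `table1`, `winter_trial` and `summer_trial`
scenarios and the acceptance script use the **proportions** comparison:
reproducing the published power table for the 1-year fixed-dose experiment
requires it. Effect sizes back-calculated from the published powers agree
closely, at every population baseline, with the standardized difference of
the >=1-infection indicators produced by this generative model, and are
~1.4-1.8x smaller than the count-mean effect sizes; with the proportions
test the simulated powers land within a few percentage points of the
published column at baseline 35 nmol/L across the whole sample-size grid.
A residual upward offset (up to ~8-10 points mid-power) remains at the
15 and 60 nmol/L baselines, consistent with a remaining convention
difference (most plausibly the logistic attainment fraction or the exact
dose-uptake distribution) that we deliberately do not tune.

## Problem sizes used in the checks

The test suite runs reduced but honest simulation sizes: 10^5 draws for
moment recovery, 10^4 replicates for the exposure-process goodness-of-fit,
~1000 replicate tests for type-I calibration, 200-500 trial realisations
per power cell (vs 500 x 5 in the full study settings), with tolerances
set from the corresponding Monte-Carlo standard errors (typically 4 SE).
The acceptance script uses 500 x 5 trials at single cells and a two-stage
budget over sample-size grids: a 300-trial sweep, then 500 x 3 trials for
cells whose first-pass power is within 0.12 of the 80% target, so
precision concentrates at the decision boundary.

## What the simulations do not show

The generator emulates the planning model itself, so passing tests
demonstrate internal correctness (distributions, laws, calibration,
reproducibility) and faithful reproduction of the published experiment's
settings — not that the model describes any real cohort. Real trials add
dropout, non-compliance, staggered enrolment, correlated within-person
disease episodes, covariate-linked exposure behaviour and measurement
error in 25OHD, none of which are modelled. Status trajectories are smooth
annual curves without trend; disease outcomes with long latency (e.g.
cancer) are outside the model's scope.
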