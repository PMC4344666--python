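# Methods

## Model and procedure

The pipeline treats daily mortality as a smooth function of same-day
apparent temperature, estimated independently per region in four stages.

**Exposure.** Apparent temperature combines air and dew-point temperature,
`Tapp = −2.653 + 0.994·Tair + 0.0153·Tdewpt²` (all °C). The dew-point term
is applied exactly as written — squaring makes sub-zero dew points
contribute like their positive mirror; no clamping is applied. Mortality is
expressed as a rate, deaths per million population per day, so regions of
very different size are comparable. Zero lag is assumed throughout: a day's
deaths are paired with that day's temperature.

**Empirical curve.** The observed `Tapp` range is partitioned into
half-open, equally spaced intervals (default 0.1 °C), left-anchored at the
observed minimum so every day is assigned exactly once. Within each
interval the member days' temperatures and rates are averaged; the response
is `log(mean rate)` — average first, then log, matching the definition of
the interval statistic being modelled (this is *not* the mean of daily log
rates; the distinction matters at low counts). Intervals with fewer than
`min_days_per_interval` (default 1) days, or a zero mean rate, are flagged
missing. A centred 31-term moving-average filter (≈ 3 °C at the default
width) smooths the log-rate series; windows shrink at the curve's ends
rather than dropping points, so the minimum search covers the full observed
range, and missing intervals are simply skipped within a window. The
smoothed minimum is the comfort temperature; ties break toward the colder
interval, and a minimum at the first/last populated interval (a monotone
curve — no interior minimum in the observed range) is flagged and warned
about rather than rejected. Smoothing operates on the log scale by default
(the scale of the model); a rate-scale option exists
(`smoothing_scale="rate"`).

**Tail models.** Populated intervals at or above the comfort temperature
form the warm tail (equality is warm), the rest the cold tail; each tail
needs at least `min_tail_points = 8` intervals (twice the parameter count)
or the fit is refused. The raw (not smoothed) log mean rates feed the
regression by default — the smoother exists to locate the minimum, not to
pre-filter the likelihood (`fit_input="smoothed"` is available). Each tail
is a cubic in temperature centred at the comfort temperature, fitted under
a Normal likelihood with a conjugate Normal–Inverse-Gamma prior:
coefficient mean 0 and SD 100 (relative to σ, standard conjugate coupling),
σ² ~ InvGamma(0.01, 0.01). These are vague on centred predictors; with a
flat prior (`PriorSpec.flat()`) the posterior mean is exactly the
least-squares solution, which the tests exploit as an oracle. Sampling is
exact — σ² from its marginal Inverse-Gamma, coefficients from the
conditional Normal — so results are deterministic given a seed and involve
no convergence diagnostics. Intervals are not weighted by occupancy in the
default fit (the model treats interval means homoskedastically); weighted
fitting is available behind a flag. Internally the design matrix is
column-scaled for conditioning; posteriors are mapped back to natural
units, and `PosteriorDraws.recenter()` re-expands the cubic about any other
origin exactly, which is how fitted coefficients are compared against
truths defined about the true comfort temperature.

**Scenario simulation and warnings.** For an episode of daily temperatures,
each day routes to the tail containing it (comfort temperature itself →
warm). Per posterior draw and day, a log rate is drawn from the Normal with
that draw's curve value and σ — the full posterior predictive, not just the
mean curve. Rates are exponentiated and averaged over the episode's days;
the exceedance probability is the fraction of draws whose event-mean rate
strictly exceeds the emergency threshold (ties have probability zero under
the continuous model). The threshold is the 75th percentile (linear
interpolation between order statistics) of *observed* daily rates
conditional on the tail over the observation period — an empirical
operational trigger, deliberately not model-derived. The observed outcome
is defined symmetrically: observed event-mean rate > threshold.

**Verification.** Warnings fire when the forecast probability is ≥ the
decision threshold (a stated 70% trigger fires at exactly 70%). Hit rate,
false-alarm rate and proportion correct come from the cross-region 2×2
table; a rate with an empty denominator is reported as undefined, never as
zero. The ROC curve sweeps the unique forecast probabilities (exact at
1000-draw resolution), augments with (0,0) and (1,1), and integrates
trapezoidally; this equals the tie-corrected Mann–Whitney probability,
which the tests verify to 10⁻¹² against brute-force pair counting.

## Synthetic data: what it emulates, and what it does not

Real multi-country daily mortality series are not redistributable, so the
generator produces panels with the structure the method assumes: a
region-specific comfort temperature; a continuous two-piece cubic log-rate
curve, monotone on each side of its minimum (coefficient triples are
rejection-sampled against a 0.1 °C grid check and the two intercepts are
tied at the comfort temperature); a cosine seasonal temperature cycle
peaking on 1 August with additive Gaussian noise, which crosses the comfort
temperature twice a year; and daily noise either log-normal on the rate
(matching the model assumption exactly — used for parameter-recovery
claims) or Poisson on the counts (count discreteness — used for robustness
checks). Raw air temperatures are back-solved from the generated apparent
temperatures at a constant per-region dew point (6 °C), so preprocessing
reproduces the generated exposure to 10⁻⁹ °C.

Default ranges, chosen once for realism at European scale: baseline
20–35 deaths/million/day (≈ 1% annual mortality); comfort temperature
15–25 °C; warm-tail linear slope 0.010–0.030 per °C with positive quadratic
0.001–0.006 (heat effects steepen away from comfort), cold-tail slope
−0.025 to −0.008; cubic terms small and constrained by monotonicity; daily
log-rate SD 0.05–0.15 (the Poisson coefficient of variation at ~50
deaths/day); annual-mean temperature 2–6 °C below comfort with seasonal
amplitude 9–13 °C and 1.5–3 °C daily weather noise, so both tails receive
several years of data. Populations span 0.5–5 million.

Deliberately absent: spatial correlation between regions, influenza and
air-pollution confounding, demographic trends, lagged effects, and
measurement error in exposure. Passing tests therefore demonstrate that
the pipeline recovers the truth *when the model's assumptions hold* (plus
count discreteness); they do not certify performance on real data, where
tail shapes are not exactly cubic and non-thermal seasonal mortality is
entangled with the cold tail.

Scenario episodes are 15-day blocks: heat waves at comfort + severity
(default 8 °C, the scale of a major European summer event) with small
positive noise, cold spells at comfort − severity − 5 °C seasonal offset
(default severity 10 °C). "Observed" outcomes are one stochastic
realisation from the ground-truth model at the scenario temperatures.

## Numerical choices and degenerate inputs

- Interval edges: half-open `[lo, hi)`; float roundoff at the maximum is
  clipped into the last interval.
- Filter window must be odd; even windows are rejected before computation.
- Comfort-temperature ties break toward the lower temperature
  (deterministic argmin-first).
- Rank-deficient tail designs (fewer than four distinct temperatures) fail
  explicitly rather than returning a pseudo-inverse fit.
- An exact-fit dataset under a fully flat prior would give a zero posterior
  scale; the scale is floored at the smallest positive float so sampling
  still works in the degenerate limit.
- All randomness descends from one integer seed via `SeedSequence`
  substreams keyed (seed, stage, region-index), so region-parallel
  execution and re-runs are byte-identical; derived seeds stay below 2³¹.

## Reported problem sizes

The test suite and the acceptance script run the study at 54 regions ×
6 years (2191 days) with 1000 posterior draws per tail — the scale the
method targets — which completes in seconds because tail fitting is exact
conjugate sampling. The Monte-Carlo oracle checks use 10⁵ draws; the
no-skill resampling check uses 1000 resamples of 54 regions.

## Known limitations

- The likelihood is on interval means, ignoring unequal interval occupancy;
  sparse extreme-temperature intervals contribute as much as dense mild
  ones. Weighted fitting is available but not default.
- `log(mean rate)` of noisy daily rates carries a small upward Jensen bias
  (≈ σ²/2) that loads on the intercept; with daily σ ≤ 0.15 this is well
  inside posterior uncertainty but visible in coverage at very large n.
- Cubic tails extrapolate badly; predictions outside the fitted temperature
  range are flagged, not refused.
- The comfort temperature is estimated, not known; its error (≲ 1.6 °C at
  default resolution) propagates into tail membership near the minimum,
  where the curve is flat and the effect on rates is second-order.
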