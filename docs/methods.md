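# Methods

## The habitat metric

Daily sea-ice area for a subpopulation region is
A(d) = Σᵢ cᵢ(d)·aᵢ over the region's grid cells with concentration
cᵢ(d) > 0.15 (strict inequality; the cutoff is applied per cell before area
weighting). Concentrations are fractions in [0, 1]; files on a 0–100 scale
are rescaled on read with a logged note.

The *ice* metric for a calendar year is the number of days with A(d)
strictly above the region's midpoint. The midpoint is
½·(mean of annual minima + mean of annual maxima) pooled over a baseline
period (default: the full observed record). Pooling gives one fixed
threshold per region, which makes yearly counts comparable across years —
a requirement of the trend analysis. A per-year midpoint would absorb part
of the signal the trend is meant to measure. "Above" is strict; ties have
measure ~0 on real data and a degenerate constant series counts zero days.

Missing days are filled by linear interpolation (nearest value at the
edges); runs of more than `max_gap` (default 5) consecutive missing days
are an error rather than silently interpolated. A year is scored only when
at least 300 days have data after filling. Real calendars use the actual
year length; synthetic data use 365-day years so oracle day counts have no
leap-year nuisance term.

Trends are ordinary least squares of the yearly count on calendar year,
centred on the mean year internally for numerical stability and reported on
the calendar scale with slope/intercept standard errors, residual sd and
the slope–intercept covariance. Projections clamp the predicted count to
[0, 366] since the metric is a day count; the prediction is defined for any
year (the centroid identity ŷ(x̄) = ȳ is used as a test oracle), though
the intended use is extrapolation beyond the record.

## Generation length

GL is the mean age of adult females with cubs of the year. Females seen
with yearlings in year t+1 are back-dated to a pseudo-observation at
(t, age−1). The adult threshold is 5 years (configurable) and applies to
the event age after back-dating; younger records are dropped with a
warning. The point estimate is the mean of per-subpopulation mean ages
(the cross-subpopulation mean weights each studied subpopulation equally
rather than by sampling effort); a pooled mode is available. The bootstrap
resamples events with replacement within subpopulation, recomputes the
subpopulation means and their cross mean, with 5,000 replicates by default
and empirical 5th/95th percentiles (linear interpolation). The resampling
unit is the reproductive event; resampling females or whole subpopulations
would widen the intervals and can be emulated by relabelling.

## Ice–abundance relations

Observed changes are annualized on the log scale, r = ln(N₂/N₁)/Δt,
because log rates are symmetric and compose multiplicatively over time
(projection then compounds exp(β·Δice) annually). The covariate d_ice is
the OLS slope of the yearly ice counts over the pair's interval rather
than the endpoint difference divided by the span, which is robust to
single-year ice noise. Approach 2 pairs each subpopulation's earliest and
latest estimates and keeps pairs spanning ≥ 10 years; approach 3 uses all
consecutive estimate pairs of any span, which subsumes the two-estimate
subpopulations and adds the longer series. Regressions are through the
origin — zero ice change predicts stable N, and the assessed relation is a
slope, not a level; an intercept mode exists for sensitivity analysis.
Fits are unweighted by default; inverse-variance weighting by the
delta-method variance of r is a straightforward extension not enabled by
default because estimate standard errors are missing or incomparable for
several historical estimates.

Approach 1 bypasses abundance data entirely: the proportional change in N
equals the proportional change in projected ice-covered days, floored at
−1 (the clamp of projected ice at 0 days can drive the ratio to −1; the
floor and the clamp interact correctly by construction).

## Projection engine

A scenario is (approach, GL); the horizon is round-half-up(3·GL) years
(3·11.5 → 35, 3·13.6 → 41). Each of the 62,500 replicates draws

* one β per scope and replicate — a scope-level coefficient is a single
  uncertain quantity, so its draw is shared by every subpopulation in the
  scope (global for approach 2, ecoregion for approach 3);
* one (slope, level) pair per subpopulation trend, drawn jointly in the
  centred parametrization where slope and mean-year level are independent,
  which induces the calendar-scale slope–intercept covariance.

Draws are normal at the point estimate with the estimated standard error —
the standard regression-coefficient simulation convention; the only
truncation is the −1 floor on proportional changes. Subpopulation changes
are aggregated to per cent change in MGPS with the most recent abundance
estimates as fixed weights (propagating weight uncertainty is a
straightforward extension; it second-order affects only the aggregation).
The replicate distribution is summarized by its median ("most likely
change"), percentile 95% interval, and the exceedance fractions of the
0/30/50/80% reduction thresholds. The Red List rule assigns the highest
category whose reduction probability meets the risk tolerance (default
0.5); probabilities must be non-increasing in the threshold, which every
summary satisfies by construction. RNG streams are split per scenario and
per stage from the master seed and logged.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
sea-ice physics or bear demography:

* **Concentration fields.** The daily area target is a seasonal sinusoid
  (winter maximum at day 75, summer minimum half a year later) plus a
  linear trend and Gaussian noise, clipped to [0, total grid area]. The
  target is distributed over cells by a fixed smooth spatial gradient and a
  per-day scale found by bisection, so some cells always sit below the 15%
  cutoff while others saturate — the cutoff rule is exercised, not just
  totals. For a sinusoid of amplitude A about a fixed midpoint, a mean
  shift of δ km² moves the day count by δ·365/(π·A) days; the stand-in
  study system uses this identity to calibrate area trends to target
  ice-day slopes. Because a pure sinusoid spends exactly half the year
  above its midpoint, synthetic baselines sit near 182 ice-covered days —
  real regions with asymmetric seasonal cycles can sit much higher or
  lower, which is why the projection stand-ins specify baselines directly.
* **Captures.** Cub-of-year mother ages are normal (truncated at the adult
  threshold) with known mean; each litter is independently re-observed as
  yearlings the following year with probability p, at age +1, so the
  back-dating rule can be verified by exhaustive pairing.
* **Abundance.** Latent dynamics are log-linear in the ice change,
  ln N(t+1) = ln N(t) + β·Δice(t), matching the estimator family, with
  mean-one multiplicative lognormal observation error of chosen CV.

Passing tests on these inputs show the estimators recover the quantities
the generators encode; they do not validate the ecological assumptions
(N/K stability, linearity, no density dependence or harvest interaction)
on real data.

## The packaged study reconstruction

`icepipe.synthetic_study` fixes one set of study conditions used by the
tests and the acceptance script. Published summary values are taken as
inputs: the ecoregion slopes β (seasonal 0.013 ± 0.002, divergent
0.032 ± 0.009, convergent −0.008 ± 0.009, archipelago −0.029 ± 0.030), a
global slope of 0.0005 ± 0.005 (reported only as "< 0.001"), GL values
11.5 and 13.6 years, and the six-scenario summary table. Quantities only
available in the undeposited supplementary material are synthetic
stand-ins chosen once: 19 trend slopes whose median is −1.26 d/yr and
whose 2.5/97.5 quantiles approximate the published interval (−3.37,
−0.71), with steeper slopes in the divergent ecoregion and shallower in
the archipelago; 2015 baselines of 150/200/280/300 ice-covered days for
the seasonal/divergent/convergent/archipelago ecoregions; round-number
latest-N weights summing to ≈ 25,200 of the ≈ 26,000 global total; capture
conditions sized to ≈ 3,374 reproductive events across 11 subpopulations;
and abundance availability for seven subpopulations, four with longer
series.

Under these stand-ins, approaches 1 and 2 reproduce the published median
MGPS changes closely (≈ −29% and ≈ −3% at GL 11.5 versus −30% and −4%),
but approach 3 yields ≈ −20% rather than −43%: with the published
negative-β convergent and archipelago coefficients, declining ice implies
*growth* in those ecoregions, and at any slope magnitudes inside the
published trend interval their weighted contribution offsets roughly 20
points of the seasonal/divergent declines. Reproducing −43% requires the
actual per-subpopulation trends and weights of the original supplementary
tables. The corresponding acceptance tests assert the published values at
Monte Carlo tolerance and are expected to fail on approach 3 under the
reconstruction; they are kept as-is rather than loosened.

## Numerical choices and problem sizes

* Bisection for the per-day concentration scale runs 80 halvings,
  reaching float precision; the map is continuous and monotone.
* OLS goes through statsmodels; tests compare against hand-rolled normal
  equations to ≥ 10 significant digits.
* Cross-scenario medians use the standard even-count convention (mean of
  the two central values).
* Default problem sizes keep the full suite and the acceptance script to
  seconds on one CPU: 5×5 or 6×6 grids with 25–36-year records for
  synthetic satellite chains, 300–5,000 bootstrap replicates, and 62,500
  projection replicates (vectorized, so cheap).

## Known limitations

* Linear, density-independent responses only; no harvest–habitat
  interaction, no quasi-extinction floors, no age structure, no spatial
  dynamics.
* The ice generator's sinusoidal seasonal cycle fixes synthetic baselines
  near half the year, unlike real asymmetric cycles.
* The midpoint definition is pooled over the baseline; a per-year midpoint
  variant is not implemented.
* Trend fitting ignores temporal autocorrelation in yearly ice counts,
  which can understate slope standard errors on real data.
* Criterion A3 only; other Red List criteria (range, small population) are
  out of scope.
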