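# icepipe

Stochastic projections of global polar bear (*Ursus maritimus*) population
change from sea-ice habitat trends, scored against IUCN Red List
criterion A3 reduction thresholds.

Polar bears depend on sea ice for essentially all of their life history, so
the species' extinction risk is commonly assessed by projecting how the
global population will respond to continued ice loss over the next three
generations. `icepipe` implements that assessment as a tested, reusable
pipeline for quantitative ecologists:

1. **Habitat metric.** Within each of the 19 subpopulation areas, daily
   sea-ice area is computed from gridded concentration data by summing
   concentration × cell area over all cells with concentration > 15%. The
   *ice* metric for a year is the number of days the daily area exceeds the
   midpoint between the mean summer-minimum and mean winter-maximum areas
   (one fixed threshold per region). Yearly counts are fit with an OLS
   linear trend, *ice*(t) = a + b·t, and projected forward.
2. **Generation length (GL).** GL is the mean age of adult females with
   new cubs, estimated from live-capture records; females with 1-year-old
   cubs in year t+1 are back-dated as pseudo-observations in year t at age
   minus one. Uncertainty comes from a stratified bootstrap over events
   within subpopulation. GL sets the assessment horizon (3·GL years).
3. **Ice–abundance relations.** Three approaches link *ice* to subpopulation
   abundance N: (1) one-to-one proportionality between *ice* and carrying
   capacity, so ΔN/N equals the projected Δ*ice*/*ice*; (2) a global
   regression through the origin of annualized log change in N,
   r = ln(N₂/N₁)/Δt, on the annual change in *ice* (r = β·Δ*ice*); and
   (3) the same regression fit separately per ecoregion (convergent,
   divergent, archipelago, seasonal).
4. **Projection engine.** 62,500 Monte Carlo replicates per scenario draw
   coefficients from their sampling distributions (normal at estimate ± se;
   trend slope and level jointly), compound β·Δ*ice* over the horizon per
   subpopulation, and aggregate to per cent change in mean global
   population size (MGPS) weighted by the most recent N. The replicate
   distribution gives the median change, a 95% interval, and the
   probabilities that the reduction exceeds 0/30/50/80% — the criterion A3
   thresholds for Vulnerable (≥30%), Endangered (≥50%) and Critically
   Endangered (≥80%) at a chosen risk tolerance (default 0.5).

Because the original satellite extractions, capture records and abundance
tables were never deposited, the package includes a first-class synthetic
data module (`icepipe.synthetic_data`) that generates seeded inputs with the
same statistical structure, plus a synthetic reconstruction of the study
system (`icepipe.synthetic_study`) used by the tests and the acceptance
script.

## Worked example

```python
import numpy as np
from icepipe import (IceFieldSpec, RegionDefinition, gen_ice_concentration,
                     annual_ice_series, fit_ice_trend, project_ice,
                     Scenario, run_scenario, RelationFit, red_list_category)
from icepipe.ice_metrics import region_daily_series

# 1. synthetic daily sea-ice concentration for one subpopulation area
spec = IceFieldSpec(region_id="WH", n_years=36, start_year=1979,
                    mean_area=1.5e6, seasonal_amplitude=6e5,
                    trend=-6.5e3, noise_sd=2e4, grid_shape=(5, 5),
                    cell_area=2.5e5)
ds = gen_ice_concentration(spec, seed=1)
cells = tuple(f"r{r}c{c}" for r in range(5) for c in range(5))
region = RegionDefinition("WH", "seasonal", cells, (2.5e5,) * 25)

# 2. ice-covered days per year and the linear trend
annual = annual_ice_series(region_daily_series(ds, region))
trend = fit_ice_trend(annual)
print(f"ice trend: {trend.slope:+.2f} d/yr (s.e. {trend.slope_se:.2f})")
print(f"projected ice-covered days in 2050: {project_ice(trend, 2050)[0]:.0f}")

# 3. a 35-year stochastic projection under a fitted ice-abundance relation
fit = RelationFit(approach=3, scope="seasonal", beta=0.013, beta_se=0.002, n_obs=10)
scen = Scenario(approach=3, gl=11.5, n_sims=62_500, seed=1)
s = run_scenario(scen, {"WH": trend}, {"WH": 1030.0},
                 fits={"seasonal": fit}, ecoregions={"WH": "seasonal"})
print(f"median change over 3 generations: {s.median_change:.1f}% "
      f"[{s.ci_low:.1f}, {s.ci_high:.1f}]")
print(f"P(reduction >= 30%) = {s.p_decline_30:.2f}, "
      f"P(>= 50%) = {s.p_decline_50:.2f}")
```

Output:

```
ice trend: -1.27 d/yr (s.e. 0.02)
projected ice-covered days in 2050: 119
median change over 3 generations: -43.8% [-52.8, -33.2]
P(reduction >= 30%) = 0.99, P(>= 50%) = 0.09
```

The simulated area loses ice-covered days at −1.27 d/yr; with a fitted
slope of β = 0.013 per ice-covered day, the population declines by a median
43.8% over three 11.5-year generations. The reduction exceeds 30% with
probability 0.99 but 50% with probability only 0.09, which under the
default risk tolerance maps to the Vulnerable category
(`red_list_category(s)`).

## Command line

```bash
icepipe simulate-data --config config.yaml --seed 1 --out inputs/
icepipe ice-metric --concentration inputs/ --regions inputs/regions.csv --out metrics
icepipe gl --captures inputs/captures.csv --out gl.csv
icepipe fit --abundance inputs/abundance.csv --annual-ice metrics_annual_ice.csv --out fits.csv
icepipe project --trends metrics_trends.csv --fits fits.csv --abundance inputs/abundance.csv --out table.csv
icepipe report --table table.csv --out report.json
# or everything at once:
icepipe run --config config.yaml --out results/
```

`icepipe run` writes per-stage CSVs, a six-row scenario table
(3 approaches × 2 GL values), and a JSON report with cross-scenario median
threshold probabilities and the Red List category; reruns with the same
configuration and seed are byte-identical.

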