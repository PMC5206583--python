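"""Synthetic reconstruction of the global polar bear study system.

This module packages the conditions of the reference global assessment in a
form the pipeline can run without the original data, which were never
deposited:

* published summary values used as *inputs*: the four ecoregion slope
  coefficients of the ice-abundance relation (with standard errors), the
  near-zero global coefficient, the two generation-length values (mean and
  95th percentile), and the six-scenario summary table (median change and
  reduction-threshold probabilities per approach x generation length);
* synthetic stand-ins, chosen once, for quantities only available in the
  original supplementary material: the 19 per-subpopulation ice-trend
  slopes (their median is -1.26 days/yr and their 2.5/97.5 quantiles
  approximate the published interval -3.37 to -0.71), baseline ice-covered
  days in 2015 per ecoregion, and most-recent abundance weights (round
  numbers summing to ~25,000 of the ~26,000 global total, Arctic Basin
  excluded from projections).

Everything here is a stand-in for unavailable reference data, not a
measurement; see docs/methods.md for the rationale behind each choice.
"""

from __future__ import annotations

import numpy as np

from .ice_metrics import AnnualIceSeries, IceTrend
from .projection_engine import ProjectionSummary, Scenario
from .relation_models import GLOBAL_SCOPE, RelationFit
from .synthetic_data import AbundanceSimSpec, CaptureSimSpec, IceFieldSpec

#: generation length (years): estimated mean and 95th bootstrap percentile
GL_MEAN = 11.5
GL_P95 = 13.6

#: published ice-abundance slope (beta, se) per ecoregion (approach 3)
ECOREGION_BETAS: dict[str, tuple[float, float]] = {
    "seasonal": (0.013, 0.002),
    "divergent": (0.032, 0.009),
    "convergent": (-0.008, 0.009),
    "archipelago": (-0.029, 0.030),
}

#: published global slope (approach 2): below 0.001 and not significant
GLOBAL_BETA = (0.0005, 0.005)

#: (subpopulation, ecoregion, ice slope d/yr, ice-covered days in 2015, latest N)
#: slopes and baselines are synthetic stand-ins; the 19-slope median is -1.26
SUBPOPULATIONS: list[tuple[str, str, float, float, float]] = [
    ("EG", "convergent", -1.00, 280.0, 1000.0),
    ("NB", "convergent", -0.90, 280.0, 980.0),
    ("SB", "divergent", -1.60, 200.0, 900.0),
    ("CS", "divergent", -1.80, 200.0, 3000.0),
    ("LP", "divergent", -2.20, 200.0, 1000.0),
    ("KS", "divergent", -3.00, 200.0, 1000.0),
    ("BS", "divergent", -3.37, 200.0, 2650.0),
    ("MC", "archipelago", -0.75, 300.0, 280.0),
    ("VM", "archipelago", -0.73, 300.0, 160.0),
    ("NW", "archipelago", -0.71, 300.0, 200.0),
    ("KB", "archipelago", -0.85, 300.0, 360.0),
    ("LS", "archipelago", -0.80, 300.0, 2540.0),
    ("GB", "archipelago", -0.78, 300.0, 1590.0),
    ("WH", "seasonal", -1.30, 150.0, 1030.0),
    ("FB", "seasonal", -1.26, 150.0, 2580.0),
    ("BB", "seasonal", -1.50, 150.0, 2830.0),
    ("DS", "seasonal", -1.40, 150.0, 2160.0),
    ("SH", "seasonal", -1.10, 150.0, 940.0),
    ("AB", "convergent", -1.26, 330.0, 500.0),
]

#: subpopulations excluded from projections (few year-round residents)
EXCLUDED = ("AB",)

#: per-subpopulation trend uncertainty (stand-in): residual sd of yearly ice
#: counts about the line, and the slope se it implies over 1979-2014
TREND_RESIDUAL_SD = 10.0
TREND_YEARS = (1979, 2014)

#: published six-scenario summary: (approach, gl, median change %, ci_low,
#: ci_high, p>=0%, p>=30%, p>=50%, p>=80%)
REFERENCE_SCENARIOS: list[tuple] = [
    (1, GL_MEAN, -30.0, -35.0, -25.0, 1.00, 0.56, 0.00, 0.00),
    (1, GL_P95, -34.0, -40.0, -29.0, 1.00, 0.95, 0.00, 0.00),
    (2, GL_MEAN, -4.0, -62.0, 50.0, 0.55, 0.20, 0.06, 0.00),
    (2, GL_P95, -4.0, -68.0, 56.0, 0.55, 0.24, 0.08, 0.00),
    (3, GL_MEAN, -43.0, -76.0, -20.0, 1.00, 0.86, 0.30, 0.01),
    (3, GL_P95, -45.0, -79.0, -21.0, 1.00, 0.88, 0.35, 0.02),
]

#: capture-study conditions: 11 subpopulations, true GL offsets about the
#: 11.5-year mean; event counts sized so observed+pseudo events total ~3,374
CAPTURE_SUBPOPS: list[tuple[str, float]] = [
    ("WH", -1.8), ("SB", -1.2), ("NB", -0.9), ("SH", -0.5), ("DS", -0.2),
    ("FB", 0.0), ("BB", 0.3), ("GB", 0.6), ("LS", 0.9), ("KB", 1.2),
    ("CS", 1.6),
]
CAPTURE_EVENTS_PER_SUBPOP = 234
CAPTURE_AGE_SD = 2.5
CAPTURE_P_YEARLING = 0.31

#: abundance-estimate availability: four subpopulations with longer series,
#: three with a single >=10-year pair (seven subpopulations in total)
ABUNDANCE_EST_YEARS: dict[str, tuple[int, ...]] = {
    "WH": (1984, 1989, 1994, 1999, 2004, 2011),
    "SB": (1986, 1992, 1998, 2004, 2010),
    "SH": (1986, 1992, 1999, 2005, 2012),
    "LS": (1980, 1986, 1992, 1998, 2004, 2010),
    "CS": (1990, 2010),
    "BS": (1988, 2008),
    "DS": (1986, 2007),
}
ABUNDANCE_OBS_CV = 0.12


def mean_year() -> float:
    return 0.5 * (TREND_YEARS[0] + TREND_YEARS[1])


def trend_slope_se() -> float:
    years = np.arange(TREND_YEARS[0], TREND_YEARS[1] + 1)
    sxx = float(np.sum((years - years.mean()) ** 2))
    return TREND_RESIDUAL_SD / np.sqrt(sxx)


def make_trends() -> dict[str, IceTrend]:
    """Stand-in ice trends anchored to the 2015 baselines."""
    n = TREND_YEARS[1] - TREND_YEARS[0] + 1
    ybar = mean_year()
    se = trend_slope_se()
    out = {}
    for sub, _, slope, baseline, _ in SUBPOPULATIONS:
        intercept = baseline - slope * 2015.0
        intercept_se = float(np.sqrt(TREND_RESIDUAL_SD ** 2 / n + ybar ** 2 * se ** 2))
        out[sub] = IceTrend(
            region_id=sub, slope=slope, intercept=intercept, slope_se=se,
            intercept_se=intercept_se, residual_sd=TREND_RESIDUAL_SD,
            slope_intercept_cov=-ybar * se ** 2, mean_year=ybar,
            mean_ice=intercept + slope * ybar, n_years=n,
        )
    return out


def make_weights(include_excluded: bool = False) -> dict[str, float]:
    return {sub: n for sub, _, _, _, n in SUBPOPULATIONS
            if include_excluded or sub not in EXCLUDED}


def ecoregion_map() -> dict[str, str]:
    return {sub: eco for sub, eco, _, _, _ in SUBPOPULATIONS}


def published_fits() -> dict[str, RelationFit]:
    """Published relation coefficients as RelationFit inputs."""
    fits = {GLOBAL_SCOPE: RelationFit(2, GLOBAL_SCOPE, *GLOBAL_BETA, n_obs=7)}
    for eco, (b, se) in ECOREGION_BETAS.items():
        fits[eco] = RelationFit(3, eco, b, se, n_obs=0)
    return fits


def reference_summaries() -> list[ProjectionSummary]:
    """The published six-scenario table as ProjectionSummary objects."""
    return [
        ProjectionSummary(Scenario(approach=a, gl=g, n_sims=62_500),
                          med, lo, hi, p0, p30, p50, p80)
        for a, g, med, lo, hi, p0, p30, p50, p80 in REFERENCE_SCENARIOS
    ]


def make_annual_ice(seed: int, noise_sd: float = 8.0) -> dict[str, AnnualIceSeries]:
    """Stand-in yearly ice-covered-day series consistent with the trends."""
    rng = np.random.default_rng(seed)
    years = np.arange(TREND_YEARS[0], TREND_YEARS[1] + 1)
    out = {}
    for sub, _, slope, baseline, _ in SUBPOPULATIONS:
        ice = baseline + slope * (years - 2015.0) + rng.normal(0, noise_sd, len(years))
        ice = np.clip(np.round(ice), 0, 366).astype(int)
        out[sub] = AnnualIceSeries(sub, years, ice, midpoint=np.nan)
    return out


def capture_specs() -> list[CaptureSimSpec]:
    return [
        CaptureSimSpec(true_gl=GL_MEAN + off, age_sd=CAPTURE_AGE_SD,
                       n_events=CAPTURE_EVENTS_PER_SUBPOP,
                       p_yearling=CAPTURE_P_YEARLING, subpopulation=sub,
                       start_year=1985, n_years=25)
        for sub, off in CAPTURE_SUBPOPS
    ]


def abundance_specs() -> dict[str, AbundanceSimSpec]:
    ecos = ecoregion_map()
    weights = make_weights(include_excluded=True)
    out = {}
    for sub, est_years in ABUNDANCE_EST_YEARS.items():
        beta = ECOREGION_BETAS[ecos[sub]][0]
        out[sub] = AbundanceSimSpec(true_beta=beta, n0=weights[sub],
                                    obs_cv=ABUNDANCE_OBS_CV, est_years=est_years)
    return out


def ice_field_spec(sub: str, grid: tuple[int, int] = (5, 5)) -> IceFieldSpec:
    """Concentration-field spec whose implied ice-day trend matches the
    subpopulation's stand-in slope.

    For a sinusoid of amplitude A crossing a fixed midpoint, a shift of the
    annual mean by delta km^2 moves the day count by delta * 365 / (pi * A)
    days, so the daily-area trend is calibrated as slope * pi * A / 365.
    """
    amplitude = 6.0e5
    slope = dict((s, sl) for s, _, sl, _, _ in SUBPOPULATIONS)[sub]
    return IceFieldSpec(
        region_id=sub,
        n_years=TREND_YEARS[1] - TREND_YEARS[0] + 1,
        start_year=TREND_YEARS[0],
        mean_area=1.5e6,
        seasonal_amplitude=amplitude,
        trend=slope * np.pi * amplitude / 365.0,
        noise_sd=2.0e4,
        grid_shape=grid,
        cell_area=2.5e5,
    )
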