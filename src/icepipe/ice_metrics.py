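"""Standardized sea-ice habitat metric *ice* (ice-covered days per year).

The metric is computed per subpopulation area from daily sea-ice area:
daily area is the concentration-weighted cell area over all grid cells whose
concentration exceeds a cutoff (default 15%); a fixed per-region threshold
(the midpoint between the mean summer-minimum and mean winter-maximum areas
over a baseline period) converts the daily series into a yearly count of
days above the midpoint. Yearly counts are then fit with an ordinary
least-squares linear trend and projected forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

ECOREGIONS = ("convergent", "divergent", "archipelago", "seasonal")

#: minimum number of days with data required to score a calendar year
MIN_DAYS_PER_YEAR = 300


def days_in_year(year: int, calendar: str = "noleap") -> int:
    if calendar == "noleap":
        return 365
    y = int(year)
    leap = (y % 4 == 0 and y % 100 != 0) or (y % 400 == 0)
    return 366 if leap else 365


@dataclass(frozen=True)
class RegionDefinition:
    """A subpopulation area: a set of grid cells with areas, in an ecoregion."""

    region_id: str
    ecoregion: str
    cell_ids: tuple[str, ...]
    cell_areas: tuple[float, ...]

    def __post_init__(self):
        if self.ecoregion not in ECOREGIONS:
            raise ValueError(
                f"unknown ecoregion {self.ecoregion!r}; expected one of {ECOREGIONS}"
            )
        if len(self.cell_ids) == 0:
            raise ValueError(f"region {self.region_id}: empty cell set")
        if len(self.cell_ids) != len(self.cell_areas):
            raise ValueError(f"region {self.region_id}: cell_ids/cell_areas length mismatch")
        if any(a <= 0 for a in self.cell_areas):
            raise ValueError(f"region {self.region_id}: cell areas must be positive")


@dataclass
class DailyIceSeries:
    """Daily total sea-ice area (km^2) for one region.

    Days are identified by (year, doy).  ``calendar`` is "noleap" (365-day
    years, the synthetic convention) or "standard".
    """

    region_id: str
    year: np.ndarray
    doy: np.ndarray
    area: np.ndarray
    calendar: str = "noleap"

    def __post_init__(self):
        self.year = np.asarray(self.year, dtype=int)
        self.doy = np.asarray(self.doy, dtype=int)
        self.area = np.asarray(self.area, dtype=float)
        if not (len(self.year) == len(self.doy) == len(self.area)):
            raise ValueError("year/doy/area must have equal length")
        idx = self.day_index()
        if np.any(np.diff(idx) <= 0):
            raise ValueError(f"region {self.region_id}: dates must be strictly increasing")
        if np.any(self.area < 0):
            raise ValueError(f"region {self.region_id}: negative daily area")

    def day_index(self) -> np.ndarray:
        """Running day count from the first year in the series."""
        y0 = int(self.year.min()) if len(self.year) else 0
        if self.calendar == "noleap":
            return (self.year - y0) * 365 + (self.doy - 1)
        years = np.arange(y0, int(self.year.max()) + 1)
        lengths = np.array([days_in_year(y, "standard") for y in years])
        offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        return offsets[self.year - y0] + (self.doy - 1)

    @classmethod
    def from_dates(cls, region_id: str, dates: Sequence, area: Sequence[float]) -> "DailyIceSeries":
        dt = pd.DatetimeIndex(dates)
        return cls(region_id, dt.year.values, dt.dayofyear.values,
                   np.asarray(area, float), calendar="standard")


@dataclass
class AnnualIceSeries:
    """Yearly ice-covered-day counts for one region, with the midpoint used."""

    region_id: str
    years: np.ndarray
    ice: np.ndarray
    midpoint: float

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.ice = np.asarray(self.ice, dtype=int)
        if len(self.years) != len(self.ice):
            raise ValueError("years/ice length mismatch")
        if len(np.unique(self.years)) != len(self.years):
            raise ValueError("duplicate years in annual series")
        if np.any(self.ice < 0) or np.any(self.ice > 366):
            raise ValueError("ice-covered days must lie in [0, 366]")


@dataclass
class IceTrend:
    """OLS linear trend of ice-covered days on calendar year."""

    region_id: str
    slope: float          # days per year
    intercept: float      # days, at calendar year 0
    slope_se: float
    intercept_se: float
    residual_sd: float
    slope_intercept_cov: float
    mean_year: float = 0.0
    mean_ice: float = 0.0
    n_years: int = 0

    def __post_init__(self):
        if self.slope_se < 0 or self.residual_sd < 0:
            raise ValueError("standard errors must be non-negative")


def daily_ice_area(
    concentration: Mapping[str, float] | pd.Series,
    region: RegionDefinition,
    cutoff: float = 0.15,
) -> float:
    """Sum concentration x cell-area over region cells with concentration > cutoff.

    ``concentration`` maps cell_id -> fractional concentration for one day.
    Cells at or below the cutoff contribute nothing (strict inequality).
    """
    conc = pd.Series(concentration)
    missing = [c for c in region.cell_ids if c not in conc.index]
    if missing:
        raise KeyError(
            f"region {region.region_id}: cells missing from concentration grid: {missing}"
        )
    vals = conc.loc[list(region.cell_ids)].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 1 + 1e-9):
        raise ValueError(
            f"region {region.region_id}: concentrations must be finite fractions in [0, 1]"
        )
    areas = np.asarray(region.cell_areas, dtype=float)
    mask = vals > cutoff
    return float(np.sum(vals[mask] * areas[mask]))


def region_daily_series(ds, region: RegionDefinition, cutoff: float = 0.15) -> DailyIceSeries:
    """Vectorized daily_ice_area over an xarray concentration Dataset.

    Expects variables ``concentration`` (time, row, col) and ``cell_area``
    (row, col), with cells identified as ``r{row}c{col}``; time carries either
    datetime64 values or integer ``year``/``doy`` coordinates.
    """
    conc = np.asarray(ds["concentration"].values, dtype=float)
    areas = np.asarray(ds["cell_area"].values, dtype=float)
    nrow, ncol = areas.shape
    id_to_rc = {f"r{r}c{c}": (r, c) for r in range(nrow) for c in range(ncol)}
    missing = [cid for cid in region.cell_ids if cid not in id_to_rc]
    if missing:
        raise KeyError(f"region {region.region_id}: cells missing from grid: {missing}")
    rows, cols = zip(*(id_to_rc[cid] for cid in region.cell_ids))
    sub = conc[:, rows, cols]                      # (time, ncells)
    if np.any(~np.isfinite(sub)) or sub.min() < 0 or sub.max() > 1 + 1e-9:
        raise ValueError("concentrations must be finite fractions in [0, 1]")
    w = np.asarray(region.cell_areas, dtype=float)
    area = np.where(sub > cutoff, sub, 0.0) @ w
    tvals = ds["time"].values
    if np.issubdtype(np.asarray(tvals).dtype, np.datetime64):
        dt = pd.DatetimeIndex(tvals)
        return DailyIceSeries(region.region_id, dt.year.values, dt.dayofyear.values,
                              area, calendar="standard")
    return DailyIceSeries(region.region_id, np.asarray(ds["year"].values, int),
                          np.asarray(ds["doy"].values, int), area, calendar="noleap")


def fill_gaps(series: DailyIceSeries, max_gap: int = 5) -> DailyIceSeries:
    """Fill missing days by linear interpolation (edges: nearest value).

    A run of more than ``max_gap`` consecutive missing days is an error.
    """
    idx = series.day_index()
    full = np.arange(idx[0], idx[-1] + 1)
    if len(full) == len(idx):
        return series
    present = np.zeros(len(full), dtype=bool)
    present[idx - idx[0]] = True
    # longest run of missing days
    runs = np.diff(idx)
    worst = int(runs.max()) - 1
    if worst > max_gap:
        raise ValueError(
            f"region {series.region_id}: gap of {worst} consecutive missing days "
            f"exceeds max_gap={max_gap}"
        )
    area = np.interp(full, idx, series.area)
    # reconstruct (year, doy) for the full index
    y0 = int(series.year.min())
    if series.calendar == "noleap":
        year = y0 + full // 365
        doy = full % 365 + 1
    else:
        years = np.arange(y0, int(series.year.max()) + 1)
        lengths = np.array([days_in_year(y, "standard") for y in years])
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        year = y0 + np.searchsorted(offsets, full, side="right") - 1
        doy = full - offsets[year - y0] + 1
    return DailyIceSeries(series.region_id, year, doy, area, calendar=series.calendar)


def _year_slice(series: DailyIceSeries, year: int) -> np.ndarray:
    return series.area[series.year == year]


def annual_extremes(series: DailyIceSeries, year: int) -> tuple[float, float]:
    """(summer minimum, winter maximum) of daily area in one calendar year."""
    vals = _year_slice(series, year)
    if len(vals) < MIN_DAYS_PER_YEAR:
        raise ValueError(
            f"region {series.region_id}, year {year}: only {len(vals)} days with data "
            f"(need >= {MIN_DAYS_PER_YEAR})"
        )
    return float(vals.min()), float(vals.max())


def compute_midpoint(series: DailyIceSeries, baseline_years: Iterable[int]) -> float:
    """Midpoint between mean annual minimum and mean annual maximum area.

    One fixed threshold per region, pooled over the baseline years.
    """
    years = list(baseline_years)
    if not years:
        raise ValueError("empty baseline for midpoint")
    mins, maxs = zip(*(annual_extremes(series, y) for y in years))
    return 0.5 * (float(np.mean(mins)) + float(np.mean(maxs)))


def ice_covered_days(series: DailyIceSeries, midpoint: float, year: int) -> int:
    """Number of days in the year with area strictly above the midpoint."""
    vals = _year_slice(series, year)
    if len(vals) < MIN_DAYS_PER_YEAR:
        raise ValueError(
            f"region {series.region_id}, year {year}: only {len(vals)} days with data "
            f"(need >= {MIN_DAYS_PER_YEAR})"
        )
    return int(np.sum(vals > midpoint))


def annual_ice_series(
    series: DailyIceSeries,
    baseline_years: Iterable[int] | None = None,
    max_gap: int = 5,
) -> AnnualIceSeries:
    """Gap-fill a daily series and reduce it to yearly ice-covered-day counts."""
    filled = fill_gaps(series, max_gap=max_gap)
    years = np.unique(filled.year)
    years = np.array([y for y in years
                      if np.sum(filled.year == y) >= MIN_DAYS_PER_YEAR])
    if baseline_years is None:
        baseline_years = years
    mid = compute_midpoint(filled, baseline_years)
    ice = np.array([ice_covered_days(filled, mid, y) for y in years])
    return AnnualIceSeries(series.region_id, years, ice, mid)


def fit_ice_trend(annual: AnnualIceSeries) -> IceTrend:
    """OLS fit of yearly ice-covered days on calendar year.

    The regression is centred on the mean year internally; slope/intercept and
    their covariance are reported on the calendar scale.
    """
    if len(annual.years) < 3:
        raise ValueError(
            f"region {annual.region_id}: need >= 3 years to fit a trend, "
            f"got {len(annual.years)}"
        )
    ybar = float(np.mean(annual.years))
    x = annual.years - ybar
    X = sm.add_constant(x)
    res = sm.OLS(annual.ice.astype(float), X).fit()
    b0, b1 = res.params          # level at mean year, slope
    v0, v1 = np.diag(res.cov_params())
    intercept = b0 - b1 * ybar
    intercept_var = v0 + ybar ** 2 * v1      # cov(b0,b1)=0 for centred x
    cov = -ybar * v1
    return IceTrend(
        region_id=annual.region_id,
        slope=float(b1),
        intercept=float(intercept),
        slope_se=float(np.sqrt(v1)),
        intercept_se=float(np.sqrt(intercept_var)),
        residual_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        slope_intercept_cov=float(cov),
        mean_year=ybar,
        mean_ice=float(b0),
        n_years=len(annual.years),
    )


def project_ice(trend: IceTrend, year: float) -> tuple[float, float]:
    """Point prediction of ice-covered days (clamped to [0, 366]) and its SE.

    The SE is that of the mean prediction from the fitted line.
    """
    pred = trend.intercept + trend.slope * year
    pred = float(np.clip(pred, 0.0, 366.0))
    if trend.n_years > 0:
        var_level = trend.residual_sd ** 2 / trend.n_years
    else:
        var_level = trend.intercept_se ** 2 - trend.mean_year ** 2 * trend.slope_se ** 2
        var_level = max(var_level, 0.0)
    se = float(np.sqrt(var_level + (year - trend.mean_year) ** 2 * trend.slope_se ** 2))
    return pred, se
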