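"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the three observational inputs:

* daily gridded sea-ice concentration whose area-weighted total follows a
  seasonal sinusoid (winter maximum, summer minimum) with a linear trend and
  Gaussian noise, distributed over cells by a smooth spatial gradient so the
  concentration cutoff is exercised;
* capture records of adult females with dependent cubs, whose
  cub-of-the-year mothers have a known mean age (the true generation
  length), a fraction of litters re-observed as yearlings one year later;
* subpopulation abundance series generated from a known log-linear
  ice-abundance slope with multiplicative lognormal sampling error.

Synthetic calendars use 365-day years (no leap days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .ice_metrics import AnnualIceSeries

#: day of (365-day) year at which the seasonal winter maximum occurs
WINTER_PEAK_DOY = 75


@dataclass(frozen=True)
class IceFieldSpec:
    """Parameters of a synthetic daily sea-ice concentration field."""

    region_id: str
    n_years: int
    start_year: int
    mean_area: float            # km^2, annual mean of daily total area
    seasonal_amplitude: float   # km^2
    trend: float                # km^2 per year applied to daily area
    noise_sd: float             # km^2
    grid_shape: tuple[int, int] = (8, 8)
    cell_area: float = 625.0    # km^2, nominal 25 x 25 km cells

    def __post_init__(self):
        if self.n_years <= 0:
            raise ValueError("n_years must be positive")
        if not (self.mean_area > self.seasonal_amplitude >= 0):
            raise ValueError("require mean_area > seasonal_amplitude >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cell_area <= 0 or min(self.grid_shape) <= 0:
            raise ValueError("grid cells must have positive size")
        if self.mean_area > self.total_grid_area:
            raise ValueError(
                f"mean_area {self.mean_area} exceeds total grid area "
                f"{self.total_grid_area}"
            )

    @property
    def total_grid_area(self) -> float:
        return self.grid_shape[0] * self.grid_shape[1] * self.cell_area


@dataclass(frozen=True)
class AbundanceSimSpec:
    """Parameters of a synthetic abundance-estimate series."""

    true_beta: float            # proportional change in N per ice-covered-day change
    n0: float                   # initial abundance (bears)
    obs_cv: float               # CV of the multiplicative observation error
    est_years: tuple[int, ...]  # calendar years with an estimate

    def __post_init__(self):
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.obs_cv < 0:
            raise ValueError("obs_cv must be non-negative")
        if len(self.est_years) == 0:
            raise ValueError("est_years must not be empty")


@dataclass(frozen=True)
class CaptureSimSpec:
    """Parameters of a synthetic capture-record set for one subpopulation."""

    true_gl: float              # years; mean age of cub-of-year mothers
    age_sd: float               # years
    n_events: int               # number of cub-of-year litters
    p_yearling: float           # P(litter re-observed as yearlings in t+1)
    subpopulation: str = "SYN"
    start_year: int = 2000
    n_years: int = 10

    def __post_init__(self):
        if self.true_gl <= 0:
            raise ValueError("true_gl must be positive")
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not (0.0 <= self.p_yearling <= 1.0):
            raise ValueError("p_yearling must lie in [0, 1]")
        if self.age_sd < 0:
            raise ValueError("age_sd must be non-negative")


def _spatial_gradient(grid_shape: tuple[int, int]) -> np.ndarray:
    """Smooth per-cell weight pattern in (0, 1], decreasing away from one corner.

    The gradient guarantees that for intermediate total areas some cells sit
    below the concentration cutoff while others saturate, so the cutoff rule
    is exercised by downstream metrics.
    """
    nrow, ncol = grid_shape
    r = np.arange(nrow)[:, None] / max(nrow - 1, 1)
    c = np.arange(ncol)[None, :] / max(ncol - 1, 1)
    d = np.sqrt(r ** 2 + c ** 2) / np.sqrt(2.0)
    return 0.05 + 0.95 * (1.0 - d)


def _solve_scale(targets: np.ndarray, base: np.ndarray, areas: np.ndarray,
                 iters: int = 80) -> np.ndarray:
    """Per-day scale s such that sum(clip(s*base, 0, 1) * areas) == target.

    The map s -> area is continuous and non-decreasing; bisection converges to
    float precision in `iters` halvings.
    """
    total = float(areas.sum())
    targets = np.clip(targets, 0.0, total)
    lo = np.zeros_like(targets)
    hi = np.full_like(targets, 1.0 / base.min())
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        got = np.clip(mid[:, None] * base[None, :], 0.0, 1.0) @ areas
        too_low = got < targets
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def seasonal_daily_area(spec: IceFieldSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free daily target areas (year, doy, area) for the spec."""
    n_days = spec.n_years * 365
    t = np.arange(n_days)
    year = spec.start_year + t // 365
    doy = t % 365 + 1
    phase = 2.0 * np.pi * (doy - WINTER_PEAK_DOY) / 365.0
    area = (spec.mean_area
            + spec.seasonal_amplitude * np.cos(phase)
            + spec.trend * (t / 365.0))
    return year, doy, area


def gen_ice_concentration(spec: IceFieldSpec, seed: int) -> xr.Dataset:
    """Generate daily concentration grids whose area-weighted total follows
    mean_area + seasonal sinusoid + trend + Gaussian noise.

    Returns an xarray Dataset with ``concentration`` (time, row, col),
    ``cell_area`` (row, col) and integer ``year``/``doy`` coordinates
    (365-day calendar).
    """
    rng = np.random.default_rng(seed)
    year, doy, target = seasonal_daily_area(spec)
    if spec.noise_sd > 0:
        target = target + rng.normal(0.0, spec.noise_sd, size=target.shape)
    target = np.clip(target, 0.0, spec.total_grid_area)

    base = _spatial_gradient(spec.grid_shape).ravel()
    areas = np.full(base.shape, spec.cell_area)
    scale = _solve_scale(target, base, areas)
    conc = np.clip(scale[:, None] * base[None, :], 0.0, 1.0)
    conc = conc.reshape(len(target), *spec.grid_shape)

    nrow, ncol = spec.grid_shape
    ds = xr.Dataset(
        {
            "concentration": (("time", "row", "col"), conc),
            "cell_area": (("row", "col"), np.full((nrow, ncol), spec.cell_area)),
        },
        coords={
            "time": np.arange(len(target)),
            "year": ("time", year),
            "doy": ("time", doy),
            "row": np.arange(nrow),
            "col": np.arange(ncol),
        },
        attrs={"region_id": spec.region_id, "calendar": "noleap", "units": "fraction"},
    )
    return ds


def gen_abundance_series(spec: AbundanceSimSpec, ice: AnnualIceSeries, seed: int) -> pd.DataFrame:
    """Simulate abundance estimates from log-linear ice-driven dynamics.

    Latent dynamics: ln N(t+1) = ln N(t) + true_beta * (ice(t+1) - ice(t)),
    anchored at n0 in the first ice year.  Observed estimates carry
    multiplicative lognormal error with coefficient of variation obs_cv and
    mean 1 (so estimates are unbiased for the latent N on the natural scale).

    Returns a DataFrame (subpopulation, year, n, se, latent_n).
    """
    missing = [y for y in spec.est_years if y not in set(ice.years.tolist())]
    if missing:
        raise ValueError(f"est_years not covered by ice series: {missing}")
    rng = np.random.default_rng(seed)
    ln_n = np.empty(len(ice.years))
    ln_n[0] = np.log(spec.n0)
    d_ice = np.diff(ice.ice.astype(float))
    for i, d in enumerate(d_ice):
        ln_n[i + 1] = ln_n[i] + spec.true_beta * d
    latent = dict(zip(ice.years.tolist(), np.exp(ln_n)))

    sigma2 = np.log1p(spec.obs_cv ** 2)
    rows = []
    for y in spec.est_years:
        eps = rng.normal(-0.5 * sigma2, np.sqrt(sigma2)) if sigma2 > 0 else 0.0
        n_obs = latent[y] * np.exp(eps)
        rows.append({
            "subpopulation": ice.region_id,
            "year": int(y),
            "n": float(n_obs),
            "se": float(spec.obs_cv * n_obs),
            "latent_n": float(latent[y]),
        })
    return pd.DataFrame(rows)


def gen_capture_data(spec: CaptureSimSpec, seed: int) -> pd.DataFrame:
    """Simulate capture records (subpopulation, year, age, cub_class).

    Cub-of-the-year mothers have ages ~ Normal(true_gl, age_sd), truncated
    below at 5 (adult).  Each litter is independently re-observed as
    yearlings in the following year (mother one year older) with probability
    p_yearling.
    """
    rng = np.random.default_rng(seed)
    years = rng.integers(spec.start_year, spec.start_year + spec.n_years,
                         size=spec.n_events)
    ages = rng.normal(spec.true_gl, spec.age_sd, size=spec.n_events)
    ages = np.maximum(ages, 5.0)
    rows = [
        {"subpopulation": spec.subpopulation, "year": int(y), "age": float(a),
         "cub_class": "coy"}
        for y, a in zip(years, ages)
    ]
    follow = rng.random(spec.n_events) < spec.p_yearling
    for y, a, f in zip(years, ages, follow):
        if f:
            rows.append({"subpopulation": spec.subpopulation, "year": int(y) + 1,
                         "age": float(a) + 1.0, "cub_class": "yearling"})
    return pd.DataFrame(rows, columns=["subpopulation", "year", "age", "cub_class"])
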