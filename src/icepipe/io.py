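"""File readers and writers for the pipeline's input and output formats.

Conventions: CSV is UTF-8, comma-separated, with a header row and '.'
decimals; dates are ISO-8601.  Grid cells are identified by opaque strings
("r{row}c{col}" for synthetic grids) so real polar-stereographic products
and synthetic grids share one code path.  Concentration grids travel as
NetCDF (classic format via the scipy engine) with dimensions
time x row x col.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .generation_length import GenerationLengthEstimate
from .ice_metrics import AnnualIceSeries, IceTrend, RegionDefinition
from .projection_engine import ProjectionSummary
from .relation_models import AbundanceEstimate, RelationFit

logger = logging.getLogger(__name__)

NETCDF_ENGINE = "scipy"


# --- concentration grids -------------------------------------------------

def write_concentration(ds: xr.Dataset, path: str | Path) -> None:
    ds.to_netcdf(path, engine=NETCDF_ENGINE)


def read_concentration(path: str | Path) -> xr.Dataset:
    """Read a daily concentration file and validate it.

    Values on a 0-100 scale (flagged by a ``units`` attribute of "percent",
    or detected from the value range) are rescaled to fractions with a
    logged note.  Duplicate dates and non-finite values are errors.
    """
    ds = xr.load_dataset(path, engine=NETCDF_ENGINE)
    if "concentration" not in ds:
        raise ValueError(f"{path}: no 'concentration' variable")
    conc = ds["concentration"].values
    if not np.all(np.isfinite(conc)):
        raise ValueError(f"{path}: non-finite concentration values")
    units = str(ds.attrs.get("units", "")).lower()
    cmax = float(conc.max(initial=0.0))
    if units in ("percent", "%") or (units == "" and cmax > 1.5):
        logger.info("%s: rescaling 0-100 concentrations to fractions", path)
        ds["concentration"] = ds["concentration"] / 100.0
        ds.attrs["units"] = "fraction"
        conc = ds["concentration"].values
    if conc.min(initial=0.0) < 0 or conc.max(initial=0.0) > 1 + 1e-9:
        raise ValueError(f"{path}: concentrations outside [0, 1] (units {units!r})")
    tvals = np.asarray(ds["time"].values)
    if np.issubdtype(tvals.dtype, np.datetime64):
        keys = tvals
    elif "year" in ds.coords and "doy" in ds.coords:
        keys = ds["year"].values * 1000 + ds["doy"].values
    else:
        keys = tvals
    uniq, counts = np.unique(keys, return_counts=True)
    dup = uniq[counts > 1]
    if len(dup):
        raise ValueError(f"{path}: duplicated dates: {dup[:5].tolist()}")
    return ds


def read_concentration_csv(path: str | Path) -> pd.DataFrame:
    """Long-format alternative: columns (date | year,doy), cell_id, concentration."""
    df = pd.read_csv(path)
    need = {"cell_id", "concentration"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    if not np.all(np.isfinite(df["concentration"])):
        raise ValueError(f"{path}: non-finite concentration values")
    if df["concentration"].max() > 1.5:
        logger.info("%s: rescaling 0-100 concentrations to fractions", path)
        df["concentration"] = df["concentration"] / 100.0
    if df["concentration"].min() < 0 or df["concentration"].max() > 1 + 1e-9:
        raise ValueError(f"{path}: concentrations outside [0, 1]")
    return df


# --- region table --------------------------------------------------------

def write_region_table(regions: Sequence[RegionDefinition], path: str | Path) -> None:
    rows = [
        {"region_id": r.region_id, "ecoregion": r.ecoregion,
         "cell_id": cid, "cell_area_km2": a}
        for r in regions for cid, a in zip(r.cell_ids, r.cell_areas)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_region_table(path: str | Path) -> list[RegionDefinition]:
    df = pd.read_csv(path)
    need = {"region_id", "ecoregion", "cell_id", "cell_area_km2"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    out = []
    for rid, grp in df.groupby("region_id", sort=True):
        eco = grp["ecoregion"].iloc[0]
        out.append(RegionDefinition(str(rid), str(eco),
                                    tuple(grp["cell_id"].astype(str)),
                                    tuple(grp["cell_area_km2"].astype(float))))
    return out


# --- captures and abundance ----------------------------------------------

def write_captures(captures: pd.DataFrame, path: str | Path) -> None:
    captures.to_csv(path, index=False)


def read_captures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"subpopulation", "year", "age", "cub_class"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    bad = set(df["cub_class"].unique()) - {"coy", "yearling", "none"}
    if bad:
        raise ValueError(f"{path}: unknown cub_class values {sorted(bad)}")
    return df


def write_abundance(estimates: Sequence[AbundanceEstimate] | pd.DataFrame,
                    path: str | Path,
                    ecoregions: Mapping[str, str] | None = None) -> None:
    if isinstance(estimates, pd.DataFrame):
        df = estimates.copy()
    else:
        df = pd.DataFrame([{"subpopulation": e.subpopulation, "year": e.year,
                            "n": e.n, "se": e.se} for e in estimates])
    if ecoregions is not None:
        df["ecoregion"] = df["subpopulation"].map(ecoregions)
    df.to_csv(path, index=False)


def read_abundance(path: str | Path) -> tuple[list[AbundanceEstimate], dict[str, str]]:
    df = pd.read_csv(path)
    need = {"subpopulation", "year", "n", "se"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    ests = [AbundanceEstimate(str(r.subpopulation), int(r.year), float(r.n), float(r.se))
            for r in df.itertuples(index=False)]
    ecos = {}
    if "ecoregion" in df.columns:
        ecos = dict(zip(df["subpopulation"].astype(str), df["ecoregion"].astype(str)))
    return ests, ecos


# --- annual ice and trends -----------------------------------------------

def write_annual_ice(series: Sequence[AnnualIceSeries], path: str | Path) -> None:
    rows = [
        {"region_id": s.region_id, "year": int(y), "ice_days": int(i),
         "midpoint_km2": s.midpoint}
        for s in series for y, i in zip(s.years, s.ice)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annual_ice(path: str | Path) -> dict[str, AnnualIceSeries]:
    df = pd.read_csv(path)
    need = {"region_id", "year", "ice_days", "midpoint_km2"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    out = {}
    for rid, grp in df.sort_values("year").groupby("region_id"):
        out[str(rid)] = AnnualIceSeries(str(rid), grp["year"].to_numpy(),
                                        grp["ice_days"].to_numpy(),
                                        float(grp["midpoint_km2"].iloc[0]))
    return out


_TREND_COLS = ["region_id", "slope", "intercept", "slope_se", "intercept_se",
               "residual_sd", "slope_intercept_cov", "mean_year", "mean_ice",
               "n_years"]


def write_trends(trends: Sequence[IceTrend], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(t, c) for c in _TREND_COLS} for t in trends]) \
        .to_csv(path, index=False)


def read_trends(path: str | Path) -> dict[str, IceTrend]:
    df = pd.read_csv(path)
    if not set(_TREND_COLS) <= set(df.columns):
        raise ValueError(f"{path}: need columns {_TREND_COLS}")
    out = {}
    for r in df.itertuples(index=False):
        kw = {c: getattr(r, c) for c in _TREND_COLS}
        kw["region_id"] = str(kw["region_id"])
        kw["n_years"] = int(kw["n_years"])
        out[kw["region_id"]] = IceTrend(**kw)
    return out


# --- fits, scenarios, reports --------------------------------------------

def write_fits(fits: Sequence[RelationFit], path: str | Path) -> None:
    pd.DataFrame([{"approach": f.approach, "scope": f.scope, "beta": f.beta,
                   "se": f.beta_se, "n_obs": f.n_obs} for f in fits]) \
        .to_csv(path, index=False)


def read_fits(path: str | Path) -> list[RelationFit]:
    df = pd.read_csv(path)
    return [RelationFit(int(r.approach), str(r.scope), float(r.beta),
                        float(r.se), int(r.n_obs))
            for r in df.itertuples(index=False)]


def write_scenario_table(summaries: Sequence[ProjectionSummary], path: str | Path) -> None:
    """Scenario-by-scenario results: one row per (approach, horizon)."""
    rows = [
        {
            "approach": s.scenario.approach,
            "gl": s.scenario.gl,
            "horizon_years": s.scenario.horizon,
            "median_change_pct": round(s.median_change, 4),
            "ci_low_pct": round(s.ci_low, 4),
            "ci_high_pct": round(s.ci_high, 4),
            "p_decline_0": round(s.p_decline_0, 6),
            "p_decline_30": round(s.p_decline_30, 6),
            "p_decline_50": round(s.p_decline_50, 6),
            "p_decline_80": round(s.p_decline_80, 6),
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_gl_summary(est: GenerationLengthEstimate, per_subpop: pd.DataFrame,
                     path: str | Path) -> None:
    overall = pd.DataFrame([{
        "subpopulation": "ALL", "n": est.n_events, "gl": est.gl_mean,
        "percentile_5": est.percentile_5, "percentile_95": est.percentile_95,
    }])
    df = per_subpop.copy()
    df["percentile_5"] = np.nan
    df["percentile_95"] = np.nan
    pd.concat([df, overall], ignore_index=True).to_csv(path, index=False)


def write_json_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(_sanitize_keys(report), indent=2,
                                     sort_keys=True, default=_default) + "\n")


def _sanitize_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize_keys(v) for v in obj]
    return obj
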