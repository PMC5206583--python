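"""Three approaches relating the habitat metric *ice* to abundance N.

Approach 1 assumes carrying capacity, hence N, is one-to-one proportional to
ice-covered days: the projected proportional change in N equals the
projected proportional change in *ice*.

Approaches 2 and 3 regress observed annualized proportional changes in N
(r_n = ln(N2/N1) / span, per year) on the concurrent annual change in
ice-covered days (d_ice, the OLS slope of *ice* over the pair's interval),
through the origin: r_n = beta * d_ice.  Approach 2 pools observations into
one global fit; approach 3 fits one relation per ecoregion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ice_metrics import AnnualIceSeries, IceTrend, fit_ice_trend, project_ice

logger = logging.getLogger(__name__)

GLOBAL_SCOPE = "global"


@dataclass(frozen=True)
class AbundanceEstimate:
    """A subpopulation abundance estimate with sampling uncertainty."""

    subpopulation: str
    year: int
    n: float   # bears
    se: float  # bears

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError(f"{self.subpopulation} {self.year}: abundance must be positive")
        if self.se < 0:
            raise ValueError(f"{self.subpopulation} {self.year}: se must be non-negative")


@dataclass(frozen=True)
class PairedChange:
    """One (change in N, change in ice) observation from a pair of estimates."""

    subpopulation: str
    ecoregion: str
    r_n: float     # annualized proportional change in N, log scale (1/yr)
    d_ice: float   # annual change in ice-covered days (days/yr)
    span: float    # years between the paired estimates


@dataclass(frozen=True)
class RelationFit:
    """Fitted (or assumed) ice-abundance relation for one scope."""

    approach: int
    scope: str            # "global" or an ecoregion name
    beta: float           # per-day annualized proportional change in N
    beta_se: float
    n_obs: int

    def __post_init__(self):
        if self.beta_se < 0:
            raise ValueError("beta_se must be non-negative")


def _ice_slope(annual: AnnualIceSeries, y1: int, y2: int) -> float:
    """OLS slope of ice-covered days over the inclusive year window [y1, y2].

    Falls back to the endpoint difference divided by the span when fewer than
    three annual values fall in the window.
    """
    mask = (annual.years >= y1) & (annual.years <= y2)
    yrs = annual.years[mask]
    ice = annual.ice[mask].astype(float)
    if len(yrs) >= 3:
        sub = AnnualIceSeries(annual.region_id, yrs, ice.astype(int), annual.midpoint)
        return fit_ice_trend(sub).slope
    if len(yrs) == 2:
        return float((ice[1] - ice[0]) / (yrs[1] - yrs[0]))
    raise ValueError(
        f"region {annual.region_id}: ice series does not cover [{y1}, {y2}]"
    )


def paired_changes(
    estimates: Sequence[AbundanceEstimate],
    annual_ice: Mapping[str, AnnualIceSeries],
    ecoregions: Mapping[str, str],
    mode: str = "two-point",
    min_span: float = 10.0,
) -> list[PairedChange]:
    """Build (r_n, d_ice) observations from abundance estimates.

    two-point mode: per subpopulation, the earliest/latest pair of estimates,
    kept only when it spans at least ``min_span`` years.  series mode: every
    consecutive pair of estimates, regardless of span.
    """
    if mode not in ("two-point", "series"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    df = pd.DataFrame(
        [(e.subpopulation, e.year, e.n) for e in estimates],
        columns=["subpopulation", "year", "n"],
    ).sort_values(["subpopulation", "year"])
    out: list[PairedChange] = []
    for sub, grp in df.groupby("subpopulation"):
        if len(grp) < 2:
            logger.info("subpopulation %s: fewer than 2 estimates, skipped", sub)
            continue
        if sub not in annual_ice:
            raise KeyError(f"no ice series for subpopulation {sub}")
        if mode == "two-point":
            pairs = [(grp.iloc[0], grp.iloc[-1])]
        else:
            pairs = [(grp.iloc[i], grp.iloc[i + 1]) for i in range(len(grp) - 1)]
        for a, b in pairs:
            span = float(b.year - a.year)
            if span <= 0:
                continue
            if mode == "two-point" and span < min_span:
                logger.info("subpopulation %s: pair span %.0f < %.0f years, skipped",
                            sub, span, min_span)
                continue
            r_n = float(np.log(b.n / a.n) / span)
            d_ice = _ice_slope(annual_ice[sub], int(a.year), int(b.year))
            out.append(PairedChange(sub, ecoregions.get(sub, ""), r_n, d_ice, span))
    return out


def fit_relation(
    observations: Sequence[PairedChange],
    scope: str = GLOBAL_SCOPE,
    approach: int = 2,
    include_intercept: bool = False,
) -> RelationFit:
    """No-intercept least squares of r_n on d_ice for one scope.

    ``scope`` "global" uses all observations; an ecoregion name restricts to
    observations from that ecoregion.  Zero ice change predicting stable N is
    the default (regression through the origin); an intercept can be added
    via ``include_intercept``.
    """
    if scope == GLOBAL_SCOPE:
        obs = list(observations)
    else:
        obs = [o for o in observations if o.ecoregion == scope]
    if len(obs) < 2:
        raise ValueError(f"scope {scope!r}: need >= 2 observations, got {len(obs)}")
    x = np.array([o.d_ice for o in obs])
    y = np.array([o.r_n for o in obs])
    if np.allclose(x, 0.0):
        raise ValueError(f"scope {scope!r}: all d_ice are zero; beta unidentifiable")
    X = sm.add_constant(x) if include_intercept else x[:, None]
    res = sm.OLS(y, X).fit()
    slope_idx = 1 if include_intercept else 0
    return RelationFit(
        approach=approach,
        scope=scope,
        beta=float(res.params[slope_idx]),
        beta_se=float(res.bse[slope_idx]),
        n_obs=len(obs),
    )


def approach1_change(trend: IceTrend, start_year: int, horizon_years: int) -> float:
    """Proportional change in N under one-to-one ice proportionality.

    change = ice(start + horizon) / ice(start) - 1, using point predictions
    of the fitted ice trend (clamped to [0, 366] days), floored at -1.
    """
    base, _ = project_ice(trend, start_year)
    if base <= 0:
        raise ValueError(
            f"region {trend.region_id}: projected ice at start year {start_year} "
            f"is {base}; proportional change undefined"
        )
    future, _ = project_ice(trend, start_year + horizon_years)
    return max(future / base - 1.0, -1.0)
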