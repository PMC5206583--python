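"""Stochastic projections of mean global population size (MGPS).

Each Monte Carlo replicate draws regression coefficients from their
estimated sampling distributions (normal, mean = point estimate,
sd = standard error; trend slope and level jointly), projects every
subpopulation's proportional change in N over the three-generation horizon,
aggregates to a per cent change in MGPS using the most recent abundance
estimates as weights, and the replicate distribution is summarized by its
median, 95% percentile interval, and the probabilities of exceeding the
0/30/50/80% reduction thresholds of Red List criterion A3.

Coefficient draws are shared across subpopulations within a scope (one
global beta draw per replicate for approach 2, one per-ecoregion draw for
approach 3); ice-trend draws are per-subpopulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ice_metrics import IceTrend
from .relation_models import GLOBAL_SCOPE, RelationFit

#: Red List criterion A3 reduction thresholds (%)
THRESHOLDS = (0.0, 30.0, 50.0, 80.0)

CATEGORY_RULES = (
    ("critically-endangered", 80.0),
    ("endangered", 50.0),
    ("vulnerable", 30.0),
)


def three_generation_horizon(gl: float) -> int:
    """Assessment horizon in years: 3 x GL, rounded half up."""
    return int(math.floor(3.0 * gl + 0.5))


@dataclass(frozen=True)
class Scenario:
    approach: int
    gl: float
    n_sims: int = 62_500
    seed: int = 0
    start_year: int = 2015

    def __post_init__(self):
        if self.approach not in (1, 2, 3):
            raise ValueError("approach must be 1, 2 or 3")
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        if self.gl <= 0:
            raise ValueError("gl must be positive")

    @property
    def horizon(self) -> int:
        return three_generation_horizon(self.gl)


@dataclass(frozen=True)
class ProjectionSummary:
    scenario: Scenario
    median_change: float   # % change in MGPS
    ci_low: float          # 2.5th percentile, %
    ci_high: float         # 97.5th percentile, %
    p_decline_0: float
    p_decline_30: float
    p_decline_50: float
    p_decline_80: float

    def __post_init__(self):
        probs = (self.p_decline_0, self.p_decline_30,
                 self.p_decline_50, self.p_decline_80)
        if any(np.diff(probs) > 1e-12):
            raise ValueError("threshold probabilities must be non-increasing")
        if not (self.ci_low <= self.median_change + 1e-9
                and self.median_change - 1e-9 <= self.ci_high):
            raise ValueError("95% interval must bracket the median")

    @property
    def probabilities(self) -> dict[float, float]:
        return dict(zip(THRESHOLDS, (self.p_decline_0, self.p_decline_30,
                                     self.p_decline_50, self.p_decline_80)))


@dataclass(frozen=True)
class RedListResult:
    category: str
    rule: str
    tolerance: float


def simulate_coefficients(
    fit: RelationFit | IceTrend, n_sims: int, seed: int | np.random.Generator
):
    """Draw coefficients from the estimated sampling distribution.

    For a RelationFit: returns an array of beta draws ~ N(beta, beta_se).
    For an IceTrend: returns (slope_draws, intercept_draws) drawn jointly;
    the slope and the level at the mean observation year are independent in
    the centred OLS parametrization, which induces the slope-intercept
    covariance on the calendar scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(fit, RelationFit):
        return rng.normal(fit.beta, fit.beta_se, size=n_sims)
    if isinstance(fit, IceTrend):
        slope = rng.normal(fit.slope, fit.slope_se, size=n_sims)
        level = fit.intercept + fit.slope * fit.mean_year
        level_se = (fit.residual_sd / np.sqrt(fit.n_years) if fit.n_years > 0
                    else np.sqrt(max(fit.intercept_se ** 2
                                     - fit.mean_year ** 2 * fit.slope_se ** 2, 0.0)))
        level_draw = rng.normal(level, level_se, size=n_sims)
        intercept = level_draw - slope * fit.mean_year
        return slope, intercept
    raise TypeError(f"cannot simulate coefficients for {type(fit).__name__}")


def project_subpopulation(
    scenario: Scenario,
    beta_draws: np.ndarray | None = None,
    trend_draws: tuple[np.ndarray, np.ndarray] | None = None,
    trend: IceTrend | None = None,
) -> np.ndarray:
    """Terminal proportional change in N per replicate, floored at -1.

    Approaches 2-3: change = exp(beta * slope * horizon) - 1, the annual
    log-change beta * d_ice compounded over the horizon; slope draws come
    from the subpopulation's ice trend.  Approach 1: the ratio of projected
    ice (clamped to [0, 366] days) at the horizon end to the start, minus 1,
    under the drawn trend line.
    """
    h = scenario.horizon
    if scenario.approach == 1:
        if trend_draws is None:
            raise ValueError("approach 1 requires joint trend draws")
        slope, intercept = trend_draws
        i0 = np.clip(intercept + slope * scenario.start_year, 0.0, 366.0)
        i1 = np.clip(intercept + slope * (scenario.start_year + h), 0.0, 366.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = np.where(i0 > 0, i1 / i0 - 1.0, 0.0)
    else:
        if beta_draws is None:
            raise ValueError("approaches 2-3 require beta draws")
        if trend_draws is not None:
            slope = trend_draws[0]
        elif trend is not None:
            slope = trend.slope
        else:
            raise ValueError("approaches 2-3 require ice-trend slope draws")
        change = np.exp(beta_draws * slope * h) - 1.0
    return np.maximum(change, -1.0)


def aggregate_mgps(
    changes: Mapping[str, np.ndarray | float], weights: Mapping[str, float]
) -> np.ndarray:
    """Per cent change in MGPS: the abundance-weighted mean of changes x 100."""
    if set(changes) != set(weights):
        raise ValueError(
            f"subpopulation sets differ: changes {sorted(changes)} vs "
            f"weights {sorted(weights)}"
        )
    if any(w <= 0 for w in weights.values()):
        raise ValueError("weights must be positive")
    subs = sorted(changes)
    w = np.array([weights[s] for s in subs])
    c = np.vstack([np.atleast_1d(np.asarray(changes[s], dtype=float)) for s in subs])
    return 100.0 * (w @ c) / w.sum()


def summarize_changes(scenario: Scenario, mgps_changes: np.ndarray) -> ProjectionSummary:
    """Summarize a replicate vector of % MGPS changes.

    Reduction = -change; p_decline_k is the fraction of replicates with
    reduction >= k per cent.
    """
    mgps_changes = np.asarray(mgps_changes, dtype=float)
    med = float(np.median(mgps_changes))
    lo, hi = np.percentile(mgps_changes, [2.5, 97.5])
    reduction = -mgps_changes
    probs = [float(np.mean(reduction >= t)) for t in THRESHOLDS]
    return ProjectionSummary(scenario, med, float(lo), float(hi), *probs)


def run_scenario(
    scenario: Scenario,
    trends: Mapping[str, IceTrend],
    weights: Mapping[str, float],
    fits: Mapping[str, RelationFit] | None = None,
    ecoregions: Mapping[str, str] | None = None,
) -> ProjectionSummary:
    """Monte Carlo projection of MGPS change for one scenario.

    ``trends``/``weights`` are keyed by subpopulation (the analysis set; any
    exclusions are applied by the caller).  For approach 2 ``fits`` must hold
    the global fit under scope "global"; for approach 3, one fit per
    ecoregion, with ``ecoregions`` mapping subpopulation -> ecoregion.
    Subpopulations without a dedicated fit inherit their scope's fit.
    """
    subs = sorted(weights)
    missing = [s for s in subs if s not in trends]
    if missing:
        raise ValueError(f"missing ice trends for subpopulations: {missing}")
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_sims

    beta_by_scope: dict[str, np.ndarray] = {}
    if scenario.approach == 2:
        if not fits or GLOBAL_SCOPE not in fits:
            raise ValueError("approach 2 requires a global relation fit")
        beta_by_scope[GLOBAL_SCOPE] = simulate_coefficients(fits[GLOBAL_SCOPE], n, rng)
    elif scenario.approach == 3:
        if not fits or ecoregions is None:
            raise ValueError("approach 3 requires per-ecoregion fits and an "
                             "ecoregion mapping")
        for eco in sorted({ecoregions[s] for s in subs}):
            if eco not in fits:
                raise ValueError(f"no relation fit for ecoregion {eco!r}")
            beta_by_scope[eco] = simulate_coefficients(fits[eco], n, rng)

    changes: dict[str, np.ndarray] = {}
    for s in subs:
        trend_draws = simulate_coefficients(trends[s], n, rng)
        if scenario.approach == 1:
            changes[s] = project_subpopulation(scenario, trend_draws=trend_draws)
        else:
            scope = GLOBAL_SCOPE if scenario.approach == 2 else ecoregions[s]
            changes[s] = project_subpopulation(
                scenario, beta_draws=beta_by_scope[scope], trend_draws=trend_draws
            )
    mgps = aggregate_mgps(changes, weights)
    return summarize_changes(scenario, mgps)


def summarize_scenarios(summaries: Sequence[ProjectionSummary]) -> dict:
    """Cross-scenario median/min/max per reduction threshold and for the median change."""
    if len(summaries) == 0:
        raise ValueError("no scenario summaries")
    out: dict = {"n_scenarios": len(summaries), "thresholds": {}}
    for t in THRESHOLDS:
        vals = np.array([s.probabilities[t] for s in summaries])
        out["thresholds"][t] = {
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    med = np.array([s.median_change for s in summaries])
    out["median_change"] = {
        "median": float(np.median(med)),
        "min": float(med.min()),
        "max": float(med.max()),
    }
    return out


def red_list_category(
    probabilities: Mapping[float, float] | ProjectionSummary | dict,
    tolerance: float = 0.5,
) -> RedListResult:
    """Red List criterion A3 category from reduction-threshold probabilities.

    Returns the highest category (CR >= 80%, EN >= 50%, VU >= 30%) whose
    reduction probability meets the risk tolerance; otherwise the taxon does
    not qualify as threatened under A3.
    """
    if isinstance(probabilities, ProjectionSummary):
        probs = probabilities.probabilities
    elif "thresholds" in probabilities:
        probs = {t: v["median"] for t, v in probabilities["thresholds"].items()}
    else:
        probs = {float(k): float(v) for k, v in probabilities.items()}
    needed = [t for _, t in CATEGORY_RULES]
    if any(t not in probs for t in needed):
        raise ValueError(f"need probabilities at thresholds {needed}")
    seq = [probs[t] for t in sorted(probs)]
    if any(np.diff(seq) > 1e-12):
        raise ValueError("threshold probabilities must be non-increasing in the threshold")
    for category, t in CATEGORY_RULES:
        if probs[t] >= tolerance:
            return RedListResult(
                category=category,
                rule=f"P(reduction >= {t:.0f}%) = {probs[t]:.3f} >= tolerance",
                tolerance=tolerance,
            )
    return RedListResult(
        category="least-concern-range",
        rule=f"no reduction threshold probability reaches tolerance {tolerance}",
        tolerance=tolerance,
    )
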