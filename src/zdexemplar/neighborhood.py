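"""Baseline-matched "neighborhood" comparisons.

A target country (in the study: the Gavi Learning Hub countries Nigeria,
Mali, Uganda and Bangladesh) is paired with the candidate exemplar whose
no-DTP measures at the baseline year are closest, and the two entities'
trajectories are compared through the end year.  Distance can be measured on
national prevalence alone, on the subnational gap alone, or jointly in the
(national, gap) plane (Euclidean, optionally standardized by the pool's
per-axis standard deviations).  Entities are any identifiers carried by the
metrics table, so the same operations apply unchanged to admin-1 aggregates
within one country.

"Different trajectories" is quantified descriptively as the end-year
difference vector (matched minus target); no statistical test is attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import DIM_GAP, DIM_NATIONAL

logger = logging.getLogger(__name__)

DIM_JOINT = "joint"


@dataclass(frozen=True)
class NeighborMatch:
    """A baseline pairing between a target and its nearest candidate."""

    target: str
    matched_entity: str
    baseline_year: int
    match_dimension: str
    distance: float
    divergence_end: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matched_entity == self.target:
            raise ValueError("an entity cannot be matched to itself")
        if self.distance < 0:
            raise ValueError("distance must be nonnegative")


def entity_metrics_at(metrics: pd.DataFrame, year: int) -> pd.DataFrame:
    """(national, gap) per entity at one year, indexed by entity code."""
    sub = metrics[metrics["year"] == year]
    if sub.empty:
        raise ValueError(f"no metrics for year {year}")
    out = sub.set_index("country_code")[["national_no_dtp", "gap"]]
    return out.rename(columns={"national_no_dtp": "national"})


def baseline_distance(
    a: pd.Series,
    b: pd.Series,
    dimension: str = DIM_JOINT,
    scale: tuple[float, float] | None = None,
) -> float:
    """Distance between two entities' baseline (national, gap) measures.

    Single dimensions use |difference| in percentage points; ``joint`` uses
    Euclidean distance in the (national, gap) plane, with each axis divided
    by the corresponding entry of ``scale`` when given (typically the
    candidate pool's standard deviations).
    """
    for s in (a, b):
        if pd.isna(s.get("national")) or pd.isna(s.get("gap")):
            raise ValueError("entity is missing baseline metrics")
    if dimension == DIM_NATIONAL:
        return float(abs(a["national"] - b["national"]))
    if dimension == DIM_GAP:
        return float(abs(a["gap"] - b["gap"]))
    if dimension == DIM_JOINT:
        sn, sg = scale if scale is not None else (1.0, 1.0)
        if sn <= 0 or sg <= 0:
            raise ValueError("scale factors must be positive")
        dn = (a["national"] - b["national"]) / sn
        dg = (a["gap"] - b["gap"]) / sg
        return float(np.hypot(dn, dg))
    raise ValueError(f"unknown match dimension {dimension!r}")


def match_neighbor(
    target: str,
    baseline: pd.DataFrame,
    pool: list[str],
    baseline_year: int,
    dimension: str = DIM_JOINT,
    standardize: bool = True,
    end: pd.DataFrame | None = None,
) -> NeighborMatch:
    """Nearest candidate to ``target`` at the baseline year.

    Parameters
    ----------
    baseline
        Per-entity (national, gap) table at the baseline year, as produced by
        :func:`entity_metrics_at`.
    pool
        Candidate entity codes; the target is removed if present.  Ties in
        distance are broken alphabetically, and pool order never matters.
    standardize
        For ``joint`` only: divide each axis by the standard deviation over
        the pool plus the target, making the match invariant to rescaling
        either axis by a common positive factor.
    end
        Optional per-entity table at the end year; when given, the end-year
        differences (matched - target) populate ``divergence_end``.
    """
    candidates = sorted(c for c in pool if c != target)
    if not candidates:
        raise ValueError("candidate pool is empty (after removing the target)")
    missing = [c for c in candidates + [target] if c not in baseline.index]
    if missing:
        raise ValueError(f"entities missing baseline metrics: {missing}")
    scale = None
    if dimension == DIM_JOINT and standardize:
        ref = baseline.loc[candidates + [target]]
        scale = (float(ref["national"].std(ddof=1)), float(ref["gap"].std(ddof=1)))
    t = baseline.loc[target]
    dists = {c: baseline_distance(t, baseline.loc[c], dimension, scale) for c in candidates}
    best = min(candidates, key=lambda c: (dists[c], c))
    divergence: dict[str, float] = {}
    if end is not None and target in end.index and best in end.index:
        divergence = {
            DIM_NATIONAL: float(end.loc[best, "national"] - end.loc[target, "national"]),
            DIM_GAP: float(end.loc[best, "gap"] - end.loc[target, "gap"]),
        }
    return NeighborMatch(
        target=target,
        matched_entity=best,
        baseline_year=baseline_year,
        match_dimension=dimension,
        distance=dists[best],
        divergence_end=divergence,
    )


def divergence_report(
    metrics: pd.DataFrame,
    target: str,
    matched: str,
    year_start: int,
    year_end: int,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Paired per-year metric series for a match, plus end-year differences.

    Works on any year coverage shared by both entities (endpoint-only
    fixtures included), but both entities must cover the two endpoint years.
    """
    cols = ["country_code", "year", "national_no_dtp", "gap"]
    sub = metrics[metrics["country_code"].isin([target, matched])][cols]
    wide = sub.pivot(index="year", columns="country_code", values=["national_no_dtp", "gap"])
    years = wide.dropna().index
    years = years[(years >= year_start) & (years <= year_end)]
    if year_start not in years or year_end not in years:
        raise ValueError(
            f"{target} and {matched} do not share coverage of both {year_start} and {year_end}"
        )
    table = pd.DataFrame(
        {
            "year": years,
            "target_national": wide.loc[years, ("national_no_dtp", target)].to_numpy(),
            "match_national": wide.loc[years, ("national_no_dtp", matched)].to_numpy(),
            "target_gap": wide.loc[years, ("gap", target)].to_numpy(),
            "match_gap": wide.loc[years, ("gap", matched)].to_numpy(),
        }
    )
    last = table[table["year"] == year_end].iloc[0]
    deltas = {
        DIM_NATIONAL: float(last["match_national"] - last["target_national"]),
        DIM_GAP: float(last["match_gap"] - last["target_gap"]),
    }
    return table.reset_index(drop=True), deltas


#: per-target match dimension reproducing the study's published pairings
LEARNING_HUB_PLAN: tuple[tuple[str, str], ...] = (
    ("NGA", DIM_JOINT),
    ("MLI", DIM_GAP),
    ("UGA", DIM_NATIONAL),
)


def match_learning_hubs(
    baseline: pd.DataFrame,
    pool: list[str],
    baseline_year: int = 2000,
    plan: tuple[tuple[str, str], ...] = LEARNING_HUB_PLAN,
    end: pd.DataFrame | None = None,
) -> list[NeighborMatch]:
    """Sequentially match target countries to exemplars without replacement.

    Targets are processed in ``plan`` order and each claimed exemplar leaves
    the pool, so every target receives a distinct neighbor.  With the default
    plan and the five study exemplars this reproduces the published pairings:
    Nigeria pairs with Ethiopia in the joint (national, gap) plane, Mali with
    the DRC on subnational gaps among the remaining candidates, and Uganda
    with Burundi on national prevalence.  The joint match here is
    unstandardized so the pairing does not depend on how the pool shrinks.
    """
    remaining = list(pool)
    matches = []
    for target, dimension in plan:
        m = match_neighbor(
            target,
            baseline,
            remaining,
            baseline_year,
            dimension=dimension,
            standardize=False,
            end=end,
        )
        matches.append(m)
        remaining = [c for c in remaining if c != m.matched_entity]
    return matches


def matches_to_frame(matches: list[NeighborMatch]) -> pd.DataFrame:
    rows = [
        {
            "target": m.target,
            "matched_entity": m.matched_entity,
            "baseline_year": m.baseline_year,
            "match_dimension": m.match_dimension,
            "distance": m.distance,
            "divergence_end_national": m.divergence_end.get(DIM_NATIONAL, np.nan),
            "divergence_end_gap": m.divergence_end.get(DIM_GAP, np.nan),
        }
        for m in matches
    ]
    return pd.DataFrame(rows)
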