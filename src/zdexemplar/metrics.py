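"""Equity metrics for zero-dose (no-DTP) prevalence.

Two metrics summarise a country-year:

* **national no-DTP prevalence** — either supplied externally (the study used
  modelled national estimates), or aggregated from admin-2 units as a
  population-weighted or unweighted mean;
* **subnational gap** — the difference between the 95th and 5th percentile of
  no-DTP prevalence across the country's admin-2 units, in percentage points.
  Percentiles (rather than min/max) damp the influence of single outlier
  units and of widely varying unit counts.

Quantiles use linear interpolation between order statistics (Hyndman-Fan
type 7, the numpy default); the rule is pinned so results are reproducible.
Change metrics follow the end-minus-start sign convention: reductions are
negative.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NO_DTP_COL, StudyFixture

logger = logging.getLogger(__name__)

DIM_NATIONAL = "national"
DIM_GAP = "subnational_gap"

CAT_BOTH_REDUCED = "both_reduced"
CAT_NATIONAL_ONLY = "national_only_reduced"
CAT_GAP_ONLY = "gap_only_reduced"
CAT_BOTH_INCREASED = "both_increased"
CATEGORIES = [CAT_BOTH_REDUCED, CAT_NATIONAL_ONLY, CAT_GAP_ONLY, CAT_BOTH_INCREASED]


def subnational_gap(
    values: Sequence[float] | np.ndarray,
    lower: float = 0.05,
    upper: float = 0.95,
) -> tuple[float, float, float]:
    """Return (p_lower, p_upper, gap) of no-DTP prevalence across units.

    ``gap = p_upper - p_lower`` in percentage points; permutation-invariant;
    zero for constant input.  A single-unit country has a well-defined gap of
    zero (logged, since it carries no inequality information).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("subnational_gap requires at least one unit value")
    if np.isnan(arr).any():
        raise ValueError("subnational_gap input contains NaN")
    if not (0.0 <= lower < upper <= 1.0):
        raise ValueError(f"need 0 <= lower < upper <= 1, got ({lower}, {upper})")
    if arr.size == 1:
        logger.debug("single-unit country: gap defined as 0")
    lo, hi = np.quantile(arr, [lower, upper], method="linear")
    return float(lo), float(hi), float(hi - lo)


def gap_series(
    panel: pd.DataFrame,
    lower: float = 0.05,
    upper: float = 0.95,
    by: Sequence[str] = ("country_code", "year"),
) -> pd.DataFrame:
    """Per-entity-year percentile endpoints and gap across admin-2 units."""
    def _one(g: pd.Series) -> pd.Series:
        lo, hi, gap = subnational_gap(g.to_numpy(), lower, upper)
        return pd.Series({"p5": lo, "p95": hi, "gap": gap})

    out = panel.groupby(list(by))[NO_DTP_COL].apply(_one).unstack().reset_index()
    return out


def national_series(
    panel: pd.DataFrame,
    mode: str = "unweighted_mean",
    national_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """National no-DTP prevalence per country-year.

    ``mode='provided'`` passes through an external national table
    (columns country_code, year, national_no_dtp), as the study did with
    modelled national estimates; ``'pop_weighted'`` computes
    sum(pop * no_dtp) / sum(pop) over admin-2 units; ``'unweighted_mean'``
    averages units equally.
    """
    if mode == "provided":
        if national_table is None:
            raise ValueError("mode='provided' requires national_table")
        required = {"country_code", "year", "national_no_dtp"}
        if not required.issubset(national_table.columns):
            raise ValueError(f"national_table needs columns {sorted(required)}")
        covered = panel[["country_code", "year"]].drop_duplicates()
        merged = covered.merge(national_table, on=["country_code", "year"], how="left")
        if merged["national_no_dtp"].isna().any():
            missing = merged[merged["national_no_dtp"].isna()]
            raise ValueError(
                "national_table missing country-years: "
                f"{missing[['country_code', 'year']].to_records(index=False).tolist()[:10]}"
            )
        return merged
    if mode == "pop_weighted":
        if "population" not in panel.columns or panel["population"].isna().any():
            raise ValueError("mode='pop_weighted' requires a complete population column")

        def _w(g: pd.DataFrame) -> float:
            tot = g["population"].sum()
            if tot <= 0:
                raise ValueError("zero total population in a country-year")
            return float(np.average(g[NO_DTP_COL], weights=g["population"]))

        out = (
            panel.groupby(["country_code", "year"])
            .apply(_w, include_groups=False)
            .rename("national_no_dtp")
            .reset_index()
        )
        return out
    if mode == "unweighted_mean":
        out = (
            panel.groupby(["country_code", "year"])[NO_DTP_COL]
            .mean()
            .rename("national_no_dtp")
            .reset_index()
        )
        return out
    raise ValueError(f"unknown national aggregation mode: {mode!r}")


def country_year_metrics(
    panel: pd.DataFrame,
    mode: str = "unweighted_mean",
    national_table: pd.DataFrame | None = None,
    lower: float = 0.05,
    upper: float = 0.95,
) -> pd.DataFrame:
    """Combined per-country-year table: national level, p5, p95, gap."""
    nat = national_series(panel, mode=mode, national_table=national_table)
    gaps = gap_series(panel, lower=lower, upper=upper)
    return nat.merge(gaps, on=["country_code", "year"], how="inner")


def fixture_metrics(fixture: StudyFixture) -> pd.DataFrame:
    """Reshape the published endpoint-year fixture into the metrics layout.

    Produces the same (country_code, year, national_no_dtp, p5, p95, gap)
    table the pipeline computes from a full panel, restricted to the two
    published years; percentile endpoints are only available for the five
    exemplar countries.
    """
    rows = []
    for _, r in fixture.levels.iterrows():
        for year in (2000, 2019):
            rows.append(
                {
                    "country_code": r["country_code"],
                    "year": year,
                    "national_no_dtp": r[f"national_{year}"],
                    "gap": r[f"gap_{year}"],
                }
            )
    metrics = pd.DataFrame(rows)
    metrics = metrics.merge(fixture.percentiles, on=["country_code", "year"], how="left")
    return metrics[["country_code", "year", "national_no_dtp", "p5", "p95", "gap"]]


def change_metrics(
    metrics: pd.DataFrame,
    year_start: int = 2000,
    year_end: int = 2019,
) -> pd.DataFrame:
    """Absolute (pp) and relative (%) change per country and dimension.

    One record per country x {national, subnational_gap}.  Sign convention:
    change = end - start, so reductions are negative.  Relative change is
    (end - start) / start * 100 and is undefined (NaN, flagged) when the
    start value is zero.  Countries missing either endpoint year are dropped
    with a logged error entry; others proceed.
    """
    records = []
    for code, g in metrics.groupby("country_code"):
        g = g.set_index("year")
        if year_start not in g.index or year_end not in g.index:
            logger.error("country %s missing endpoint year(s); skipped", code)
            continue
        for dim, col in ((DIM_NATIONAL, "national_no_dtp"), (DIM_GAP, "gap")):
            start = float(g.loc[year_start, col])
            end = float(g.loc[year_end, col])
            abs_change = end - start
            rel_change = (end - start) / start * 100.0 if start > 0 else np.nan
            if start == 0:
                logger.warning("country %s %s starts at 0; relative change undefined", code, dim)
            records.append(
                {
                    "country_code": code,
                    "dimension": dim,
                    "value_start": start,
                    "value_end": end,
                    "absolute_change": abs_change,
                    "relative_change": rel_change,
                }
            )
    if not records:
        raise ValueError("no country had both endpoint years")
    return pd.DataFrame(records)


def classify_progress(changes: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Four-way progress classification from absolute changes.

    A country is in ``both_reduced`` iff both its national level and its
    subnational gap strictly decreased between the endpoint years (zero
    change counts as "not reduced").  Returns (per-country categories,
    category counts).  Countries missing either dimension are excluded with
    a warning.
    """
    wide = changes.pivot(index="country_code", columns="dimension", values="absolute_change")
    incomplete = wide[wide.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("excluded from classification (missing dimension): %s", list(incomplete.index))
        wide = wide.dropna()
    nat_red = wide[DIM_NATIONAL] < 0
    gap_red = wide[DIM_GAP] < 0
    category = pd.Series(CAT_BOTH_INCREASED, index=wide.index, name="category")
    category[nat_red & gap_red] = CAT_BOTH_REDUCED
    category[nat_red & ~gap_red] = CAT_NATIONAL_ONLY
    category[~nat_red & gap_red] = CAT_GAP_ONLY
    quadrants = category.reset_index()
    counts = category.value_counts().reindex(CATEGORIES, fill_value=0)
    return quadrants, counts


def units_gap_correlation(
    panel: pd.DataFrame,
    year: int,
    lower: float = 0.05,
    upper: float = 0.95,
) -> tuple[float, bool]:
    """Pearson r between per-country admin-2 unit counts and gaps in a year.

    Used to probe whether countries carved into more units mechanically show
    wider percentile gaps.  Returns (r, defined); ``defined`` is False (and r
    NaN) when either variable has zero variance or fewer than 3 countries
    are available.
    """
    sub = panel[panel["year"] == year]
    if sub.empty:
        raise ValueError(f"no panel rows for year {year}")
    counts = sub.groupby("country_code")["admin2_id"].nunique()
    gaps = gap_series(sub, lower=lower, upper=upper).set_index("country_code")["gap"]
    aligned = pd.concat([counts.rename("n_units"), gaps], axis=1).dropna()
    if len(aligned) < 3:
        raise ValueError("units_gap_correlation needs at least 3 countries")
    if aligned["n_units"].nunique() == 1 or aligned["gap"].nunique() == 1:
        logger.warning("zero variance in unit counts or gaps; correlation undefined")
        return float("nan"), False
    r, _ = stats.pearsonr(aligned["n_units"], aligned["gap"])
    return float(r), True


def reconcile_fixture_changes(fixture: StudyFixture, tol_pp: float = 0.15) -> pd.DataFrame:
    """Cross-check printed change columns against changes recomputed from levels.

    The published change columns were derived from unrounded source values,
    so recomputation from rounded levels can differ by up to ~0.1 pp.
    Returns a per-country report; raises if any absolute change disagrees by
    more than ``tol_pp`` or any printed/recomputed change pair disagrees in
    sign.
    """
    lv = fixture.levels
    rep = pd.DataFrame({"country_code": lv["country_code"]})
    for dim, pre in ((DIM_NATIONAL, "national"), (DIM_GAP, "gap")):
        recomputed = lv[f"{pre}_2019"] - lv[f"{pre}_2000"]
        printed = lv[f"{pre}_change_pp"]
        rep[f"{pre}_printed_pp"] = printed
        rep[f"{pre}_recomputed_pp"] = recomputed
        if (np.abs(recomputed - printed) > tol_pp).any():
            bad = lv.loc[np.abs(recomputed - printed) > tol_pp, "country_code"]
            raise ValueError(f"absolute-change reconciliation failure for {list(bad)}")
        if (np.sign(recomputed) != np.sign(printed)).any():
            bad = lv.loc[np.sign(recomputed) != np.sign(printed), "country_code"]
            raise ValueError(f"sign disagreement for {list(bad)}")
    return rep
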