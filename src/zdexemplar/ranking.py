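"""Dual-track positive-outlier ranking of countries.

Each country is ranked ordinally (1..N) on its change in national no-DTP
prevalence and, separately, on its change in the subnational percentile gap,
with rank 1 the largest reduction (most negative change) and rank N the
smallest reduction or largest increase.  The mean of the two ranks scores
overall progress across both geographic dimensions; the countries with the
smallest mean rank are the candidate exemplars.  The procedure runs once on
absolute changes (percentage points) and once on relative changes (percent),
since large absolute and large relative reductions reflect different starting
points and programme stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .metrics import DIM_GAP, DIM_NATIONAL

logger = logging.getLogger(__name__)

TRACK_ABSOLUTE = "absolute"
TRACK_RELATIVE = "relative"
_TRACK_COLUMN = {TRACK_ABSOLUTE: "absolute_change", TRACK_RELATIVE: "relative_change"}
_TIE_METHOD = {"average": "average", "competition": "min"}


def rank_dimension(
    changes: pd.DataFrame,
    dimension: str,
    track: str = TRACK_ABSOLUTE,
    tie_policy: str = "average",
) -> pd.Series:
    """Ordinal ranks for one dimension and track, indexed by country.

    Most negative change -> rank 1.  Ties share the average rank under the
    default policy (keeps the rank-column sum at N(N+1)/2); competition
    ranking ("min") is available.  On the relative track, countries whose
    relative change is undefined (zero start value) are excluded and logged.
    """
    col = _TRACK_COLUMN[track]
    sub = changes[changes["dimension"] == dimension]
    if sub.empty:
        raise ValueError(f"no change records for dimension {dimension!r}")
    if sub["country_code"].duplicated().any():
        raise ValueError("multiple change records per country for one dimension")
    values = sub.set_index("country_code")[col]
    undefined = values[values.isna()]
    if len(undefined):
        if track != TRACK_RELATIVE:
            raise ValueError(f"NaN changes on the {track} track: {list(undefined.index)}")
        logger.info(
            "relative track: excluded %s (undefined relative change)", list(undefined.index)
        )
        values = values.dropna()
    if values.empty:
        raise ValueError("no rankable countries after exclusions")
    ranks = rankdata(values.to_numpy(), method=_TIE_METHOD[tie_policy])
    return pd.Series(ranks, index=values.index, name=f"rank_{dimension}")


def mean_rank(rank_national: pd.Series, rank_gap: pd.Series) -> pd.Series:
    """Arithmetic mean of the two dimension ranks (equal weighting).

    Countries missing either rank are excluded with a warning.
    """
    joined = pd.concat([rank_national, rank_gap], axis=1)
    incomplete = joined[joined.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("mean_rank: excluded %s (missing a dimension rank)", list(incomplete.index))
        joined = joined.dropna()
    return joined.mean(axis=1).rename("mean_rank")


def ranking_table(
    changes: pd.DataFrame,
    track: str = TRACK_ABSOLUTE,
    tie_policy: str = "average",
) -> pd.DataFrame:
    """Full per-track ranking table: both dimension ranks plus mean rank.

    Also carries the national change value on the track, used for
    deterministic tie-breaking in exemplar selection.
    """
    r_nat = rank_dimension(changes, DIM_NATIONAL, track, tie_policy)
    r_gap = rank_dimension(changes, DIM_GAP, track, tie_policy)
    score = mean_rank(r_nat, r_gap)
    nat_change = (
        changes[changes["dimension"] == DIM_NATIONAL]
        .set_index("country_code")["absolute_change"]
        .rename("national_abs_change")
    )
    table = pd.concat([r_nat, r_gap, score, nat_change], axis=1).dropna(subset=["mean_rank"])
    table.index.name = "country_code"
    table["track"] = track
    return table.sort_values(["mean_rank", "national_abs_change", "country_code"]).reset_index()


def select_exemplars(table: pd.DataFrame, k: int) -> list[str]:
    """The k countries with the smallest mean rank on a track.

    Mean-rank ties are broken deterministically: larger national absolute
    reduction first (more negative change), then alphabetically by country
    code.  ``ranking_table`` already sorts by exactly this key.
    """
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} ranked countries")
    ordered = table.sort_values(["mean_rank", "national_abs_change", "country_code"])
    chosen = ordered.head(k)
    tied_at_cut = ordered["mean_rank"].iloc[k - 1 : k + 1] if k < len(ordered) else None
    if tied_at_cut is not None and tied_at_cut.nunique() == 1:
        logger.info("mean-rank tie at the selection boundary broken by national reduction, then name")
    return list(chosen["country_code"])


def dual_track_exemplars(
    changes: pd.DataFrame,
    k_absolute: int = 3,
    k_relative: int = 2,
    tie_policy: str = "average",
) -> dict[str, dict]:
    """Run both tracks end to end.

    Defaults mirror the study design: the top 3 on the absolute track and the
    top 2 on the relative track are flagged as candidate exemplars.
    """
    out: dict[str, dict] = {}
    for track, k in ((TRACK_ABSOLUTE, k_absolute), (TRACK_RELATIVE, k_relative)):
        table = ranking_table(changes, track=track, tie_policy=tie_policy)
        exemplars = select_exemplars(table, k)
        table["exemplar"] = table["country_code"].isin(exemplars)
        out[track] = {"table": table, "exemplars": exemplars}
    return out
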