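"""Reading, validating and writing subnational coverage panels.

The pipeline's raw input is a long ("tidy") table of DTP1 coverage estimates
(% of under-one children who received a first dose of the diphtheria-tetanus-
pertussis vaccine) by country, admin-1 unit, admin-2 unit and year, optionally
with unit populations.  Internally everything is a pandas DataFrame on the
percent scale (0-100).  The zero-dose indicator used throughout the analysis
is *no-DTP prevalence*: 100 minus DTP1 coverage.

The module also exposes the bundled study fixture: national no-DTP levels and
5th-95th percentile subnational gaps in 2000 and 2019 for the 56 low- and
lower-middle-income countries of the study, the printed change columns, and
the published percentile endpoints for the five exemplar countries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for a coverage panel
PANEL_COLUMNS = ["country_code", "admin1_id", "admin2_id", "year", "dtp1_coverage"]
#: key that must be unique per panel row
PANEL_KEY = ["country_code", "admin2_id", "year"]

COVERAGE_COL = "dtp1_coverage"
NO_DTP_COL = "no_dtp"


class SchemaError(ValueError):
    """A required column cannot be resolved in the input table."""


class PanelValidationError(ValueError):
    """Panel rows violate a structural invariant (bounds, duplicate keys)."""

    def __init__(self, message: str, bad_rows: pd.DataFrame | None = None):
        super().__init__(message)
        self.bad_rows = bad_rows


def _value_column(panel: pd.DataFrame) -> str:
    if NO_DTP_COL in panel.columns:
        return NO_DTP_COL
    if COVERAGE_COL in panel.columns:
        return COVERAGE_COL
    raise SchemaError(
        f"panel has neither '{COVERAGE_COL}' nor '{NO_DTP_COL}' column"
    )


def validate_panel(panel: pd.DataFrame, allow_varying_units: bool = False) -> pd.DataFrame:
    """Validate a coverage or no-DTP panel in place and return it.

    Checks bounds ([0, 100]), key uniqueness, and (unless
    ``allow_varying_units``) that every country keeps the same admin-2 unit
    set across its covered years.  Offending rows are reported by index.
    """
    missing = [c for c in PANEL_KEY + ["admin1_id"] if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel missing required columns: {missing}")
    value_col = _value_column(panel)

    values = pd.to_numeric(panel[value_col], errors="coerce")
    out_of_bounds = panel[(values < 0) | (values > 100) | values.isna()]
    if len(out_of_bounds):
        raise PanelValidationError(
            f"{len(out_of_bounds)} row(s) with {value_col} outside [0, 100] "
            f"(row indices {list(out_of_bounds.index[:10])})",
            bad_rows=out_of_bounds,
        )

    dup = panel.duplicated(subset=PANEL_KEY, keep=False)
    if dup.any():
        raise PanelValidationError(
            f"duplicate (country, admin2, year) keys at row indices "
            f"{list(panel.index[dup][:10])}",
            bad_rows=panel[dup],
        )

    if "population" in panel.columns and (pd.to_numeric(panel["population"], errors="coerce") < 0).any():
        raise PanelValidationError("negative populations present")

    if not allow_varying_units:
        units_per_year = (
            panel.groupby(["country_code", "year"])["admin2_id"]
            .apply(frozenset)
            .groupby("country_code")
            .nunique()
        )
        varying = units_per_year[units_per_year > 1]
        if len(varying):
            raise PanelValidationError(
                f"admin-2 unit set varies across years for {list(varying.index)}; "
                "pass allow_varying_units=True to accept"
            )
    return panel


def read_panel(
    path: str | Path,
    schema: dict[str, str] | None = None,
    allow_varying_units: bool = False,
) -> pd.DataFrame:
    """Read a long-format coverage panel from a delimited text file.

    Parameters
    ----------
    path
        CSV file with one row per (country, admin-2 unit, year).
    schema
        Optional mapping from canonical column names (``country_code``,
        ``admin1_id``, ``admin2_id``, ``year``, ``dtp1_coverage``,
        ``population``) to the names actually used in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in df.columns}
        unresolved = [canon for canon, src in schema.items() if src not in df.columns]
        if unresolved:
            raise SchemaError(f"schema maps missing column(s): {unresolved}")
        df = df.rename(columns=rename)
    value_col = _value_column(df)
    keep = [c for c in PANEL_COLUMNS + ["population", NO_DTP_COL] if c in df.columns]
    missing = [c for c in PANEL_KEY + ["admin1_id"] if c not in df.columns]
    if missing:
        raise SchemaError(f"input {path.name} missing column(s): {missing}")
    df = df[keep].copy()
    df["year"] = df["year"].astype(int)
    df[value_col] = df[value_col].astype(float)
    if "population" not in df.columns:
        logger.info("panel %s has no population column; weighted options disabled", path.name)
    return validate_panel(df.reset_index(drop=True), allow_varying_units=allow_varying_units)


def write_panel(panel: pd.DataFrame, path: str | Path, precision: int = 1) -> Path:
    """Write a panel as CSV with fixed decimal precision for float columns."""
    return write_table(panel, path, precision=precision)


def write_table(df: pd.DataFrame, path: str | Path, precision: int = 1) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=f"%.{precision}f")
    return path


def to_no_dtp(panel: pd.DataFrame) -> pd.DataFrame:
    """Convert a DTP1-coverage panel to a no-DTP panel (and vice versa).

    no_dtp = 100 - dtp1_coverage, keys unchanged.  Applying the conversion
    twice returns the original panel (involution), so the same function maps
    a no-DTP panel back to coverage.
    """
    value_col = _value_column(panel)
    other = NO_DTP_COL if value_col == COVERAGE_COL else COVERAGE_COL
    out = panel.copy()
    out[other] = 100.0 - out[value_col]
    out = out.drop(columns=[value_col])
    # keep canonical column order with the value column where it was
    cols = [c if c != value_col else other for c in panel.columns]
    return out[cols]


# ---------------------------------------------------------------------------
# bundled study fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyFixture:
    """Published country-level no-DTP levels/changes and exemplar percentiles.

    ``levels`` has one row per country with national no-DTP prevalence and
    the subnational 5th-95th percentile gap in 2000 and 2019, the printed
    absolute (pp) and relative (%) change columns, and exemplar flags for the
    absolute and relative tracks.  ``percentiles`` holds the published 5th
    and 95th percentile endpoints for the five exemplar countries (the 2019
    endpoints for Bangladesh were not published and are stored as missing).
    """

    levels: pd.DataFrame
    percentiles: pd.DataFrame

    @property
    def countries(self) -> list[str]:
        return list(self.levels["country_code"])


def _read_bundled(name: str) -> pd.DataFrame:
    ref = resources.files("zdexemplar.data").joinpath(name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_study_fixture() -> StudyFixture:
    """Load the bundled 56-country study fixture."""
    levels = _read_bundled("country_levels.csv")
    percentiles = _read_bundled("exemplar_percentiles.csv")
    if len(levels) != 56:  # corrupted bundle guard
        raise RuntimeError(f"study fixture expected 56 countries, found {len(levels)}")
    for col in ("exemplar_absolute", "exemplar_relative"):
        levels[col] = levels[col].astype(bool)
    return StudyFixture(levels=levels, percentiles=percentiles)


def load_country_meta() -> pd.DataFrame:
    """Country metadata: income group, Gavi segmentation, Learning Hub flag."""
    meta = _read_bundled("country_meta.csv")
    meta["gavi_supported"] = meta["gavi_supported"].astype(bool)
    meta["learning_hub"] = meta["learning_hub"].astype(bool)
    if meta["country_code"].duplicated().any():
        raise RuntimeError("country metadata has duplicate country codes")
    return meta
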