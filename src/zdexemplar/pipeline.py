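"""End-to-end pipeline orchestration and plot-ready exports.

``run_pipeline`` drives the full analysis — ingest (file, bundled fixture, or
synthetic panel), equity metrics, change metrics, progress quadrants,
dual-track exemplar ranking, and neighborhood matching — and writes every
stage's table plus a run manifest (config digest, seed, package version, and
a content digest per output file).  Identical config and seed reproduce
byte-identical outputs.

Figure-oriented exports produce coordinates only (change-scatter points and
per-entity phase-plane trajectories); rendering is left to the caller.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .io import load_study_fixture, read_panel, to_no_dtp, write_table
from .metrics import (
    DIM_GAP,
    DIM_NATIONAL,
    change_metrics,
    classify_progress,
    country_year_metrics,
    fixture_metrics,
)
from .neighborhood import (
    LEARNING_HUB_PLAN,
    entity_metrics_at,
    match_learning_hubs,
    match_neighbor,
    matches_to_frame,
)
from .ranking import dual_track_exemplars
from .simulate import SyntheticSpec, generate_study

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "input": {"mode": "fixture"},
    "years": {"start": 2000, "end": 2019},
    "quantiles": {"lower": 0.05, "upper": 0.95},
    "ranking": {"k_absolute": 3, "k_relative": 2, "tie_policy": "average"},
    "output": {"precision": 4},
}


def _merged_config(config: dict) -> dict:
    if not config:
        raise ValueError("empty pipeline config")
    merged = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _config_digest(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_inputs(config: dict, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Resolve the configured input into a country-year metrics table.

    Returns (metrics, truth) where truth is the designed-truth table for
    synthetic inputs and None otherwise.
    """
    inp = config["input"]
    mode = inp.get("mode")
    years = config["years"]
    q = config["quantiles"]
    if mode == "fixture":
        metrics = fixture_metrics(load_study_fixture())
        logger.info("stage ingest: fixture mode, %d countries", metrics["country_code"].nunique())
        return metrics, None
    if mode == "synthetic":
        spec_kwargs = dict(inp.get("synthetic", {}))
        spec_kwargs.setdefault("year_start", years["start"])
        spec_kwargs.setdefault("year_end", years["end"])
        if seed is not None:
            spec_kwargs["seed"] = seed
        spec = SyntheticSpec(**spec_kwargs)
        panel, truth = generate_study(spec)
        panel = to_no_dtp(panel)
        metrics = country_year_metrics(
            panel,
            mode=inp.get("national_mode", "unweighted_mean"),
            lower=q["lower"],
            upper=q["upper"],
        )
        logger.info(
            "stage ingest: synthetic mode, %d countries x %d years",
            metrics["country_code"].nunique(),
            metrics["year"].nunique(),
        )
        return metrics, truth
    if mode == "panel":
        panel = read_panel(inp["path"], schema=inp.get("schema"))
        panel = to_no_dtp(panel)
        national_table = None
        if inp.get("national_table"):
            national_table = pd.read_csv(inp["national_table"])
        metrics = country_year_metrics(
            panel,
            mode=inp.get("national_mode", "unweighted_mean"),
            national_table=national_table,
            lower=q["lower"],
            upper=q["upper"],
        )
        logger.info("stage ingest: panel %s, %d countries", inp["path"], metrics["country_code"].nunique())
        return metrics, None
    raise ValueError(f"unknown input mode {mode!r}")


def export_change_scatter(
    changes: pd.DataFrame, quadrants: pd.DataFrame, metrics: pd.DataFrame, year_end: int
) -> pd.DataFrame:
    """Per-country change-scatter coordinates with quadrant category.

    One row per country: absolute national change (x), absolute gap change
    (y), the end-year national level (colour key), and the progress quadrant.
    """
    wide = changes.pivot(index="country_code", columns="dimension", values="absolute_change")
    wide = wide.rename(columns={DIM_NATIONAL: "national_abs_change", DIM_GAP: "gap_abs_change"})
    end_levels = (
        metrics[metrics["year"] == year_end]
        .set_index("country_code")["national_no_dtp"]
        .rename(f"national_{year_end}")
    )
    out = wide.join(end_levels).join(quadrants.set_index("country_code"))
    return out.reset_index().sort_values("country_code").reset_index(drop=True)


def export_phase_trajectories(
    metrics: pd.DataFrame, highlights: dict[str, str] | None = None
) -> pd.DataFrame:
    """Phase-plane trajectories: (national, gap) per entity-year, ordered.

    ``highlights`` maps entity codes to labels (e.g. "exemplar",
    "learning_hub"); unknown codes are warned about and ignored, everything
    else is labelled "other".
    """
    highlights = dict(highlights or {})
    known = set(metrics["country_code"])
    for code in list(highlights):
        if code not in known:
            logger.warning("highlight code %s not in metrics; ignored", code)
            highlights.pop(code)
    out = metrics[["country_code", "year", "national_no_dtp", "gap"]].copy()
    out = out.rename(columns={"country_code": "entity", "national_no_dtp": "national"})
    out["highlight"] = out["entity"].map(highlights).fillna("other")
    out = out.sort_values(["entity", "year"]).reset_index(drop=True)
    if out.duplicated(subset=["entity", "year"]).any():
        raise ValueError("multiple records per entity-year")
    return out


def _neighborhood_stage(
    config: dict, metrics: pd.DataFrame, exemplars: list[str]
) -> pd.DataFrame:
    nb = config.get("neighborhood")
    if nb is None:
        return pd.DataFrame()
    years = config["years"]
    baseline_year = nb.get("baseline", years["start"])
    end_year = nb.get("end", years["end"])
    baseline = entity_metrics_at(metrics, baseline_year)
    end = entity_metrics_at(metrics, end_year)
    pool = nb.get("pool", "exemplars")
    pool = exemplars if pool == "exemplars" else list(pool)
    targets = nb.get("targets", "learning_hubs")
    if targets == "learning_hubs":
        plan = tuple((t, d) for t, d in LEARNING_HUB_PLAN if t in baseline.index)
        matches = match_learning_hubs(baseline, pool, baseline_year, plan=plan, end=end)
    else:
        dimension = nb.get("dimension", "joint")
        matches = [
            match_neighbor(t, baseline, pool, baseline_year, dimension=dimension, end=end)
            for t in targets
        ]
    return matches_to_frame(matches)


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every analysis stage and write all outputs under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``): config digest,
    seed, package version, and a sha256 digest per output file.
    """
    config = _merged_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    years = config["years"]
    precision = config["output"]["precision"]

    metrics, truth = load_inputs(config, seed=seed)
    changes = change_metrics(metrics, years["start"], years["end"])
    quadrants, counts = classify_progress(changes)
    logger.info("stage classify: %s", counts.to_dict())

    rk = config["ranking"]
    tracks = dual_track_exemplars(
        changes,
        k_absolute=rk["k_absolute"],
        k_relative=rk["k_relative"],
        tie_policy=rk["tie_policy"],
    )
    exemplars = sorted(set(tracks["absolute"]["exemplars"]) | set(tracks["relative"]["exemplars"]))
    logger.info(
        "stage rank: absolute=%s relative=%s",
        tracks["absolute"]["exemplars"],
        tracks["relative"]["exemplars"],
    )

    matches = _neighborhood_stage(config, metrics, exemplars)

    highlights = dict(config.get("highlights", {}))
    for code in exemplars:
        highlights.setdefault(code, "exemplar")
    trajectories = export_phase_trajectories(metrics, highlights)
    scatter = export_change_scatter(changes, quadrants, metrics, years["end"])

    exemplar_rows = [
        {"track": track, "order": i + 1, "country_code": code}
        for track in ("absolute", "relative")
        for i, code in enumerate(tracks[track]["exemplars"])
    ]

    outputs = {
        "metrics.csv": metrics,
        "changes.csv": changes,
        "quadrants.csv": quadrants,
        "quadrant_counts.csv": counts.rename_axis("category").rename("n").reset_index(),
        "ranking_absolute.csv": tracks["absolute"]["table"],
        "ranking_relative.csv": tracks["relative"]["table"],
        "exemplars.csv": pd.DataFrame(exemplar_rows),
        "matches.csv": matches,
        "scatter.csv": scatter,
        "trajectories.csv": trajectories,
    }
    if truth is not None:
        outputs["truth.csv"] = truth

    digests = {}
    for name, df in outputs.items():
        path = write_table(df, out_dir / name, precision=precision)
        digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_digest": _config_digest(config),
        "config": config,
        "files": digests,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
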