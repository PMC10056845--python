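"""Export plot-ready coordinates for the change scatter and phase plane.

From the published fixture: (1) the per-country change scatter — absolute
national change vs absolute gap change, coloured by 2019 national level and
labelled with the progress quadrant; (2) endpoint phase-plane trajectories
(national level on x, subnational gap on y) with exemplars and Learning Hub
countries highlighted.  Coordinates go to results/figures/ as CSV; rendering
is intentionally left separate.
"""

from pathlib import Path

from zdexemplar.io import load_country_meta, load_study_fixture, write_table
from zdexemplar.metrics import change_metrics, classify_progress, fixture_metrics
from zdexemplar.pipeline import export_change_scatter, export_phase_trajectories
from zdexemplar.ranking import dual_track_exemplars

OUT = Path(__file__).resolve().parents[1] / "results" / "figures"


def main() -> None:
    metrics = fixture_metrics(load_study_fixture())
    changes = change_metrics(metrics, 2000, 2019)
    quadrants, _ = classify_progress(changes)

    scatter = export_change_scatter(changes, quadrants, metrics, 2019)
    write_table(scatter, OUT / "change_scatter.csv", precision=2)

    tracks = dual_track_exemplars(changes)
    exemplars = set(tracks["absolute"]["exemplars"]) | set(tracks["relative"]["exemplars"])
    meta = load_country_meta()
    hubs = set(meta[meta["learning_hub"]]["country_code"])
    highlights = {c: "exemplar" for c in exemplars}
    highlights.update({c: "learning_hub" for c in hubs - exemplars})
    trajectories = export_phase_trajectories(metrics, highlights)
    write_table(trajectories, OUT / "phase_trajectories.csv", precision=2)

    print(f"change scatter: {len(scatter)} countries -> {OUT / 'change_scatter.csv'}")
    print(
        f"phase trajectories: {trajectories['entity'].nunique()} entities, "
        f"highlighting {sorted(exemplars)} (exemplar) and "
        f"{sorted(hubs - exemplars)} (learning hub)"
    )


if __name__ == "__main__":
    main()
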