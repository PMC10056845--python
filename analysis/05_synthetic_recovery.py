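"""Validate exemplar identification on synthetic panels with known truth.

Over seeded replicates, simulates a 12-country panel whose designated
exemplar truly dominates both reduction dimensions, runs the full metric +
ranking pipeline, and records whether the exemplar is recovered at the top
of the absolute track.  Writes the per-replicate table under
results/synthetic/.
"""

import argparse
from pathlib import Path

import pandas as pd

from zdexemplar.io import to_no_dtp, write_table
from zdexemplar.metrics import change_metrics, country_year_metrics
from zdexemplar.ranking import dual_track_exemplars
from zdexemplar.simulate import SyntheticSpec, generate_study

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=20)
    args = parser.parse_args()

    rows = []
    for i in range(args.replicates):
        rep_seed = (args.seed * 1000 + i) % (2**31)
        spec = SyntheticSpec(
            n_countries=12, n_units_range=(8, 120), designated_exemplar=True, seed=rep_seed
        )
        panel, _ = generate_study(spec)
        changes = change_metrics(country_year_metrics(to_no_dtp(panel)))
        tracks = dual_track_exemplars(changes, k_absolute=1, k_relative=1)
        table = tracks["absolute"]["table"].set_index("country_code")
        rows.append(
            {
                "replicate": i,
                "seed": rep_seed,
                "top_absolute": tracks["absolute"]["exemplars"][0],
                "recovered": tracks["absolute"]["exemplars"][0] == "EXEMPLAR",
                "exemplar_mean_rank": float(table.loc["EXEMPLAR", "mean_rank"]),
            }
        )
    report = pd.DataFrame(rows)
    write_table(report, OUT / "recovery.csv", precision=2)
    n_rec = int(report["recovered"].sum())
    print(
        f"designed exemplar recovered top-1 on the absolute track in "
        f"{n_rec}/{args.replicates} replicates "
        f"(mean rank {report['exemplar_mean_rank'].mean():.2f})"
    )
    print(f"table written to {OUT / 'recovery.csv'}")


if __name__ == "__main__":
    main()
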