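"""Identify potential exemplars in reducing zero-dose children.

Ranks every study country ordinally (1..56) on its national no-DTP change
and on its subnational-gap change, separately for absolute (pp) and relative
(%) progress, averages the two ranks per track, and selects the top 3
(absolute) and top 2 (relative) as candidate exemplars.  Writes ranking
tables and the exemplar list under results/fixture/.
"""

from pathlib import Path

import pandas as pd

from zdexemplar.io import load_study_fixture, write_table
from zdexemplar.metrics import change_metrics, fixture_metrics
from zdexemplar.ranking import dual_track_exemplars

OUT = Path(__file__).resolve().parents[1] / "results" / "fixture"


def main() -> None:
    changes = change_metrics(fixture_metrics(load_study_fixture()), 2000, 2019)
    tracks = dual_track_exemplars(changes)

    rows = []
    for track in ("absolute", "relative"):
        table = tracks[track]["table"]
        write_table(table, OUT / f"ranking_{track}.csv", precision=2)
        for order, code in enumerate(tracks[track]["exemplars"], 1):
            rows.append({"track": track, "order": order, "country_code": code})
        top = table.head(5)[["country_code", "rank_national", "rank_subnational_gap", "mean_rank"]]
        print(f"{track} track, best mean ranks:")
        print(top.to_string(index=False))
    write_table(pd.DataFrame(rows), OUT / "exemplars.csv")

    print(
        "\nexemplars -> absolute: "
        + ", ".join(tracks["absolute"]["exemplars"])
        + "; relative: "
        + ", ".join(tracks["relative"]["exemplars"])
    )
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
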