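# zdexemplar

Positive-outlier ("exemplar") analysis of **zero-dose children** — children
who have received no doses of the diphtheria–tetanus–pertussis vaccine
(no-DTP) — across 56 low- and lower-middle-income countries, 2000–2019.

Progress in reaching unvaccinated children is summarised per country-year by
two metrics on the percent scale:

* **national no-DTP prevalence**: `no_dtp = 100 − DTP1 coverage`, the share of
  under-one children with no DTP doses;
* **subnational gap**: `gap = Q_0.95(x) − Q_0.05(x)`, the difference between
  the 95th and 5th percentile of no-DTP prevalence `x` across a country's
  second-level administrative units (districts, zones, communes, LGAs), in
  percentage points. Percentiles rather than min/max damp outlier units and
  the effect of widely varying unit counts (≈8 to ≈800 per country).

For each metric the analysis computes absolute change (`end − start`, pp) and
relative change (`(end − start)/start × 100`, %) over the study window, ranks
countries ordinally 1..N on each dimension (rank 1 = largest reduction), and
scores each country by the **mean of its two ranks**, separately for the
absolute and the relative track. The best mean ranks identify candidate
exemplars. A four-way quadrant classification (reduced both / national only /
gap only / increased both) summarises the joint direction of change, and
"neighborhood" comparisons pair target countries (the Gavi Learning Hubs:
Nigeria, Mali, Uganda, Bangladesh) with the exemplar closest to their
baseline-year measures to contrast diverging trajectories.

The subnational estimate panel behind the original study is not publicly
deposited, so the package bundles (a) the published country-level levels,
changes, and exemplar percentile endpoints as a fixture, and (b) a synthetic
panel generator (`zdexemplar.simulate`) that emulates the assumed data
structure — logit-scale declining unit trajectories, country- and unit-level
rate heterogeneity, observation noise, conflict-style shock periods, and a
designated true exemplar for identity-recovery validation.

## Layout

* `src/zdexemplar/` — library: `io` (panel reading/validation, coverage
  conversion, bundled fixtures), `metrics` (gap statistic, national series,
  changes, quadrants), `ranking` (dual-track mean-rank selection),
  `neighborhood` (baseline matching, divergence), `simulate` (synthetic
  panels), `pipeline` + `cli` (orchestration, exports, `zdexemplar` command).
* `analysis/01…06_*.py` — numbered narrative drivers writing tables under
  `results/`.
* `docs/methods.md` — modelling and design notes.

## Worked example

```python
from zdexemplar import load_study_fixture, dual_track_exemplars
from zdexemplar.metrics import fixture_metrics, change_metrics, classify_progress

metrics = fixture_metrics(load_study_fixture())       # country-year levels
changes = change_metrics(metrics, 2000, 2019)          # per-dimension changes
quadrants, counts = classify_progress(changes)
print(counts.to_dict())
tracks = dual_track_exemplars(changes)
print(tracks["absolute"]["exemplars"], tracks["relative"]["exemplars"])
```

prints

```
{'both_reduced': 44, 'national_only_reduced': 5, 'gap_only_reduced': 2, 'both_increased': 5}
['COD', 'ETH', 'IND'] ['BGD', 'BDI']
```

i.e. 44 of 56 countries (78.6%) reduced both national no-DTP prevalence and
the subnational gap; the largest joint absolute reductions were achieved by
the Democratic Republic of the Congo, Ethiopia, and India, and the largest
joint relative reductions by Bangladesh and Burundi. The same pipeline runs
from the command line (`zdexemplar all --out results/run`) or on any tidy
coverage panel CSV (`zdexemplar metrics --panel your_panel.csv ...`).

Running `python analysis/03_neighborhood.py` pairs the Learning Hub
countries with their nearest exemplars at 2000 — Nigeria↔Ethiopia (joint
plane, distance 25.1), Mali↔DRC (gap dimension, 1.0 pp), Uganda↔Burundi
(national dimension, 3.5 pp) — and tabulates how each pair diverged by 2019.

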