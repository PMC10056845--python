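"""Synthetic subnational no-DTP panels with known ground truth.

The real study data (modelled subnational DTP1 estimates) are not publicly
deposited, so every pipeline stage is exercised on synthetic panels that
reproduce the statistical structure the analysis assumes:

* per-country sets of admin-2 units with heterogeneous baselines, from ~8
  units (small island states) to ~800 (Nigeria's local government areas);
* smooth, mostly declining unit trajectories generated on the log-odds scale
  so values respect [0, 100] without clipping dominating the dynamics:
  ``no_dtp(t) = 100 * expit(b_u - r_u * (t - t0))``;
* country-level heterogeneity in baselines and decline rates, plus unit-level
  heterogeneity within a country.  Unit rates are the country rate times a
  log-normal factor, so a positive country rate yields strictly declining
  trajectories for every unit;
* bounded observation noise on the percent scale (clipped to [0, 100]);
* optional additive "shock" blocks (conflict-style coverage collapses) over
  a year interval for a fraction of units;
* log-normal unit populations, constant over years.

A study can designate one country as a true exemplar: it is constructed with
the largest baseline dispersion and the fastest decline, so its true
reductions in national prevalence and in the subnational percentile gap
strictly dominate every other country's — the basis for identity-recovery
tests of the ranking pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import subnational_gap

__all__ = [
    "ShockBlock",
    "CountrySpec",
    "SyntheticSpec",
    "generate_country",
    "generate_study",
    "values_with_percentile_endpoints",
]


@dataclass(frozen=True)
class ShockBlock:
    """An additive no-DTP increase for a fraction of units over a year span."""

    year_start: int
    year_end: int
    unit_fraction: float
    added_no_dtp: float  # percentage points

    def __post_init__(self) -> None:
        if not 0.0 <= self.unit_fraction <= 1.0:
            raise ValueError("unit_fraction must be in [0, 1]")
        if self.year_end < self.year_start:
            raise ValueError("shock interval reversed")
        if self.added_no_dtp < 0:
            raise ValueError("shock increment must be nonnegative")


@dataclass(frozen=True)
class CountrySpec:
    """Trajectory parameters for one synthetic country."""

    country_code: str
    n_units: int
    baseline_logit: float  # country mean of unit baseline log-odds of no-DTP
    unit_baseline_sd: float  # log-odds dispersion across units
    decline_rate: float  # logits per year, >= 0 for declining burden
    unit_rate_sd: float = 0.3  # sd of the log-normal unit rate multiplier
    noise_sd: float = 1.0  # observation noise, percentage points
    shocks: tuple[ShockBlock, ...] = ()
    pop_log_mean: float = 10.4
    pop_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for name in ("unit_baseline_sd", "unit_rate_sd", "noise_sd", "pop_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite([self.baseline_logit, self.decline_rate]).all():
            raise ValueError("rates must be finite")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-level design for a multi-country synthetic panel.

    Defaults emulate the study conditions: 56 countries observed 2000-2019,
    admin-2 unit counts spread log-uniformly over ~8-800, mean baseline
    no-DTP around 25% with wide country- and unit-level heterogeneity,
    gradual log-odds declines with occasional stagnation (rates truncated at
    zero), 1 pp observation noise, and a 10% chance per country of a
    conflict-style shock block.
    """

    n_countries: int = 56
    year_start: int = 2000
    year_end: int = 2019
    n_units_range: tuple[int, int] = (8, 800)
    baseline_logit_mean: float = -1.1  # expit(-1.1) ~ 25% no-DTP
    baseline_logit_sd: float = 0.8  # across countries
    unit_baseline_sd: float = 0.7  # across units within a country
    decline_rate_mean: float = 0.08  # logits / year
    decline_rate_sd: float = 0.04  # across countries
    unit_rate_sd: float = 0.3
    noise_sd: float = 1.0
    shock_probability: float = 0.1
    shock_added_no_dtp: float = 15.0
    pop_log_mean: float = 10.4
    pop_log_sd: float = 1.0
    designated_exemplar: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_logit_sd",
            "unit_baseline_sd",
            "decline_rate_sd",
            "unit_rate_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if self.n_units_range[0] < 1 or self.n_units_range[0] > self.n_units_range[1]:
            raise ValueError("invalid n_units_range")
        if self.year_end < self.year_start:
            raise ValueError("year range reversed")


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _noiseless_trajectories(
    spec: CountrySpec, years: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n_units, n_years) array of true no-DTP percents, shocks included."""
    b = rng.normal(spec.baseline_logit, spec.unit_baseline_sd, size=spec.n_units)
    mult = rng.lognormal(mean=-0.5 * spec.unit_rate_sd**2, sigma=spec.unit_rate_sd, size=spec.n_units)
    r = spec.decline_rate * mult
    t = years - years[0]
    truth = expit(b[:, None] - r[:, None] * t[None, :]) * 100.0
    for shock in spec.shocks:
        hit = rng.random(spec.n_units) < shock.unit_fraction
        in_window = (years >= shock.year_start) & (years <= shock.year_end)
        truth[np.ix_(hit, in_window)] = np.minimum(
            truth[np.ix_(hit, in_window)] + shock.added_no_dtp, 100.0
        )
    return truth


def generate_country(
    spec: CountrySpec,
    years: np.ndarray | range,
    seed_or_rng: int | np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """One country's unit-year panel plus its true (noiseless) summary.

    Returns a long DataFrame (admin1_id, admin2_id, year, no_dtp, population)
    and a dict with the country's true parameters and noiseless national
    mean / percentile gap at the first and last year.
    """
    rng = _rng(seed_or_rng)
    years = np.asarray(list(years), dtype=int)
    truth = _noiseless_trajectories(spec, years, rng)
    noise = rng.normal(0.0, spec.noise_sd, size=truth.shape) if spec.noise_sd > 0 else 0.0
    observed = np.clip(truth + noise, 0.0, 100.0)
    populations = rng.lognormal(spec.pop_log_mean, spec.pop_log_sd, size=spec.n_units)

    n_admin1 = max(1, int(np.ceil(spec.n_units / 10)))
    admin1 = [f"{spec.country_code}-S{u % n_admin1:03d}" for u in range(spec.n_units)]
    unit_ids = [f"{spec.country_code}-D{u:04d}" for u in range(spec.n_units)]

    df = pd.DataFrame(
        {
            "country_code": spec.country_code,
            "admin1_id": np.repeat(admin1, len(years)),
            "admin2_id": np.repeat(unit_ids, len(years)),
            "year": np.tile(years, spec.n_units),
            "no_dtp": observed.ravel(),
            "population": np.repeat(np.round(populations).astype(int), len(years)),
        }
    )

    def _summary(col: int) -> tuple[float, float]:
        vals = truth[:, col]
        _, _, gap = subnational_gap(vals)
        return float(vals.mean()), gap

    nat0, gap0 = _summary(0)
    nat1, gap1 = _summary(-1)
    country_truth = {
        "country_code": spec.country_code,
        "n_units": spec.n_units,
        "baseline_logit": spec.baseline_logit,
        "unit_baseline_sd": spec.unit_baseline_sd,
        "decline_rate": spec.decline_rate,
        "n_shocks": len(spec.shocks),
        "true_national_start": nat0,
        "true_national_end": nat1,
        "true_gap_start": gap0,
        "true_gap_end": gap1,
        "true_national_change": nat1 - nat0,
        "true_gap_change": gap1 - gap0,
    }
    return df, country_truth


def _draw_country_specs(spec: SyntheticSpec, rng: np.random.Generator) -> list[CountrySpec]:
    lo, hi = spec.n_units_range
    specs = []
    for i in range(spec.n_countries):
        n_units = int(np.round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        n_units = int(np.clip(n_units, lo, hi))
        baseline = rng.normal(spec.baseline_logit_mean, spec.baseline_logit_sd)
        rate = max(0.0, rng.normal(spec.decline_rate_mean, spec.decline_rate_sd))
        shocks: tuple[ShockBlock, ...] = ()
        # shock blocks sit in the interior of the window (conflict-era
        # stagnation, cf. a civil war ending mid-period) so endpoint-year
        # metrics reflect the underlying trajectories
        if spec.year_end - spec.year_start > 6 and rng.random() < spec.shock_probability:
            start = int(rng.integers(spec.year_start + 3, spec.year_end - 3))
            shocks = (
                ShockBlock(
                    year_start=start,
                    year_end=min(start + int(rng.integers(2, 6)), spec.year_end - 1),
                    unit_fraction=0.3,
                    added_no_dtp=spec.shock_added_no_dtp,
                ),
            )
        specs.append(
            CountrySpec(
                country_code=f"C{i:03d}",
                n_units=n_units,
                baseline_logit=baseline,
                unit_baseline_sd=spec.unit_baseline_sd,
                decline_rate=rate,
                unit_rate_sd=spec.unit_rate_sd,
                noise_sd=spec.noise_sd,
                shocks=shocks,
                pop_log_mean=spec.pop_log_mean,
                pop_log_sd=spec.pop_log_sd,
            )
        )
    if spec.designated_exemplar:
        # constructed to strictly dominate both reduction dimensions:
        # near-50% baseline maximises achievable unit spread on the percent
        # scale, and the decline is faster than any draw can plausibly reach
        specs[0] = replace(
            specs[0],
            country_code="EXEMPLAR",
            n_units=max(specs[0].n_units, 60),
            baseline_logit=0.3,
            unit_baseline_sd=max(1.3, 1.5 * spec.unit_baseline_sd),
            decline_rate=max(0.3, spec.decline_rate_mean + 4 * spec.decline_rate_sd),
            unit_rate_sd=0.1,  # uniform fast decline: laggard units would keep the end-year gap wide
            shocks=(),
        )
        # keep competitors inside the envelope the exemplar dominates
        for i in range(1, len(specs)):
            specs[i] = replace(
                specs[i],
                baseline_logit=min(specs[i].baseline_logit, 0.0),
                decline_rate=min(specs[i].decline_rate, 0.18),
            )
    return specs


def generate_study(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A full multi-country coverage panel plus the designed truth table.

    The returned panel carries ``dtp1_coverage`` (100 - no_dtp) and passes
    panel validation, so it enters the pipeline exactly like a real input.
    The truth table holds each country's generating parameters and noiseless
    start/end summaries; when an exemplar is designated, its true reductions
    are verified to strictly dominate every other country's on both
    dimensions.
    """
    rng = np.random.default_rng(spec.seed)
    country_specs = _draw_country_specs(spec, rng)
    years = np.arange(spec.year_start, spec.year_end + 1)
    frames, truths = [], []
    for cs in country_specs:
        df, truth = generate_country(cs, years, rng)
        frames.append(df)
        truths.append(truth)
    panel = pd.concat(frames, ignore_index=True)
    panel["dtp1_coverage"] = 100.0 - panel["no_dtp"]
    panel = panel.drop(columns=["no_dtp"])
    truth_table = pd.DataFrame(truths)
    truth_table["designated_exemplar"] = truth_table["country_code"] == "EXEMPLAR"

    if spec.designated_exemplar:
        ex = truth_table[truth_table["designated_exemplar"]].iloc[0]
        others = truth_table[~truth_table["designated_exemplar"]]
        if not (
            (ex["true_national_change"] < others["true_national_change"]).all()
            and (ex["true_gap_change"] < others["true_gap_change"]).all()
        ):
            raise RuntimeError(
                "designated exemplar does not dominate both true reduction dimensions"
            )
    return panel, truth_table


def values_with_percentile_endpoints(
    p5: float, p95: float, n: int = 21
) -> np.ndarray:
    """A unit-value vector whose type-7 5th/95th percentiles are exact.

    With n = 21 values the 5th and 95th percentile positions fall exactly on
    the 2nd and 20th order statistics, so placing ``p5`` and ``p95`` there
    (with one value below and one above) makes linear-interpolation quantiles
    reproduce the endpoints with no interpolation error.  Used to exercise
    the percentile-gap statistic against published endpoint values.
    """
    if n != 21:
        raise ValueError("the endpoint-anchoring construction is defined for n=21")
    if p95 < p5:
        raise ValueError("p95 must be >= p5")
    step = (p95 - p5) / 18.0 if p95 > p5 else 1.0
    inner = np.linspace(p5, p95, 19)
    return np.concatenate([[max(p5 - step, 0.0)], inner, [min(p95 + step, 100.0)]])
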