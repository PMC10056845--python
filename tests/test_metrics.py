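"""Percentile-gap statistic, national aggregation, changes, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zdexemplar.metrics import (
    CAT_BOTH_INCREASED,
    CAT_BOTH_REDUCED,
    CAT_GAP_ONLY,
    CAT_NATIONAL_ONLY,
    change_metrics,
    classify_progress,
    national_series,
    subnational_gap,
    units_gap_correlation,
)
from zdexemplar.simulate import values_with_percentile_endpoints

from conftest import sorted_interpolation_quantile

unit_values = st.lists(
    st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1, max_size=120
)


def _panel_from_unit_values(per_country: dict[str, np.ndarray], year: int = 2000) -> pd.DataFrame:
    rows = []
    for code, vals in per_country.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "country_code": code,
                    "admin1_id": f"{code}-s0",
                    "admin2_id": f"{code}-u{i}",
                    "year": year,
                    "no_dtp": float(v),
                }
            )
    return pd.DataFrame(rows)


class TestSubnationalGap:
    def test_constant_vector_has_zero_gap(self):
        lo, hi, gap = subnational_gap([12.0] * 20)
        assert (lo, hi, gap) == (12.0, 12.0, 0.0)

    def test_single_unit_gap_is_zero(self):
        assert subnational_gap([37.5])[2] == 0.0

    def test_reproduces_published_endpoint_pair(self):
        # a vector whose 5th/95th percentiles sit at 28.5 and 75.3 yields the
        # published 46.8 pp gap
        values = values_with_percentile_endpoints(28.5, 75.3)
        lo, hi, gap = subnational_gap(values)
        assert lo == pytest.approx(28.5, abs=1e-9)
        assert hi == pytest.approx(75.3, abs=1e-9)
        assert gap == pytest.approx(46.8, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(unit_values)
    def test_matches_sort_and_interpolate_oracle(self, values):
        lo, hi, gap = subnational_gap(values)
        assert lo == pytest.approx(sorted_interpolation_quantile(values, 0.05), abs=1e-9)
        assert hi == pytest.approx(sorted_interpolation_quantile(values, 0.95), abs=1e-9)
        assert gap >= -1e-12
        assert gap <= max(values) - min(values) + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(unit_values, st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_translation_leaves_gap_unchanged(self, values, shift):
        base_gap = subnational_gap(values)[2]
        shifted_gap = subnational_gap([v + shift for v in values])[2]
        assert shifted_gap == pytest.approx(base_gap, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(unit_values, st.randoms(use_true_random=False))
    def test_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert subnational_gap(shuffled)[2] == pytest.approx(subnational_gap(values)[2], abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            subnational_gap([])
        with pytest.raises(ValueError):
            subnational_gap([1.0], lower=0.95, upper=0.05)
        with pytest.raises(ValueError):
            subnational_gap([1.0], lower=-0.1)


class TestNationalSeries:
    def test_single_unit_country_identical_under_all_modes(self):
        panel = _panel_from_unit_values({"AAA": np.array([33.0])})
        panel["population"] = 500
        for mode in ("unweighted_mean", "pop_weighted"):
            out = national_series(panel, mode=mode)
            assert out["national_no_dtp"].iloc[0] == pytest.approx(33.0)

    def test_population_weighting_hand_example(self):
        panel = _panel_from_unit_values({"AAA": np.array([10.0, 30.0])})
        panel["population"] = [1, 3]
        out = national_series(panel, mode="pop_weighted")
        assert out["national_no_dtp"].iloc[0] == pytest.approx(25.0)

    def test_provided_mode_passes_table_through(self):
        panel = _panel_from_unit_values({"COD": np.array([50.0, 55.0]), "ETH": np.array([60.0])})
        national = pd.DataFrame(
            {"country_code": ["COD", "ETH"], "year": [2000, 2000], "national_no_dtp": [51.9, 63.4]}
        )
        out = national_series(panel, mode="provided", national_table=national)
        assert dict(zip(out["country_code"], out["national_no_dtp"])) == {"COD": 51.9, "ETH": 63.4}

    def test_provided_mode_missing_country_year_errors(self):
        panel = _panel_from_unit_values({"COD": np.array([50.0])})
        national = pd.DataFrame({"country_code": ["ETH"], "year": [2000], "national_no_dtp": [63.4]})
        with pytest.raises(ValueError, match="missing country-years"):
            national_series(panel, mode="provided", national_table=national)

    def test_zero_total_population_errors(self):
        panel = _panel_from_unit_values({"AAA": np.array([10.0, 30.0])})
        panel["population"] = [0, 0]
        with pytest.raises(ValueError, match="population"):
            national_series(panel, mode="pop_weighted")


class TestChangeMetrics:
    @staticmethod
    def _metrics(code, start, end, gap_start=10.0, gap_end=5.0):
        return pd.DataFrame(
            {
                "country_code": [code, code],
                "year": [2000, 2019],
                "national_no_dtp": [start, end],
                "gap": [gap_start, gap_end],
            }
        )

    def test_published_national_decline(self, study_changes):
        rec = study_changes.query("country_code == 'COD' and dimension == 'national'").iloc[0]
        assert rec["absolute_change"] == pytest.approx(-45.0, abs=1e-9)

    def test_no_change_gives_zero_absolute_and_relative(self):
        ch = change_metrics(self._metrics("AAA", 17.0, 17.0))
        nat = ch[ch["dimension"] == "national"].iloc[0]
        assert nat["absolute_change"] == 0.0
        assert nat["relative_change"] == 0.0

    def test_halving_is_minus_fifty_percent(self):
        ch = change_metrics(self._metrics("AAA", 20.0, 10.0))
        nat = ch[ch["dimension"] == "national"].iloc[0]
        assert nat["relative_change"] == pytest.approx(-50.0)

    def test_zero_start_flags_relative_undefined(self):
        ch = change_metrics(self._metrics("AAA", 0.0, 5.0))
        nat = ch[ch["dimension"] == "national"].iloc[0]
        assert nat["absolute_change"] == 5.0
        assert np.isnan(nat["relative_change"])

    def test_missing_endpoint_year_skips_country_but_not_others(self):
        full = self._metrics("AAA", 20.0, 10.0)
        partial = self._metrics("BBB", 30.0, 15.0).iloc[[0]]  # only year 2000
        ch = change_metrics(pd.concat([full, partial], ignore_index=True))
        assert set(ch["country_code"]) == {"AAA"}

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0.1, max_value=100, allow_nan=False),
        st.floats(min_value=0, max_value=100, allow_nan=False),
        st.floats(min_value=0.01, max_value=100, allow_nan=False),
    )
    def test_relative_change_scale_invariant(self, start, end, k):
        base = change_metrics(self._metrics("AAA", start, end, 10.0, 5.0))
        scaled = change_metrics(self._metrics("AAA", start * k, end * k, 10.0, 5.0))
        get = lambda df: df[df["dimension"] == "national"]["relative_change"].iloc[0]
        assert get(scaled) == pytest.approx(get(base), rel=1e-9, abs=1e-9)


class TestClassifyProgress:
    def test_study_partition_counts_and_membership(self, study_changes):
        quadrants, counts = classify_progress(study_changes)
        assert counts[CAT_BOTH_REDUCED] == 44
        groups = quadrants.groupby("category")["country_code"].apply(set)
        assert groups[CAT_BOTH_INCREASED] == {"BEN", "KEN", "GIN", "PNG", "UZB"}
        assert groups[CAT_NATIONAL_ONLY] == {"COG", "TJK", "DJI", "CAF", "STP"}
        assert groups[CAT_GAP_ONLY] == {"HTI", "MMR"}
        assert counts.sum() == 56

    def test_zero_change_counts_as_not_reduced(self):
        changes = pd.DataFrame(
            {
                "country_code": ["AAA", "AAA"],
                "dimension": ["national", "subnational_gap"],
                "value_start": [10.0, 10.0],
                "value_end": [10.0, 10.0],
                "absolute_change": [0.0, 0.0],
                "relative_change": [0.0, 0.0],
            }
        )
        quadrants, counts = classify_progress(changes)
        assert quadrants["category"].iloc[0] == CAT_BOTH_INCREASED
        assert counts.sum() == 1


class TestUnitsGapCorrelation:
    def test_gap_proportional_to_unit_count_gives_r_near_one(self):
        per_country = {
            f"C{i:02d}": np.linspace(0.0, n / 10.0, n)
            for i, n in enumerate(range(10, 210, 10))
        }
        panel = _panel_from_unit_values(per_country)
        r, defined = units_gap_correlation(panel, 2000)
        assert defined
        assert r > 0.999

    def test_identical_unit_counts_undefined(self):
        per_country = {f"C{i}": np.linspace(0, 10 + i, 10) for i in range(5)}
        panel = _panel_from_unit_values(per_country)
        r, defined = units_gap_correlation(panel, 2000)
        assert not defined and np.isnan(r)

    def test_independent_gaps_give_small_correlation(self):
        rng = np.random.default_rng(11)
        per_country = {}
        for i in range(60):
            n = int(rng.integers(8, 400))
            width = rng.uniform(5, 60)  # independent of n
            per_country[f"C{i:02d}"] = rng.uniform(0, width, size=n)
        panel = _panel_from_unit_values(per_country)
        r, defined = units_gap_correlation(panel, 2000)
        assert defined
        assert abs(r) < 0.3
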