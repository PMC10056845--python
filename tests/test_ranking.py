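"""Ordinal ranking, mean-rank aggregation, and exemplar selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zdexemplar.metrics import DIM_GAP, DIM_NATIONAL, change_metrics, country_year_metrics
from zdexemplar.io import to_no_dtp
from zdexemplar.ranking import (
    dual_track_exemplars,
    mean_rank,
    rank_dimension,
    ranking_table,
    select_exemplars,
)


def _changes(national, gap=None, rel_national=None):
    """Build a change-record frame from per-country change values."""
    gap = gap if gap is not None else {c: -1.0 for c in national}
    records = []
    for code, v in national.items():
        records.append(
            {
                "country_code": code,
                "dimension": DIM_NATIONAL,
                "value_start": 10.0,
                "value_end": 10.0 + v,
                "absolute_change": v,
                "relative_change": (rel_national or {}).get(code, v * 10),
            }
        )
    for code, v in gap.items():
        records.append(
            {
                "country_code": code,
                "dimension": DIM_GAP,
                "value_start": 10.0,
                "value_end": 10.0 + v,
                "absolute_change": v,
                "relative_change": v * 10,
            }
        )
    return pd.DataFrame(records)


class TestRankDimension:
    def test_strict_ordering(self):
        ranks = rank_dimension(_changes({"A": -5.0, "B": -3.0, "C": 2.0}), DIM_NATIONAL)
        assert ranks.to_dict() == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_average_tie_policy(self):
        ranks = rank_dimension(_changes({"A": -5.0, "B": -5.0, "C": 2.0}), DIM_NATIONAL)
        assert ranks.to_dict() == {"A": 1.5, "B": 1.5, "C": 3.0}

    def test_competition_tie_policy(self):
        ranks = rank_dimension(
            _changes({"A": -5.0, "B": -5.0, "C": 2.0}), DIM_NATIONAL, tie_policy="competition"
        )
        assert ranks.to_dict() == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_largest_national_decline_ranks_first_on_study_data(self, study_changes):
        ranks = rank_dimension(study_changes, DIM_NATIONAL, track="absolute")
        assert ranks.idxmin() == "ETH"
        assert ranks["ETH"] == 1.0

    def test_rank_sum_invariant(self, study_changes):
        for track in ("absolute", "relative"):
            for dim in (DIM_NATIONAL, DIM_GAP):
                ranks = rank_dimension(study_changes, dim, track=track)
                n = len(ranks)
                assert ranks.sum() == pytest.approx(n * (n + 1) / 2)

    def test_undefined_relative_changes_excluded(self):
        changes = _changes({"A": -5.0, "B": -3.0}, rel_national={"A": np.nan, "B": -30.0})
        ranks = rank_dimension(changes, DIM_NATIONAL, track="relative")
        assert list(ranks.index) == ["B"]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            rank_dimension(_changes({"A": -1.0}).iloc[0:0], DIM_NATIONAL)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.integers(min_value=-600, max_value=600).map(lambda i: i / 10.0),
            min_size=2, max_size=25, unique=True,
        ),
        st.floats(min_value=0.01, max_value=10, allow_nan=False),
        st.floats(min_value=-5, max_value=5, allow_nan=False),
    )
    def test_invariant_to_positive_affine_transform(self, values, a, b):
        codes = [f"C{i:02d}" for i in range(len(values))]
        base = rank_dimension(_changes(dict(zip(codes, values))), DIM_NATIONAL)
        scaled = rank_dimension(
            _changes(dict(zip(codes, [a * v + b for v in values]))), DIM_NATIONAL
        )
        pd.testing.assert_series_equal(base, scaled)

    def test_invariant_to_country_order(self, study_changes):
        shuffled = study_changes.sample(frac=1.0, random_state=5).reset_index(drop=True)
        base = rank_dimension(study_changes, DIM_GAP).sort_index()
        perm = rank_dimension(shuffled, DIM_GAP).sort_index()
        pd.testing.assert_series_equal(base, perm)


class TestMeanRankAndSelection:
    def test_mean_rank_arithmetic(self):
        r1 = pd.Series({"A": 1.0, "B": 2.0, "C": 1.0})
        r2 = pd.Series({"A": 1.0, "B": 2.0, "C": 56.0})
        out = mean_rank(r1, r2)
        assert out.to_dict() == {"A": 1.0, "B": 2.0, "C": 28.5}

    def test_drc_scores_mean_rank_two_on_absolute_track(self, study_changes):
        table = ranking_table(study_changes, track="absolute").set_index("country_code")
        assert table.loc["COD", "rank_national"] == 2.0
        assert table.loc["COD", "rank_subnational_gap"] == 2.0
        assert table.loc["COD", "mean_rank"] == 2.0

    def test_study_exemplar_sets(self, study_changes):
        tracks = dual_track_exemplars(study_changes)
        assert set(tracks["absolute"]["exemplars"]) == {"COD", "ETH", "IND"}
        assert set(tracks["relative"]["exemplars"]) == {"BGD", "BDI"}

    def test_mean_rank_tie_broken_by_national_reduction(self, study_changes):
        # Ethiopia and India tie at mean rank 5.5; Ethiopia's larger national
        # decline must order it ahead
        ordered = select_exemplars(ranking_table(study_changes, track="absolute"), k=3)
        assert ordered == ["COD", "ETH", "IND"]

    def test_k_equals_n_returns_everyone_ordered(self, study_changes):
        table = ranking_table(study_changes, track="absolute")
        everyone = select_exemplars(table, k=len(table))
        assert len(everyone) == 56
        assert everyone[0] == "COD"

    def test_k_larger_than_n_errors(self, study_changes):
        table = ranking_table(study_changes, track="absolute")
        with pytest.raises(ValueError):
            select_exemplars(table, k=len(table) + 1)

    def test_constructed_dominant_country_attains_mean_rank_one(self):
        national = {"DOM": -50.0, "A": -30.0, "B": -10.0, "C": 5.0}
        gap = {"DOM": -40.0, "A": -20.0, "B": -5.0, "C": 3.0}
        table = ranking_table(_changes(national, gap), track="absolute")
        assert table.set_index("country_code").loc["DOM", "mean_rank"] == 1.0
        for k in (1, 2, 4):
            assert select_exemplars(table, k)[0] == "DOM"

    def test_designed_synthetic_exemplar_recovered(self, synthetic_metrics):
        changes = change_metrics(synthetic_metrics)
        tracks = dual_track_exemplars(changes, k_absolute=1)
        assert tracks["absolute"]["exemplars"] == ["EXEMPLAR"]
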