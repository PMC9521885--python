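"""Threshold arithmetic, Fechner sensation, SDS normalization, aggregation.

The worked two-establishment example: both units see 4 baseline visits per
interval; the complaint intervals carry 20 and 6 visits, giving difference
thresholds of 400% and 50% and putting the 6-visit unit at the sensitive
end of the scale.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sds.config import ScoreConfig
from sds.core import (
    absolute_threshold,
    activity_intensity,
    aggregate_zip,
    citywide_complaint_curves,
    difference_threshold,
    score_units,
    sds_scores,
    subjective_sensation,
    type_summary,
)
from sds.ingest import bin_six_hour, flag_complaints, pool_to_buildings

from conftest import two_case_intervals
from oracle import oracle_scores, oracle_zip_means


class TestScalarOperations:
    @pytest.mark.parametrize(
        "visits,area,expected",
        [(0, 123.0, 0.0), (20, 10_000.0, 20.0), (6, 10_000.0, 6.0), (4, 5_000.0, 8.0)],
    )
    def test_activity_intensity(self, visits, area, expected):
        assert activity_intensity(visits, area) == pytest.approx(expected)

    def test_nonpositive_floor_area_is_hard_error(self):
        with pytest.raises(ValueError):
            activity_intensity(1, 0.0)

    def test_absolute_threshold_is_the_mean(self):
        assert absolute_threshold([20.0]) == 20.0
        assert absolute_threshold([7.0, 7.0, 7.0]) == 7.0
        rng = np.random.default_rng(2)
        xs = rng.uniform(0.1, 30, 17).tolist()
        assert absolute_threshold(xs) == pytest.approx(sum(xs) / len(xs), abs=1e-12)

    def test_difference_threshold_worked_example(self):
        assert difference_threshold(20.0, [4.0, 4.0, 4.0, 4.0]) == pytest.approx(4.0)
        assert difference_threshold(6.0, [4.0, 4.0, 4.0, 4.0]) == pytest.approx(0.5)
        assert difference_threshold(5.0, [5.0]) == 0.0

    def test_difference_threshold_guards(self):
        with pytest.raises(ValueError):
            difference_threshold(5.0, [])
        with pytest.raises(ValueError):
            difference_threshold(5.0, [0.0, 0.0])

    def test_subjective_sensation(self):
        assert subjective_sensation(0.0, 17.3) == 0.0
        assert subjective_sensation(2.5, 1.0) == 0.0
        assert subjective_sensation(4.0, 20.0) == pytest.approx(
            4 * math.log10(20), abs=1e-9
        )
        assert subjective_sensation(4.0, 20.0) == pytest.approx(5.20412, abs=1e-5)

    def test_sds_linear_map_endpoints_and_midpoint(self):
        assert sds_scores([0.0, 1.0, 2.0]) == pytest.approx([100.0, 50.0, 0.0])

    def test_sds_degenerate_inputs_raise_with_guidance(self):
        with pytest.raises(ValueError, match="min-max|>= 2"):
            sds_scores([3.0])
        with pytest.raises(ValueError, match="equal"):
            sds_scores([3.0, 3.0, 3.0])


class TestSdsProperties:
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=2,
            max_size=40,
            unique=True,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_range_and_endpoints(self, ss):
        out = sds_scores(ss)
        assert np.all((out >= 0.0) & (out <= 100.0))
        assert out[int(np.argmax(ss))] == 0.0
        assert out[int(np.argmin(ss))] == 100.0

    def test_extreme_ties_share_endpoints(self):
        out = sds_scores([1.0, 1.0, 2.0, 5.0, 5.0])
        assert list(out[:2]) == [100.0, 100.0]
        assert list(out[-2:]) == [0.0, 0.0]

    def test_ranking_equal_D_larger_A_scores_lower(self):
        ss = [subjective_sensation(0.5, a) for a in (30.0, 10.0)]
        out = sds_scores(ss + [0.0])
        assert out[0] < out[1]

    def test_ranking_equal_A_larger_D_scores_lower(self):
        ss = [subjective_sensation(d, 10.0) for d in (2.0, 0.5)]
        out = sds_scores(ss + [0.0])
        assert out[0] < out[1]


class TestWorkedExampleCity:
    def test_thresholds_and_inverted_normalization(self):
        intervals, units = two_case_intervals()
        est, _ = score_units(intervals, units)
        est = est.set_index("unit_id")
        assert est.loc["caseB", "A"] == pytest.approx(20.0)
        assert est.loc["caseC", "A"] == pytest.approx(6.0)
        assert est.loc["caseB", "D"] == pytest.approx(4.0)   # 400 %
        assert est.loc["caseC", "D"] == pytest.approx(0.5)   # 50 %
        # the lower-stimulus unit is the more sensitive one
        assert est.loc["caseC", "SDS"] == pytest.approx(100.0)
        assert est.loc["caseB", "SDS"] == pytest.approx(0.0)


def _random_city_intervals(seed, n_units=18, n_intervals=28):
    rng = np.random.default_rng(seed)
    units = pd.DataFrame(
        {
            "unit_id": [f"B{i}" for i in range(n_units)],
            "floor_area": rng.uniform(1_000, 20_000, n_units).round(0),
            "zip": rng.choice(["z1", "z2", "z3"], n_units),
            "poi_type": rng.choice(["food_drink", "store"], n_units),
            "n_pois_pooled": 1,
        }
    )
    starts = pd.date_range("2020-04-01", periods=n_intervals, freq="6h")
    rows = []
    for u in units["unit_id"]:
        for s in starts:
            rows.append(
                {
                    "unit_id": u,
                    "interval_start": s,
                    "visits": int(rng.poisson(6)),
                    "open": bool(rng.random() < 0.85),
                    "complaint": bool(rng.random() < 0.15),
                }
            )
    return pd.DataFrame(rows), units


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_oracle_equivalence_on_random_fixture(seed):
    """A, D, SS, SDS and zip means match a straight-loop reference to 1e-12."""
    intervals, units = _random_city_intervals(seed)
    est, _ = score_units(intervals, units)
    ref = oracle_scores(
        intervals.to_dict("records"),
        units.set_index("unit_id")["floor_area"].to_dict(),
        units.set_index("unit_id")["zip"].to_dict(),
    )
    assert set(est["unit_id"]) == set(ref)
    for _, row in est.iterrows():
        r = ref[row["unit_id"]]
        for col in ("A", "D", "SS", "SDS"):
            assert row[col] == pytest.approx(r[col], abs=1e-12), (row["unit_id"], col)
    zm = aggregate_zip(est).set_index("zip")["SDS_z"]
    for z, v in oracle_zip_means(ref).items():
        assert zm[z] == pytest.approx(v, abs=1e-12)


def test_log_base_choice_rescales_ss_but_not_sds():
    intervals, units = _random_city_intervals(7)
    est10, _ = score_units(intervals, units, ScoreConfig(log_base=10.0))
    este, _ = score_units(intervals, units, ScoreConfig(log_base=math.e))
    ratio = este["SS"].to_numpy() / est10["SS"].to_numpy()
    assert np.allclose(ratio[np.isfinite(ratio)], math.log(10), atol=1e-9)
    assert np.allclose(est10["SDS"], este["SDS"], atol=1e-9)


def test_intensity_unit_changes_sds_when_D_varies():
    """SDS is not invariant to the intensity unit: log A shifts additively
    while D multiplies, so the unit is pinned at per-10,000 sq ft."""
    intervals, units = _random_city_intervals(11)
    a, _ = score_units(intervals, units, ScoreConfig(intensity_scale=10_000.0))
    b, _ = score_units(intervals, units, ScoreConfig(intensity_scale=1.0))
    assert a["D"].nunique() > 1
    assert not np.allclose(a["SDS"], b["SDS"], atol=1e-6)


class TestScoringExclusions:
    def test_closed_intervals_never_count(self):
        intervals, units = two_case_intervals()
        extra = intervals.iloc[[0]].assign(
            interval_start=pd.Timestamp("2020-04-03"), visits=500, open=False
        )
        est, _ = score_units(pd.concat([intervals, extra], ignore_index=True), units)
        assert est.set_index("unit_id").loc["caseB", "D"] == pytest.approx(4.0)

    def test_zero_visit_complaint_interval_routed_to_ledger(self):
        intervals, units = two_case_intervals()
        extra = intervals.iloc[[0]].assign(
            interval_start=pd.Timestamp("2020-04-03"), visits=0, complaint=True
        )
        est, ledger = score_units(pd.concat([intervals, extra], ignore_index=True), units)
        assert est.set_index("unit_id").loc["caseB", "A"] == pytest.approx(20.0)
        rule = [s for s in ledger.steps if "recorded visits" in s["rule"]][0]
        assert rule["rows_dropped"] == 1


def test_slot_stratified_baseline_matches_complaint_time_of_day():
    """With stratification on, a unit whose complaint falls in a busy slot is
    compared against that slot's baseline, not the all-day mean."""
    rows = []
    # four days: quiet 06:00 slot (2 visits), busy 18:00 slot (10 visits)
    for day in range(1, 5):
        rows.append({"unit_id": "B1", "interval_start": pd.Timestamp(f"2020-04-{day:02d} 06:00"),
                     "visits": 2, "open": True, "complaint": False})
        rows.append({"unit_id": "B1", "interval_start": pd.Timestamp(f"2020-04-{day:02d} 18:00"),
                     "visits": 10, "open": True, "complaint": False})
    rows.append({"unit_id": "B1", "interval_start": pd.Timestamp("2020-04-05 18:00"),
                 "visits": 20, "open": True, "complaint": True})
    # a second unit so normalization is defined
    for day in range(1, 5):
        rows.append({"unit_id": "B2", "interval_start": pd.Timestamp(f"2020-04-{day:02d} 06:00"),
                     "visits": 4, "open": True, "complaint": False})
    rows.append({"unit_id": "B2", "interval_start": pd.Timestamp("2020-04-05 06:00"),
                 "visits": 8, "open": True, "complaint": True})
    intervals = pd.DataFrame(rows)
    units = pd.DataFrame(
        {"unit_id": ["B1", "B2"], "floor_area": [10_000.0, 10_000.0],
         "zip": ["z1", "z1"], "poi_type": ["store", "store"], "n_pois_pooled": [1, 1]}
    )
    pooled, _ = score_units(intervals, units)
    strat, _ = score_units(intervals, units, ScoreConfig(stratify_baseline=True))
    pooled = pooled.set_index("unit_id")
    strat = strat.set_index("unit_id")
    # pooled baseline for B1 is (2+10)/2 = 6 -> D = 14/6; slot baseline is 10 -> D = 1
    assert pooled.loc["B1", "D"] == pytest.approx(14 / 6)
    assert strat.loc["B1", "D"] == pytest.approx(1.0)
    # B2's complaint slot equals its only baseline slot: unchanged
    assert strat.loc["B2", "D"] == pytest.approx(pooled.loc["B2", "D"])


def test_min_baseline_requirement_excludes_units():
    intervals, units = two_case_intervals()
    with pytest.raises(ValueError, match="no scoreable"):
        score_units(intervals, units, ScoreConfig(min_baseline=5))


class TestCurves:
    def test_doubled_complaint_city_gives_doubled_curve(self):
        starts = pd.date_range("2020-04-01", periods=8, freq="6h")
        rows = []
        for u, area in [("B1", 10_000.0), ("B2", 10_000.0)]:
            for s in starts:
                rows.append({"unit_id": u, "interval_start": s, "visits": 4,
                             "open": True, "complaint": False, "intensity": 4.0})
        comp = pd.DataFrame(rows[:4]).assign(complaint=True, visits=8, intensity=8.0)
        t = pd.concat([pd.DataFrame(rows), comp], ignore_index=True)
        curves = citywide_complaint_curves(t).dropna()
        assert np.allclose(
            curves["complaint_intensity"], 2 * curves["baseline_intensity"]
        )

    def test_no_complaints_means_missing_complaint_curve(self):
        intervals, units = two_case_intervals()
        intervals = intervals.assign(
            complaint=False, intensity=intervals["visits"].astype(float)
        )
        curves = citywide_complaint_curves(intervals)
        assert curves["complaint_intensity"].isna().all()
        assert curves["baseline_intensity"].notna().all()

    def test_empty_slots_are_missing_not_zero(self):
        intervals, units = two_case_intervals()
        intervals = intervals.assign(intensity=intervals["visits"].astype(float))
        curves = citywide_complaint_curves(intervals)
        base_only = curves[curves["complaint_intensity"].isna()]
        assert (base_only["baseline_intensity"] > 0).all()


class TestAggregation:
    def test_zip_mean_examples(self):
        est = pd.DataFrame(
            {"unit_id": ["a", "b", "c"], "SDS": [40.0, 60.0, 77.0],
             "zip": ["z1", "z1", "z2"]}
        )
        zm = aggregate_zip(est).set_index("zip")
        assert zm.loc["z1", "SDS_z"] == 50.0
        assert zm.loc["z2", "SDS_z"] == 77.0
        assert zm.loc["z1", "n_units"] == 2

    def test_type_summary_single_type_share_100(self):
        intervals, units = two_case_intervals()
        est, _ = score_units(intervals, units)
        out = type_summary(est, units)
        assert len(out) == 1
        assert out.loc[0, "unit_share_pct"] == 100.0

    def test_type_summary_matches_hand_computation(self):
        est = pd.DataFrame(
            {
                "unit_id": ["a", "b", "c", "d"],
                "A": [10.0, 20.0, 5.0, 7.0],
                "D": [1.0, 3.0, 0.5, 0.7],
                "SS": [1.0, 3.9, 0.35, 0.59],
                "SDS": [80.0, 0.0, 100.0, 90.0],
                "n_complaint_intervals": [2, 1, 3, 1],
                "n_baseline_intervals": [5, 5, 5, 5],
                "zip": ["z1", "z1", "z2", "z2"],
                "poi_type": ["store", "store", "gym", "gym"],
            }
        )
        units = est[["unit_id", "zip", "poi_type"]].assign(
            floor_area=1000.0, n_pois_pooled=1
        )
        out = type_summary(est, units).set_index("poi_type")
        assert out.loc["store", "A_mean"] == 15.0
        assert out.loc["store", "A_sd"] == pytest.approx(np.std([10, 20], ddof=1))
        assert out.loc["gym", "SDS_mean"] == 95.0
        assert out.loc["gym", "complaint_volume"] == 4
        assert out.loc["store", "unit_share_pct"] == 50.0
        # sorted by sensitivity, descending
        assert list(out.index) == ["gym", "store"]


def test_end_to_end_scoring_matches_oracle_on_synthetic_city(small_city):
    _, poi, visits, complaints, _, _ = small_city
    units, uv, _ = pool_to_buildings(poi, visits)
    iv, _ = flag_complaints(bin_six_hour(uv, units), complaints)
    est, _ = score_units(iv, units)
    ref = oracle_scores(
        iv.drop(columns=["intensity"]).to_dict("records"),
        units.set_index("unit_id")["floor_area"].to_dict(),
        units.set_index("unit_id")["zip"].to_dict(),
    )
    assert set(est["unit_id"]) == set(ref)
    for _, row in est.iterrows():
        assert row["SDS"] == pytest.approx(ref[row["unit_id"]]["SDS"], abs=1e-12)
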