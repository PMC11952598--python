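"""Exposure strata, enrollment merging, ICD-10 grouping, daily aggregation."""

from datetime import date, timedelta

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from fireits.exposure import (
    AggregationError,
    CategorizationError,
    EnrollmentSpell,
    VisitRecord,
    aggregate_daily_counts,
    categorize_visit,
    classify_exposure,
    merge_enrollment_spells,
)
from fireits.synthetic import ArealUnit, FirePerimeter, generate_geography


def spell(start, end):
    return EnrollmentSpell("m1", start, end)


class TestEnrollment:
    @pytest.mark.parametrize(
        "spells, expected",
        [
            # 13-day gap <= 30: coalesce
            (
                [spell(date(2024, 1, 1), date(2024, 3, 1)), spell(date(2024, 3, 15), date(2024, 6, 1))],
                [(date(2024, 1, 1), date(2024, 6, 1))],
            ),
            # 60-day gap > 30: keep both
            (
                [spell(date(2024, 1, 1), date(2024, 3, 1)), spell(date(2024, 5, 1), date(2024, 6, 1))],
                [(date(2024, 1, 1), date(2024, 3, 1)), (date(2024, 5, 1), date(2024, 6, 1))],
            ),
            # overlapping: union
            (
                [spell(date(2024, 1, 1), date(2024, 3, 1)), spell(date(2024, 2, 1), date(2024, 4, 1))],
                [(date(2024, 1, 1), date(2024, 4, 1))],
            ),
        ],
    )
    def test_merge_examples(self, spells, expected):
        merged = merge_enrollment_spells(spells)
        assert [(s.start, s.end) for s in merged] == expected

    def test_invalid_spell_rejected(self):
        with pytest.raises(ValueError, match="start"):
            EnrollmentSpell("m1", date(2024, 2, 1), date(2024, 1, 1))

    def test_mixed_members_rejected(self):
        with pytest.raises(ValueError, match="one member"):
            merge_enrollment_spells(
                [EnrollmentSpell("a", date(2024, 1, 1), date(2024, 2, 1)),
                 EnrollmentSpell("b", date(2024, 3, 1), date(2024, 4, 1))]
            )

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(0, 60)),
            min_size=1,
            max_size=8,
        ),
        st.integers(0, 45),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_merge_idempotent_and_disjoint(self, raw, max_gap):
        base = date(2024, 1, 1)
        spells = [
            spell(base + timedelta(days=a), base + timedelta(days=a + b)) for a, b in raw
        ]
        once = merge_enrollment_spells(spells, max_gap_days=max_gap)
        twice = merge_enrollment_spells(once, max_gap_days=max_gap)
        assert once == twice
        for a, b in zip(once, once[1:]):
            assert (b.start - a.end).days - 1 > max_gap


FIRE = [FirePerimeter("f0", box(0.0, 0.0, 2000.0, 2000.0))]


def unit_at_km(uid, d_km, county="Los Angeles"):
    """1 km square due east of the fire at boundary distance d_km."""
    x0 = 2000.0 + d_km * 1000.0
    return ArealUnit(uid, box(x0, 0.0, x0 + 1000.0, 1000.0), county)


class TestClassifyExposure:
    def test_intersecting_unit_is_high_at_zero(self):
        unit = ArealUnit("u0", box(1000.0, 1000.0, 3000.0, 3000.0), "Los Angeles")
        (a,) = classify_exposure([unit], FIRE)
        assert a.distance_km == 0.0
        assert a.stratum == "high"

    def test_threshold_boundary_convention(self):
        # strictly below 20 km is high; exactly 20 km is moderate
        near, at = unit_at_km("near", 19.99), unit_at_km("at", 20.0)
        near_a, at_a = classify_exposure([near, at], FIRE)
        assert near_a.stratum == "high"
        assert at_a.stratum == "moderate"
        assert at_a.distance_km == pytest.approx(20.0, abs=1e-9)

    def test_far_outside_focal_county_is_minimal(self):
        (a,) = classify_exposure([unit_at_km("u", 35.0, county="Ventura")], FIRE)
        assert a.stratum == "minimal"

    def test_generated_mix_recovered_exactly(self):
        units, fires = generate_geography(n_fires=4, seed=2, class_mix=(10, 10, 5))
        strata = pd.Series([a.stratum for a in classify_exposure(units, fires)])
        assert strata.value_counts().to_dict() == {"high": 10, "moderate": 10, "minimal": 5}

    def test_partition_exhaustive_and_disjoint(self):
        units, fires = generate_geography(n_tracts=40, n_fires=3, seed=9)
        assignments = classify_exposure(units, fires)
        assert len(assignments) == len(units)
        assert {a.stratum for a in assignments} <= {"high", "moderate", "minimal"}

    def test_shrinking_threshold_never_promotes_to_high(self):
        units, fires = generate_geography(n_tracts=30, n_fires=3, seed=5)
        wide = {a.unit_id: a.stratum for a in classify_exposure(units, fires, threshold_km=25)}
        narrow = {a.unit_id: a.stratum for a in classify_exposure(units, fires, threshold_km=15)}
        for uid, s in narrow.items():
            if s == "high":
                assert wide[uid] == "high"

    def test_empty_perimeters_rejected(self):
        with pytest.raises(ValueError, match="perimeter"):
            classify_exposure([unit_at_km("u", 5.0)], [])

    def test_centroid_mode_uses_centroid_distance(self):
        u = unit_at_km("u", 19.6)  # boundary 19.6 km, centroid 20.1 km
        (boundary,) = classify_exposure([u], FIRE)
        (centroid,) = classify_exposure([u], FIRE, mode="centroid")
        assert boundary.stratum == "high"
        assert centroid.stratum == "moderate"


class TestCategorizeVisit:
    @pytest.mark.parametrize(
        "code, specific",
        [
            ("I00", "cardiovascular"),
            ("I21.9", "cardiovascular"),
            ("I99.9", "cardiovascular"),
            ("S00.0", "injury"),
            ("S99", "injury"),
            ("T00", "injury"),
            ("T88.9", "injury"),
            ("F01", "neuropsychiatric"),
            ("F99", "neuropsychiatric"),
            ("J00", "respiratory"),
            ("J99.8", "respiratory"),
        ],
    )
    def test_specific_ranges(self, code, specific):
        assert categorize_visit(code) == frozenset({"all_cause", specific})

    @pytest.mark.parametrize("code", ["T89", "T99.9", "F00.0", "U07.1", "Z00.00", "K21.9"])
    def test_all_cause_only_outside_ranges(self, code):
        assert categorize_visit(code) == frozenset({"all_cause"})

    @pytest.mark.parametrize("code", ["", "123", "I2", "I-21", "icd", "I21..9"])
    def test_malformed_rejected(self, code):
        with pytest.raises(CategorizationError):
            categorize_visit(code)

    def test_lowercase_normalized(self):
        assert "respiratory" in categorize_visit("j45.909")


# 50 ICD-coded visit records over 2025-01-05..09 with a frozen hand tally
# (records outside no calendar day; independent tally kept in sync with the
# literal below, counting each record toward all-cause plus its range).
ICD_RECORDS = [
    ("m00", "2025-01-08", "outpatient", "I00", "u_min"),
    ("m01", "2025-01-05", "virtual", "I99.9", "u_high"),
    ("m02", "2025-01-07", "outpatient", "I21.4", "u_high"),
    ("m03", "2025-01-07", "virtual", "S00.0", "u_min"),
    ("m04", "2025-01-09", "virtual", "S99.9", "u_high"),
    ("m05", "2025-01-06", "outpatient", "T00", "u_high"),
    ("m06", "2025-01-07", "virtual", "T88.9", "u_min"),
    ("m07", "2025-01-07", "virtual", "T89.0", "u_min"),
    ("m08", "2025-01-09", "virtual", "T99", "u_mod"),
    ("m09", "2025-01-08", "outpatient", "F00.0", "u_min"),
    ("m10", "2025-01-06", "outpatient", "F01.5", "u_mod"),
    ("m11", "2025-01-07", "virtual", "F99", "u_high"),
    ("m12", "2025-01-05", "virtual", "F32.9", "u_mod"),
    ("m13", "2025-01-09", "virtual", "J00", "u_min"),
    ("m14", "2025-01-09", "virtual", "J99.8", "u_mod"),
    ("m15", "2025-01-07", "outpatient", "J45.909", "u_min"),
    ("m16", "2025-01-07", "virtual", "U07.1", "u_min"),
    ("m17", "2025-01-06", "virtual", "Z00.00", "u_mod"),
    ("m18", "2025-01-05", "virtual", "A09", "u_min"),
    ("m19", "2025-01-09", "outpatient", "E11.9", "u_min"),
    ("m20", "2025-01-08", "virtual", "K21.9", "u_mod"),
    ("m21", "2025-01-08", "outpatient", "J44.1", "u_mod"),
    ("m22", "2025-01-09", "outpatient", "Z23", "u_mod"),
    ("m23", "2025-01-06", "virtual", "J44.1", "u_min"),
    ("m24", "2025-01-08", "virtual", "I50.9", "u_high"),
    ("m25", "2025-01-08", "outpatient", "J18.9", "u_mod"),
    ("m26", "2025-01-08", "virtual", "K21.9", "u_high"),
    ("m27", "2025-01-09", "outpatient", "I50.9", "u_mod"),
    ("m28", "2025-01-07", "outpatient", "F41.1", "u_high"),
    ("m29", "2025-01-09", "outpatient", "Z23", "u_min"),
    ("m30", "2025-01-08", "outpatient", "T14.90", "u_high"),
    ("m31", "2025-01-09", "virtual", "J44.1", "u_mod"),
    ("m32", "2025-01-05", "outpatient", "J44.1", "u_min"),
    ("m33", "2025-01-09", "virtual", "J18.9", "u_mod"),
    ("m34", "2025-01-06", "outpatient", "T14.90", "u_mod"),
    ("m35", "2025-01-07", "virtual", "Z23", "u_min"),
    ("m36", "2025-01-08", "virtual", "T14.90", "u_mod"),
    ("m37", "2025-01-06", "virtual", "I50.9", "u_min"),
    ("m38", "2025-01-06", "outpatient", "J18.9", "u_mod"),
    ("m39", "2025-01-09", "outpatient", "J18.9", "u_high"),
    ("m40", "2025-01-07", "virtual", "J18.9", "u_min"),
    ("m41", "2025-01-09", "virtual", "I10", "u_mod"),
    ("m42", "2025-01-09", "virtual", "F20.9", "u_min"),
    ("m43", "2025-01-09", "virtual", "J44.1", "u_mod"),
    ("m44", "2025-01-06", "virtual", "F41.1", "u_min"),
    ("m45", "2025-01-06", "virtual", "J44.1", "u_min"),
    ("m46", "2025-01-08", "virtual", "S72.0", "u_high"),
    ("m47", "2025-01-08", "outpatient", "T14.90", "u_high"),
    ("m48", "2025-01-06", "virtual", "J18.9", "u_min"),
    ("m49", "2025-01-06", "outpatient", "J44.1", "u_min"),
]

ICD_EXPECTED = {
    ("2025-01-05", "high", "virtual", "all_cause"): 1,
    ("2025-01-05", "high", "virtual", "cardiovascular"): 1,
    ("2025-01-05", "minimal", "outpatient", "all_cause"): 1,
    ("2025-01-05", "minimal", "outpatient", "respiratory"): 1,
    ("2025-01-05", "minimal", "virtual", "all_cause"): 1,
    ("2025-01-05", "moderate", "virtual", "all_cause"): 1,
    ("2025-01-05", "moderate", "virtual", "neuropsychiatric"): 1,
    ("2025-01-06", "high", "outpatient", "all_cause"): 1,
    ("2025-01-06", "high", "outpatient", "injury"): 1,
    ("2025-01-06", "minimal", "outpatient", "all_cause"): 1,
    ("2025-01-06", "minimal", "outpatient", "respiratory"): 1,
    ("2025-01-06", "minimal", "virtual", "all_cause"): 5,
    ("2025-01-06", "minimal", "virtual", "cardiovascular"): 1,
    ("2025-01-06", "minimal", "virtual", "neuropsychiatric"): 1,
    ("2025-01-06", "minimal", "virtual", "respiratory"): 3,
    ("2025-01-06", "moderate", "outpatient", "all_cause"): 3,
    ("2025-01-06", "moderate", "outpatient", "injury"): 1,
    ("2025-01-06", "moderate", "outpatient", "neuropsychiatric"): 1,
    ("2025-01-06", "moderate", "outpatient", "respiratory"): 1,
    ("2025-01-06", "moderate", "virtual", "all_cause"): 1,
    ("2025-01-07", "high", "outpatient", "all_cause"): 2,
    ("2025-01-07", "high", "outpatient", "cardiovascular"): 1,
    ("2025-01-07", "high", "outpatient", "neuropsychiatric"): 1,
    ("2025-01-07", "high", "virtual", "all_cause"): 1,
    ("2025-01-07", "high", "virtual", "neuropsychiatric"): 1,
    ("2025-01-07", "minimal", "outpatient", "all_cause"): 1,
    ("2025-01-07", "minimal", "outpatient", "respiratory"): 1,
    ("2025-01-07", "minimal", "virtual", "all_cause"): 6,
    ("2025-01-07", "minimal", "virtual", "injury"): 2,
    ("2025-01-07", "minimal", "virtual", "respiratory"): 1,
    ("2025-01-08", "high", "outpatient", "all_cause"): 2,
    ("2025-01-08", "high", "outpatient", "injury"): 2,
    ("2025-01-08", "high", "virtual", "all_cause"): 3,
    ("2025-01-08", "high", "virtual", "cardiovascular"): 1,
    ("2025-01-08", "high", "virtual", "injury"): 1,
    ("2025-01-08", "minimal", "outpatient", "all_cause"): 2,
    ("2025-01-08", "minimal", "outpatient", "cardiovascular"): 1,
    ("2025-01-08", "moderate", "outpatient", "all_cause"): 2,
    ("2025-01-08", "moderate", "outpatient", "respiratory"): 2,
    ("2025-01-08", "moderate", "virtual", "all_cause"): 2,
    ("2025-01-08", "moderate", "virtual", "injury"): 1,
    ("2025-01-09", "high", "outpatient", "all_cause"): 1,
    ("2025-01-09", "high", "outpatient", "respiratory"): 1,
    ("2025-01-09", "high", "virtual", "all_cause"): 1,
    ("2025-01-09", "high", "virtual", "injury"): 1,
    ("2025-01-09", "minimal", "outpatient", "all_cause"): 2,
    ("2025-01-09", "minimal", "virtual", "all_cause"): 2,
    ("2025-01-09", "minimal", "virtual", "neuropsychiatric"): 1,
    ("2025-01-09", "minimal", "virtual", "respiratory"): 1,
    ("2025-01-09", "moderate", "outpatient", "all_cause"): 2,
    ("2025-01-09", "moderate", "outpatient", "cardiovascular"): 1,
    ("2025-01-09", "moderate", "virtual", "all_cause"): 6,
    ("2025-01-09", "moderate", "virtual", "cardiovascular"): 1,
    ("2025-01-09", "moderate", "virtual", "respiratory"): 4,
}

ASSIGNMENTS = [
    a
    for a in classify_exposure(
        [
            unit_at_km("u_high", 5.0),
            unit_at_km("u_mod", 25.0),
            unit_at_km("u_min", 30.0, county="Ventura"),
        ],
        FIRE,
    )
]

CAL5 = pd.date_range("2025-01-05", "2025-01-09", freq="D")


def _records():
    return [
        VisitRecord(m, pd.Timestamp(d).date(), mod, code, unit)
        for m, d, mod, code, unit in ICD_RECORDS
    ]


class TestAggregation:
    def test_three_records_same_cell(self):
        recs = [
            VisitRecord(f"m{i}", date(2025, 1, 6), "virtual", "J18.9", "u_high")
            for i in range(3)
        ]
        cube = aggregate_daily_counts(recs, ASSIGNMENTS, CAL5)
        row = cube[
            (cube["date"] == "2025-01-06")
            & (cube["stratum"] == "high")
            & (cube["modality"] == "virtual")
            & (cube["cause"] == "respiratory")
        ]
        assert row["count"].item() == 3

    def test_empty_records_full_zero_cube(self):
        cube = aggregate_daily_counts([], ASSIGNMENTS, CAL5)
        assert len(cube) == 5 * 3 * 2 * 5
        assert (cube["count"] == 0).all()

    def test_unassigned_unit_rejected(self):
        rec = VisitRecord("m", date(2025, 1, 6), "virtual", "J18.9", "nowhere")
        with pytest.raises(AggregationError, match="nowhere"):
            aggregate_daily_counts([rec], ASSIGNMENTS, CAL5)

    def test_fixture_cube_matches_hand_tally(self):
        cube = aggregate_daily_counts(_records(), ASSIGNMENTS, CAL5)
        got = {
            (r.date.strftime("%Y-%m-%d"), r.stratum, r.modality, r.cause): r.count
            for r in cube.itertuples()
            if r.count > 0
        }
        assert got == ICD_EXPECTED

    def test_specific_causes_never_exceed_all_cause(self):
        cube = aggregate_daily_counts(_records(), ASSIGNMENTS, CAL5)
        wide = cube.pivot_table(
            index=["date", "stratum", "modality"], columns="cause", values="count"
        )
        specific = wide.drop(columns="all_cause").sum(axis=1)
        assert (specific <= wide["all_cause"]).all()
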