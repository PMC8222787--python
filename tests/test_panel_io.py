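"""Panel data model, CSV round-trips, class labels and the LOD filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trajdope as td
from trajdope.panel import (
    CONTROL,
    LongitudinalPanel,
    PanelParseError,
    PanelSchemaError,
    PanelValidationError,
    assign_classes,
    lod_filter,
    read_panel,
    write_panel,
)
from trajdope.schema import AnalyteDef, Block, read_schema, write_schema


def small_schema():
    return [
        AnalyteDef("WBC", Block.CBC, "10^9/L", None, 6.0, 0.2, 0.05),
        AnalyteDef("Androsterone", Block.STEROID, "ng/mL", 1.0, 2400.0, 0.5, 0.1),
        AnalyteDef("IGF-I", Block.ENDOCRINE, "ng/mL", None, 200.0, 0.25, 0.06),
    ]


def make_panel(rows):
    rec = pd.DataFrame(
        rows, columns=["subject_id", "arm", "day", "analyte", "value", "below_lod"]
    )
    return LongitudinalPanel(schema=small_schema(), records=rec)


class TestRoundTrip:
    def test_default_cohort_round_trips_exactly(self, default_panel, tmp_path):
        path = write_panel(default_panel, tmp_path / "panel.csv")
        back = read_panel(path, default_panel.schema)
        a = back.records.sort_values(["subject_id", "day", "analyte"]).reset_index(drop=True)
        b = default_panel.records.sort_values(["subject_id", "day", "analyte"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns], check_exact=True)
        assert len(back.sample_keys()) == 56

    def test_write_is_byte_stable(self, default_panel, tmp_path):
        p1 = write_panel(default_panel, tmp_path / "a.csv")
        # shuffle record order: output must not change
        shuffled = LongitudinalPanel(
            schema=default_panel.schema,
            records=default_panel.records.sample(frac=1.0, random_state=3),
        )
        p2 = write_panel(shuffled, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_below_lod_records_serialize_as_empty_cells(self, tmp_path):
        panel = make_panel(
            [
                ("S1", "EPO", 0, "Androsterone", np.nan, True),
                ("S1", "EPO", 0, "WBC", 5.5, False),
            ]
        )
        path = write_panel(panel, tmp_path / "p.csv")
        text = path.read_text()
        assert ",,true" in text.replace('"', "")
        back = read_panel(path, panel.schema)
        row = back.records[back.records.analyte == "Androsterone"].iloc[0]
        assert np.isnan(row.value) and bool(row.below_lod)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(data=st.data())
    def test_random_panels_round_trip(self, data, tmp_path_factory):
        days = [0, 4, 11]
        subjects = data.draw(
            st.lists(
                st.sampled_from([("S1", "EPO"), ("S2", "EGH"), ("S3", "EPO")]),
                min_size=1, max_size=3, unique=True,
            )
        )
        rows = []
        for subject, arm in subjects:
            for day in days:
                for a in small_schema():
                    v = data.draw(
                        st.floats(
                            min_value=1e-6, max_value=1e6,
                            allow_nan=False, allow_infinity=False,
                        )
                    )
                    rows.append((subject, arm, day, a.name, v, False))
        panel = make_panel(rows)
        path = tmp_path_factory.mktemp("rt") / "p.csv"
        back = read_panel(write_panel(panel, path), panel.schema)
        merged = back.records.merge(
            panel.records, on=["subject_id", "day", "analyte"], suffixes=("_a", "_b")
        )
        assert len(merged) == len(panel.records)
        assert (merged.value_a == merged.value_b).all()


class TestReadErrors:
    def test_header_only_file_gives_empty_panel(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("subject_id,arm,day,analyte,value,below_lod\n")
        panel = read_panel(p, small_schema())
        assert len(panel.records) == 0

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject_id,arm,day,analyte,value\nS1,EPO,0,WBC,5\n")
        with pytest.raises(PanelSchemaError, match="below_lod"):
            read_panel(p, small_schema())

    def test_unknown_analyte_listed(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "subject_id,arm,day,analyte,value,below_lod\n"
            "S1,EPO,0,NOPE,5,false\n"
        )
        with pytest.raises(PanelValidationError, match="NOPE"):
            read_panel(p, small_schema())

    def test_non_numeric_value_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "subject_id,arm,day,analyte,value,below_lod\n"
            "S1,EPO,0,WBC,abc,false\n"
        )
        with pytest.raises(PanelParseError, match="2"):
            read_panel(p, small_schema())

    def test_duplicate_record_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "subject_id,arm,day,analyte,value,below_lod\n"
            "S1,EPO,0,WBC,5,false\nS1,EPO,0,WBC,6,false\n"
        )
        with pytest.raises(PanelValidationError, match="duplicate"):
            read_panel(p, small_schema())

    def test_third_arm_rejected(self):
        with pytest.raises(PanelValidationError, match="arm"):
            make_panel([("S1", "PLACEBO", 0, "WBC", 5.0, False)])

    def test_negative_day_rejected(self):
        with pytest.raises(PanelValidationError, match="negative"):
            make_panel([("S1", "EPO", 0, "WBC", 5.0, False),
                        ("S1", "EPO", -1, "WBC", 5.0, False)])

    def test_missing_baseline_rejected(self):
        with pytest.raises(PanelValidationError, match="day-0"):
            make_panel([("S1", "EPO", 4, "WBC", 5.0, False)])


class TestSchemaFile:
    def test_schema_json_round_trip(self, tmp_path):
        schema = small_schema()
        back = read_schema(write_schema(schema, tmp_path / "schema.json"))
        assert back == schema


class TestAssignClasses:
    def test_day0_is_control_for_both_arms(self):
        panel = make_panel(
            [
                ("S1", "EGH", 0, "WBC", 5.0, False),
                ("S1", "EGH", 4, "WBC", 5.0, False),
                ("S2", "EPO", 0, "WBC", 5.0, False),
            ]
        )
        labels = assign_classes(panel)
        assert labels[("S1", 0)] == CONTROL
        assert labels[("S1", 4)] == "EGH"
        assert labels[("S2", 0)] == CONTROL

    def test_default_design_counts(self, default_panel):
        labels = assign_classes(default_panel)
        counts = pd.Series(list(labels.values())).value_counts().to_dict()
        assert counts == {"CONTROL": 14, "EPO": 21, "EGH": 21}
        assert len(labels) == 56

    def test_labels_partition_all_samples(self, default_panel):
        labels = assign_classes(default_panel)
        assert set(labels) == set(default_panel.sample_keys())
        assert set(labels.values()) == {"CONTROL", "EPO", "EGH"}


class TestLodFilter:
    def test_default_cohort_retains_28_steroids(self, default_panel):
        filtered, dropped = lod_filter(default_panel, 0.5)
        assert len(dropped) == 5
        steroids = [a for a in filtered.schema if a.block == Block.STEROID]
        assert len(steroids) == 28
        assert len(filtered.schema) == 63

    def test_no_censoring_is_identity(self):
        panel = make_panel([("S1", "EPO", 0, "WBC", 5.0, False)])
        filtered, dropped = lod_filter(panel, 0.5)
        assert dropped == []
        pd.testing.assert_frame_equal(filtered.records, panel.records)

    def test_fully_censored_analyte_dropped_at_high_threshold(self):
        panel = make_panel(
            [
                ("S1", "EPO", 0, "WBC", 5.0, False),
                ("S1", "EPO", 0, "Androsterone", np.nan, True),
            ]
        )
        filtered, dropped = lod_filter(panel, 0.99)
        assert dropped == ["Androsterone"]
        assert "Androsterone" not in {a.name for a in filtered.schema}

    def test_surviving_censored_values_imputed_at_half_lod(self):
        panel = make_panel(
            [
                ("S1", "EPO", 0, "Androsterone", np.nan, True),
                ("S1", "EPO", 4, "Androsterone", 100.0, False),
                ("S2", "EPO", 0, "Androsterone", 90.0, False),
                ("S2", "EPO", 4, "Androsterone", 95.0, False),
            ]
        )
        filtered, dropped = lod_filter(panel, 0.5)
        assert dropped == []
        row = filtered.records[
            (filtered.records.subject_id == "S1") & (filtered.records.day == 0)
        ].iloc[0]
        assert row.value == 0.5  # lod=1.0 for Androsterone in small_schema

    def test_idempotent(self, default_panel):
        once, dropped1 = lod_filter(default_panel, 0.5)
        twice, dropped2 = lod_filter(once, 0.5)
        assert dropped2 == []
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_never_removes_samples(self, default_panel):
        filtered, _ = lod_filter(default_panel, 0.5)
        assert filtered.sample_keys() == default_panel.sample_keys()
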