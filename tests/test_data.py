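"""Roster and scan-table parsing, validation, and round-tripping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scannet.data import (
    FormatError,
    Individual,
    Roster,
    Scan,
    ScanRecordSet,
    ValidationError,
    assign_age_class,
    make_scan,
    read_roster_table,
    read_scan_table,
    validate_records,
    write_roster_table,
    write_scan_table,
)
from scannet.simulate import default_roster, default_params, simulate_scans

from conftest import random_records


class TestRoster:
    def test_read_simple_roster(self, tmp_path, roster5):
        path = tmp_path / "roster.csv"
        write_roster_table(roster5, path)
        back = read_roster_table(path)
        assert len(back) == 5
        assert back.group_ids == ("MS1",)
        assert back["Ada"].deprivation_class == "ND"

    def test_duplicate_id_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "id": ["Gust", "Gust", "Mia"],
                "group_id": ["G"] * 3,
                "sex": ["male", "male", "female"],
                "age_class": ["mature"] * 3,
                "deprivation_class": ["ND"] * 3,
            }
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="Gust"):
            read_roster_table(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"id": ["A"], "group_id": ["G"]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_roster_table(path)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError):
            Individual("A", "G", "female", "juvenile", "ND")
        with pytest.raises(ValidationError):
            Individual("A", "G", "female", "mature", "XYZ")

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            Roster((Individual("A", "G", "female", "mature", "ND"),))

    def test_study_class_counts(self):
        """The default study roster reproduces the class sizes 10/8/7/16."""
        counts = default_roster().class_counts()
        assert (counts["ELD"], counts["LLD"], counts["EMD"], counts["ND"]) == (10, 8, 7, 16)

    @pytest.mark.parametrize(
        "sex,age,expected",
        [
            ("female", 13, "mature"),
            ("female", 33, "mature"),
            ("male", 16, "mature"),
            ("male", 33, "mature"),
            ("female", 34, "old"),
            ("male", 50, "old"),
        ],
    )
    def test_age_class_rule(self, sex, age, expected):
        assert assign_age_class(sex, age) == expected

    def test_age_below_adult_threshold(self):
        with pytest.raises(ValueError):
            assign_age_class("male", 15)


class TestScanTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "scans.csv"
        pd.DataFrame(
            rows, columns=["group", "period", "scan", "behaviour", "actor", "recipient"]
        ).to_csv(path, index=False)
        return path

    def test_single_scan_parse(self, tmp_path, roster5):
        path = self._write(
            tmp_path,
            [
                ("MS1", "2003", 1, "proximity", "Ada", "Bert"),
                ("MS1", "2003", 1, "grooming", "Ada", "Bert"),
            ],
        )
        records = read_scan_table(path, roster5)
        rs = records[("MS1", "2003")]
        assert rs.n_scans == 1
        assert rs.scans[0].proximity_pairs == frozenset({("Ada", "Bert")})
        assert rs.scans[0].grooming_events == frozenset({("Ada", "Bert")})

    def test_proximity_orientation_deduplicated(self, tmp_path, roster5):
        path = self._write(
            tmp_path,
            [
                ("MS1", "2003", 1, "proximity", "Ada", "Bert"),
                ("MS1", "2003", 1, "proximity", "Bert", "Ada"),
            ],
        )
        rs = read_scan_table(path, roster5)[("MS1", "2003")]
        assert rs.scans[0].proximity_pairs == frozenset({("Ada", "Bert")})

    def test_unknown_id_names_offender(self, tmp_path, roster5):
        path = self._write(tmp_path, [("MS1", "2003", 1, "proximity", "ZZ", "Ada")])
        with pytest.raises(ValidationError, match="'ZZ'"):
            read_scan_table(path, roster5)

    def test_self_pair_rejected_with_row(self, tmp_path, roster5):
        path = self._write(tmp_path, [("MS1", "2003", 1, "grooming", "Ada", "Ada")])
        with pytest.raises(ValidationError, match="row 1"):
            read_scan_table(path, roster5)

    def test_row_order_insensitive(self, tmp_path, roster5):
        rows = [
            ("MS1", "2003", 2, "grooming", "Cleo", "Dino"),
            ("MS1", "2003", 1, "proximity", "Ada", "Bert"),
            ("MS1", "2003", 2, "proximity", "Erna", "Ada"),
            ("MS1", "2003", 1, "grooming", "Bert", "Ada"),
        ]
        a = read_scan_table(self._write(tmp_path, rows), roster5)
        b = read_scan_table(self._write(tmp_path, rows[::-1]), roster5)
        assert a == b

    def test_round_trip_preserves_scans(self, tmp_path, roster5):
        rng = np.random.default_rng(7)
        original = random_records(roster5, "MS1", 20, rng)
        path = tmp_path / "out.csv"
        write_scan_table([original], path)
        back = read_scan_table(path, roster5)[("MS1", "P1")]
        assert back == original

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_scans=st.integers(1, 15))
    def test_round_trip_property(self, seed, n_scans, tmp_path_factory):
        """Write-then-read reproduces any simulated record set, including
        scans with no events."""
        roster = default_roster()
        rs = simulate_scans(
            roster, default_params(), n_scans, seed, group_id="S1", period_id="p"
        )
        path = tmp_path_factory.mktemp("rt") / "scans.csv"
        write_scan_table([rs], path)
        assert read_scan_table(path, roster)[("S1", "p")] == rs


class TestValidateRecords:
    def test_clean_set_reports_zero_violations(self, roster5):
        rng = np.random.default_rng(0)
        rs = random_records(roster5, "MS1", 30, rng)
        report = validate_records(rs, roster5)
        assert report.ok
        assert report.n_scans == 30

    def test_injected_self_pair_reported(self, roster5):
        scans = (Scan(frozenset({("Ada", "Ada")}), frozenset()),)
        report = validate_records(ScanRecordSet("MS1", "2003", scans), roster5)
        assert [v.kind for v in report.violations] == ["self_pair"]
        assert report.violations[0].scan_index == 1

    def test_unknown_id_reported(self, roster5):
        scans = (Scan(frozenset(), frozenset({("Ada", "Ghost")})),)
        report = validate_records(ScanRecordSet("MS1", "2003", scans), roster5)
        assert any(v.kind == "unknown_id" for v in report.violations)

    def test_scan_count_reported(self, roster5):
        """A 543-scan set (the typical per-group effort) reports n_scans=543."""
        scans = tuple(make_scan([("Ada", "Bert")]) for _ in range(543))
        report = validate_records(ScanRecordSet("MS1", "2003", scans), roster5)
        assert report.n_scans == 543
        assert report.n_proximity_pairs == 543
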