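"""Response-table I/O, cleaning rules and sum scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ravenshort as rs
from ravenshort.errors import ConfigurationError, DataError, ParseError
from ravenshort.items import ALL_ITEMS, format_item_list, parse_item_label, sort_items

from conftest import make_matrix


class TestItemLabels:
    @pytest.mark.parametrize(
        "raw,expected",
        [("a1", "A1"), (" B12 ", "B12"), ("e7", "E7"), ("C05", None), ("F1", None), ("A13", None)],
    )
    def test_parse_and_reject(self, raw, expected):
        if expected is None:
            with pytest.raises(ParseError):
                parse_item_label(raw)
        else:
            assert parse_item_label(raw) == expected

    def test_canonical_order_and_count(self):
        assert len(ALL_ITEMS) == 60
        assert ALL_ITEMS[0] == "A1" and ALL_ITEMS[11] == "A12" and ALL_ITEMS[-1] == "E12"
        shuffled = ["E5", "A12", "B5"]
        assert sort_items(shuffled) == ["A12", "B5", "E5"]

    def test_format_item_list_report_style(self):
        items = ["E5", "A12", "B5", "B9"]
        assert format_item_list(items) == "A12, B5, B9, and E5"
        assert format_item_list(["A1", "A2"]) == "A1 and A2"
        assert format_item_list(["C3"]) == "C3"


class TestReadWrite:
    def test_roundtrip_identity(self, tmp_path):
        m = make_matrix(
            [[1, 0, 1], [0, 1, np.nan], [1, 1, 0]],
            items=["A1", "B2", "E12"],
            ages=[10.5, np.nan, 14.0],
            sources=["s1", "s1", "s2"],
        )
        path = tmp_path / "m.csv"
        rs.write_response_table(m, path)
        back = rs.read_response_table(path)
        assert back.equals(m)

    def test_tab_delimited_accepted(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("person_id\tage\tsource\tA1\tA2\np1\t12.0\ts\t1\t0\n")
        m = rs.read_response_table(path)
        assert m.administered_items == ["A1", "A2"]
        assert m.responses.loc["p1", "A1"] == 1.0

    def test_missing_cell_tokens(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("person_id,age,source,A1,A2,A3\np1,,s,1,,0\np2,13,s,NA,1,1\n")
        m = rs.read_response_table(path)
        assert np.isnan(m.responses.loc["p1", "A2"])
        assert np.isnan(m.responses.loc["p2", "A1"])
        assert m.responses.loc["p1", "A1"] == 1.0 and m.responses.loc["p1", "A3"] == 0.0
        assert np.isnan(m.ages.loc["p1"]) and m.ages.loc["p2"] == 13.0

    @pytest.mark.parametrize(
        "content,fragment",
        [
            ("person_id,F1\np1,1\n", "F1"),  # unknown item column
            ("person_id,A1,A1\np1,1,1\n", "duplicate header"),
            ("person_id,A1\np1,2\n", "non-binary"),
            ("person_id,A1\np1,1\np1,0\n", "duplicate person_id"),
            ("age,A1\n12,1\n", "person_id"),
        ],
    )
    def test_parse_errors_name_the_culprit(self, tmp_path, content, fragment):
        path = tmp_path / "bad.csv"
        path.write_text(content)
        with pytest.raises(ParseError, match=fragment):
            rs.read_response_table(path)

    def test_non_binary_error_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("person_id,A1,B3\np9,1,7\n")
        with pytest.raises(ParseError, match=r"p9.*B3"):
            rs.read_response_table(path)


class TestCleaning:
    def test_rules_remove_expected_counts(self, default_bank):
        cfg = rs.GeneratorConfig(
            n_persons=60,
            item_bank=default_bank,
            sources={"s": 60},
            age_models={"s": rs.AgeModel(mean=14.0, sd=0.5, min_age=13.0, max_age=16.0)},
            seed=3,
        )
        matrix = rs.simulate_responses(cfg)
        spec = rs.DefectSpec(n_missing_rows=4, n_duplicate_rows=2, n_underage_rows=3)
        dirty = rs.inject_defects(matrix, spec, seed=5)
        cleaned, report = rs.clean_responses(dirty, min_age=12.5)
        assert report.n_input == 62
        assert report.n_missing_removed == 4
        assert report.n_duplicates_removed == 2
        assert report.n_underage_removed == 3
        assert report.n_output == cleaned.n_persons == 53
        assert cleaned.is_complete()

    def test_defect_free_matrix_is_identity(self):
        m = make_matrix([[1, 0], [0, 1]], items=["A3", "A4"], ages=[13.0, 14.0])
        cleaned, report = rs.clean_responses(m, min_age=12.5)
        assert cleaned.equals(m)
        assert (
            report.n_missing_removed
            == report.n_duplicates_removed
            == report.n_underage_removed
            == 0
        )

    def test_rule_order_missing_beats_underage(self):
        # a row that is both missing-valued and under-age counts once, as missing
        m = make_matrix(
            [[np.nan, 1], [1, 0]], items=["A3", "A4"], ages=[10.0, 14.0]
        )
        _, report = rs.clean_responses(m, min_age=12.5)
        assert report.n_missing_removed == 1
        assert report.n_underage_removed == 0

    def test_practice_items_dropped_and_idempotent(self):
        m = make_matrix([[1, 0, 1], [0, 1, 1]], items=["A1", "A2", "A3"])
        cleaned, report = rs.clean_responses(m, practice_items=("A1", "A2"))
        assert cleaned.administered_items == ["A3"]
        assert report.practice_items_dropped == ["A1", "A2"]
        again, report2 = rs.clean_responses(cleaned, practice_items=("A1", "A2"))
        assert again.equals(cleaned)
        assert report2.practice_items_dropped == []
        assert report2.n_output == report2.n_input

    def test_age_filter_without_ages_is_config_error(self):
        m = make_matrix([[1, 0], [0, 1]], items=["A3", "A4"])  # all ages NaN
        with pytest.raises(ConfigurationError):
            rs.clean_responses(m, min_age=12.5)

    def test_unknown_age_passes_filter(self):
        m = make_matrix([[1, 0], [0, 1]], items=["A3", "A4"], ages=[np.nan, 14.0])
        cleaned, report = rs.clean_responses(m, min_age=12.5)
        assert cleaned.n_persons == 2 and report.n_underage_removed == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n_missing=st.integers(0, 5),
        n_dup=st.integers(0, 5),
        n_under=st.integers(0, 5),
        seed=st.integers(0, 10_000),
    )
    def test_report_arithmetic_and_idempotence(self, default_bank, n_missing, n_dup, n_under, seed):
        cfg = rs.GeneratorConfig(
            n_persons=30,
            item_bank=default_bank,
            sources={"s": 30},
            age_models={"s": rs.AgeModel(mean=14.0, sd=0.5, min_age=13.0, max_age=16.0)},
            seed=seed,
        )
        dirty = rs.inject_defects(
            rs.simulate_responses(cfg),
            rs.DefectSpec(n_missing, n_dup, n_under),
            seed=seed + 1,
        )
        cleaned, report = rs.clean_responses(dirty, min_age=12.5)
        assert (
            report.n_output
            == report.n_input
            - report.n_missing_removed
            - report.n_duplicates_removed
            - report.n_underage_removed
        )
        # cleaning a cleaned matrix removes nothing
        again, report2 = rs.clean_responses(cleaned, min_age=12.5)
        assert again.equals(cleaned)
        assert report2.n_input == report2.n_output

    def test_report_json_roundtrip(self):
        report = rs.CleaningReport(10, 1, 2, 3, 4, practice_items_dropped=["A1"])
        assert rs.CleaningReport.from_json(report.to_json()) == report

    def test_report_arithmetic_identity_enforced(self):
        with pytest.raises(DataError):
            rs.CleaningReport(10, 1, 1, 1, 9)


class TestSumScore:
    def test_saturation_and_floor(self):
        m = make_matrix([[1] * 4, [0] * 4], items=["A1", "A2", "A3", "A4"])
        sv = rs.sum_score(m)
        assert sv.max_possible == 4
        assert sv.scores.tolist() == [4, 0]

    def test_toy_subset_hand_sums(self):
        m = make_matrix(
            [[1, 0, 1, 1], [0, 1, 1, 0], [1, 1, 0, 0]],
            items=["A1", "B1", "C1", "D1"],
        )
        sv = rs.sum_score(m, ["A1", "C1"])
        assert sv.scores.tolist() == [2, 1, 1]  # by manual addition
        assert sv.max_possible == 2

    def test_partition_additivity(self, default_bank):
        cfg = rs.GeneratorConfig(n_persons=40, item_bank=default_bank, seed=9)
        m = rs.simulate_responses(cfg)
        items = m.administered_items
        total = rs.sum_score(m).to_numpy()
        part = (
            rs.sum_score(m, items[:20]).to_numpy()
            + rs.sum_score(m, items[20:45]).to_numpy()
            + rs.sum_score(m, items[45:]).to_numpy()
        )
        assert np.array_equal(total, part)

    def test_unadministered_item_error_names_it(self):
        m = make_matrix([[1, 0]], items=["A1", "A2"])
        with pytest.raises(DataError, match="E9"):
            rs.sum_score(m, ["A1", "E9"])

    def test_incomplete_matrix_rejected(self):
        m = make_matrix([[1, np.nan]], items=["A1", "A2"])
        with pytest.raises(DataError):
            rs.sum_score(m)
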