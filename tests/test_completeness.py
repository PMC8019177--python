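import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from dqframe.completeness import (
    item_missingness,
    qualified_rates,
    segment_missingness,
    unit_missingness,
)
from dqframe.core_model import load_metadata


def md_table(rows):
    return load_metadata(pd.DataFrame(rows))


@pytest.fixture(scope="module")
def simple_metadata():
    return md_table(
        [
            {"VAR_NAMES": "id", "DATA_TYPE": "integer", "ROLE": "identifier"},
            {"VAR_NAMES": "sbp", "DATA_TYPE": "integer",
             "MISSING_LIST": "99980 = refusal | 99901 = refusal at item",
             "STUDY_SEGMENT": "bp"},
            {"VAR_NAMES": "dbp", "DATA_TYPE": "integer",
             "MISSING_LIST": "99980 = refusal", "STUDY_SEGMENT": "bp"},
            {"VAR_NAMES": "height", "DATA_TYPE": "float",
             "STUDY_SEGMENT": "soma"},
            {"VAR_NAMES": "examiner", "DATA_TYPE": "integer",
             "ROLE": "process-examiner"},
        ]
    )


class TestUnitMissingness:
    def test_one_empty_record_of_ten(self, simple_metadata):
        study = pd.DataFrame(
            {
                "id": [str(i) for i in range(10)],
                "sbp": ["120"] * 9 + [None],
                "dbp": ["80"] * 9 + [None],
                "height": ["170"] * 9 + [None],
                "examiner": ["1"] * 10,
            }
        )
        res = unit_missingness(study, simple_metadata)
        assert res.n_flagged == 1
        assert res.percent == 10.0

    def test_no_empty_records(self, simple_metadata):
        study = pd.DataFrame(
            {"id": ["1"], "sbp": ["120"], "dbp": ["80"], "height": ["170"],
             "examiner": ["1"]}
        )
        assert unit_missingness(study, simple_metadata).n_flagged == 0

    def test_process_variables_do_not_count_as_data(self, simple_metadata):
        # only the examiner ID filled: still a unit without measurements
        study = pd.DataFrame(
            {"id": ["1"], "sbp": [None], "dbp": ["99980"], "height": [None],
             "examiner": ["3"]}
        )
        assert unit_missingness(study, simple_metadata).n_flagged == 1


class TestSegmentMissingness:
    def test_segment_all_missing(self, simple_metadata):
        study = pd.DataFrame(
            {
                "id": ["1", "2", "3", "4"],
                "sbp": [None, None, None, "120"],
                "dbp": [None, "99980", None, "80"],
                "height": ["170"] * 4,
                "examiner": ["1"] * 4,
            }
        )
        res = segment_missingness(study, simple_metadata)
        assert res["bp"].n_flagged == 3
        assert res["soma"].n_flagged == 0

    def test_partially_missing_segment_not_flagged(self, simple_metadata):
        study = pd.DataFrame(
            {"id": ["1"], "sbp": [None], "dbp": ["80"], "height": ["170"],
             "examiner": ["1"]}
        )
        res = segment_missingness(study, simple_metadata)
        assert res["bp"].n_flagged == 0


class TestItemMissingness:
    def test_breakdown_example(self, simple_metadata):
        study = pd.DataFrame(
            {
                "id": ["1", "2", "3"],
                "sbp": ["178", None, "99901"],
                "dbp": ["80", "85", "90"],
                "height": ["170", "171", "172"],
                "examiner": ["1", "1", "2"],
            }
        )
        breakdowns, res_2001, res_2005, res_1008 = item_missingness(
            study, simple_metadata
        )
        bd = breakdowns["sbp"]
        assert bd.n_system_missing == 1
        assert bd.per_code == {99901: 1}
        assert bd.n_observed == 1
        assert bd.conserved

    def test_uncertain_missingness_status(self, simple_metadata):
        # empty cells where a qualified code is declared -> DQI-1008
        study = pd.DataFrame(
            {
                "id": [str(i) for i in range(6)],
                "sbp": [None, None, None, None, "120", "121"],
                "dbp": ["80"] * 6,
                "height": ["170"] * 6,
                "examiner": ["1"] * 6,
            }
        )
        _, _, _, res_1008 = item_missingness(study, simple_metadata)
        assert res_1008.n_flagged == 4

    def test_staged_denominators(self, simple_metadata):
        # unit 1 fully missing, unit 2 missing the bp segment only
        study = pd.DataFrame(
            {
                "id": ["1", "2", "3", "4"],
                "sbp": [None, None, "120", "121"],
                "dbp": [None, None, "80", "81"],
                "height": [None, "170", "171", "172"],
                "examiner": ["1"] * 4,
            }
        )
        unit = unit_missingness(study, simple_metadata)
        unit_ids = {r for r, _ in unit.flagged_cells}
        assert unit_ids == {"1"}
        seg = segment_missingness(study, simple_metadata, exclude_units=unit_ids)
        seg_ids = {s: {r for r, _ in res.flagged_cells} for s, res in seg.items()}
        assert seg_ids["bp"] == {"2"}
        breakdowns, *_ = item_missingness(
            study, simple_metadata, unit_ids, seg_ids
        )
        assert breakdowns["sbp"].n_expected == 2  # 4 - unit - segment
        assert breakdowns["height"].n_expected == 3  # 4 - unit
        assert all(b.conserved for b in breakdowns.values())

    @given(
        pattern=st_h.lists(
            st_h.sampled_from(["120", "", "99980"]), min_size=1, max_size=12
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_conservation_property(self, pattern, simple_metadata):
        study = pd.DataFrame(
            {
                "id": [str(i) for i in range(len(pattern))],
                "sbp": [p if p else None for p in pattern],
                "dbp": ["80"] * len(pattern),
                "height": ["170"] * len(pattern),
                "examiner": ["1"] * len(pattern),
            }
        )
        breakdowns, *_ = item_missingness(study, simple_metadata)
        assert all(b.conserved for b in breakdowns.values())


class TestQualifiedRates:
    def test_nonresponse_rate(self, simple_metadata):
        study = pd.DataFrame(
            {
                "id": [str(i) for i in range(1, 81)],
                "sbp": ["120"] * 80,
                "dbp": ["80"] * 80,
                "height": ["170"] * 80,
                "examiner": ["1"] * 80,
            }
        )
        roster = [str(i) for i in range(1, 101)]
        res_2002, res_2003, _ = qualified_rates(
            study, simple_metadata, roster=roster
        )
        assert res_2002.percent == 20.0

    def test_all_refusal_unit_is_responder_but_refuser(self, simple_metadata):
        study = pd.DataFrame(
            {
                "id": ["1", "2"],
                "sbp": ["99980", "120"],
                "dbp": ["99980", "80"],
                "height": ["99980", "170"],
                "examiner": ["1", "1"],
            }
        )
        # height has no declared missing codes, so strip it from the frame
        study = study.drop(columns=["height"])
        res_2002, res_2003, _ = qualified_rates(
            study, simple_metadata, roster=["1", "2"]
        )
        assert res_2002.n_flagged == 0  # refusal IS obtained information
        assert res_2003.n_flagged == 1

    def test_dropout_prefix_vs_intermittent(self, simple_metadata):
        # segments ordered (soma, bp): unit 1 completes soma only ->
        # drop-out; unit 2 skips soma but completes bp -> intermittent
        study = pd.DataFrame(
            {
                "id": ["1", "2", "3"],
                "height": ["170", None, "171"],
                "sbp": [None, "120", "121"],
                "dbp": [None, "80", "81"],
                "examiner": ["1"] * 3,
            }
        )
        *_, res_2004 = qualified_rates(
            study, simple_metadata, segment_order=["soma", "bp"]
        )
        dropout_ids = {r for r, _ in res_2004.flagged_cells}
        assert dropout_ids == {"1"}

    def test_missing_roster_not_applicable(self, simple_metadata):
        study = pd.DataFrame(
            {"id": ["1"], "sbp": ["120"], "dbp": ["80"], "height": ["170"],
             "examiner": ["1"]}
        )
        res_2002, res_2003, _ = qualified_rates(study, simple_metadata)
        assert res_2002.grading == "not-applicable"
        assert res_2003.grading == "not-applicable"
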