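"""Consistency checks, including an exhaustive truth-table comparison
of every contradiction predicate template against an independent
brute-force evaluator."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dqframe.consistency import (
    contradictions,
    evaluate_rule,
    inadmissible_categorical,
    limit_deviations,
)
from dqframe.core_model import (
    ContradictionRule,
    PREDICATE_CODES,
    load_metadata,
    parse_interval,
)


def md_table(rows):
    return load_metadata(pd.DataFrame(rows))


class TestLimitDeviations:
    def setup_method(self):
        self.md = md_table(
            [{
                "VAR_NAMES": "x", "DATA_TYPE": "float",
                "HARD_LIMITS": "[0;200]", "SOFT_LIMITS": "[40;60]",
                "MISSING_LIST": "99980 = refusal",
            }]
        )["x"]

    def test_hard_violations_split_by_direction(self):
        col = pd.Series(["-1", "50", "250"])
        res = limit_deviations(col, self.md)
        assert res["hard"].n_flagged == 2
        assert res["hard"].descriptor["n_below"] == 1
        assert res["hard"].descriptor["n_above"] == 1

    def test_uncertain_values_inside_hard(self):
        col = pd.Series(["35", "50"])
        res = limit_deviations(col, self.md)
        assert res["hard"].n_flagged == 0
        assert res["soft"].n_flagged == 1

    def test_all_inside_soft(self):
        col = pd.Series(["45", "50", "55"])
        res = limit_deviations(col, self.md)
        assert res["hard"].n_flagged == 0
        assert res["soft"].n_flagged == 0

    def test_codes_are_not_violations(self):
        col = pd.Series(["99980", "50"])
        res = limit_deviations(col, self.md)
        assert res["hard"].n_flagged == 0
        assert res["hard"].denominator == 1

    def test_closedness_respected_exactly(self):
        md = md_table(
            [{"VAR_NAMES": "x", "DATA_TYPE": "float",
              "HARD_LIMITS": "[0;200)"}]
        )["x"]
        res = limit_deviations(pd.Series(["0", "200"]), md)
        assert res["hard"].n_flagged == 1  # 200 outside, 0 inside

    def test_hard_and_uncertain_sets_disjoint(self):
        col = pd.Series(["-5", "10", "50", "90", "300"])
        res = limit_deviations(col, self.md)
        hard_cells = set(res["hard"].flagged_cells)
        soft_cells = set(res["soft"].flagged_cells)
        assert not hard_cells & soft_cells
        assert len(hard_cells | soft_cells) <= 5

    def test_no_limits_not_applicable(self):
        md = md_table([{"VAR_NAMES": "x", "DATA_TYPE": "float"}])["x"]
        res = limit_deviations(pd.Series(["1"]), md)
        assert res["hard"].grading == "not-applicable"

    def test_datetime_limits(self):
        md = md_table(
            [{"VAR_NAMES": "d", "DATA_TYPE": "datetime",
              "HARD_LIMITS": "[2001-01-01;2001-12-31]"}]
        )["d"]
        col = pd.Series(["2001-06-15", "2002-03-01"])
        res = limit_deviations(col, md)
        assert res["hard"].indicator_id == "DQI-3002"
        assert res["hard"].n_flagged == 1


class TestInadmissibleCategorical:
    def setup_method(self):
        self.md = md_table(
            [{
                "VAR_NAMES": "c", "DATA_TYPE": "integer",
                "VALUE_LABELS": "1 = a | 2 = b | 3 = c",
                "MISSING_LIST": "99980 = refusal",
            }]
        )["c"]

    def test_surplus_level(self):
        res = inadmissible_categorical(pd.Series(["1", "2", "5"]), self.md)
        assert res.n_flagged == 1
        assert res.descriptor["surplus_levels"] == ["5"]

    def test_missing_code_not_flagged(self):
        res = inadmissible_categorical(pd.Series(["1", "99980"]), self.md)
        assert res.n_flagged == 0
        assert res.denominator == 1

    def test_empty_column_undefined_percent(self):
        res = inadmissible_categorical(pd.Series([None, None]), self.md)
        assert res.n_flagged == 0
        assert res.denominator == 0
        assert res.percent is None


# ---------------------------------------------------------------------------
# The 16-template truth-table oracle
# ---------------------------------------------------------------------------

# enumerated small domain: raw cell values covering every side condition
_POOL = [None, "99980", "1", "3", "15", "2001-06-15", "2002-06-15", "x"]

_PARAMS = {
    "cat": {1},
    "num": parse_interval("[0;10]"),
    "date": parse_interval("[2001-01-01;2001-12-31]", kind="datetime"),
    "miss": None,
}


def brute_force_side(value, kind):
    """Independent re-statement of one side condition on a raw cell."""
    qualified_missing = value is None or value == "99980"
    if kind == "miss":
        return qualified_missing
    if qualified_missing:
        return False
    if kind == "cat":
        try:
            return float(value) == 1
        except ValueError:
            return False
    if kind == "num":
        try:
            return 0 <= float(value) <= 10
        except ValueError:
            return False
    if kind == "date":
        if len(value) != 10 or value.count("-") != 2:
            return False
        return "2001-01-01" <= value <= "2001-12-31"
    raise AssertionError(kind)


@pytest.mark.parametrize("code", PREDICATE_CODES)
def test_predicate_truth_table_matches_brute_force(code):
    kind_a, kind_b = code.split("_")
    pairs = list(itertools.product(_POOL, _POOL))
    study = pd.DataFrame(
        {"a": [p[0] for p in pairs], "b": [p[1] for p in pairs]}
    )
    metadata = md_table(
        [
            {"VAR_NAMES": "a", "DATA_TYPE": "string",
             "MISSING_LIST": "99980 = refusal"},
            {"VAR_NAMES": "b", "DATA_TYPE": "string",
             "MISSING_LIST": "99980 = refusal"},
        ]
    )
    rule = ContradictionRule(
        rule_id="t", predicate_code=code, var_a="a", var_b="b",
        params_a=_PARAMS[kind_a], params_b=_PARAMS[kind_b],
    )
    fired = evaluate_rule(study, rule, metadata)
    expected = np.array(
        [
            brute_force_side(va, kind_a) and brute_force_side(vb, kind_b)
            for va, vb in pairs
        ]
    )
    mismatch = np.flatnonzero(fired != expected)
    assert mismatch.size == 0, [
        (pairs[i], bool(fired[i]), bool(expected[i])) for i in mismatch
    ]


class TestContradictionsAggregation:
    def test_split_by_rule_class(self):
        study = pd.DataFrame(
            {"sex": ["1", "1", "0"], "contra": ["1", "0", "1"],
             "age": ["30", "30", "60"]}
        )
        rules = [
            ContradictionRule("L1", "cat_cat", "sex", "contra", {1}, {1},
                              rule_class="logical"),
            ContradictionRule("E1", "cat_num", "contra", "age", {1},
                              parse_interval("[55;120]"),
                              rule_class="empirical"),
        ]
        res_log, res_emp, per_rule = contradictions(study, rules)
        assert per_rule == {"L1": 1, "E1": 1}
        assert res_log.indicator_id == "DQI-3008"
        assert res_emp.indicator_id == "DQI-3009"

    def test_disjoint_categories_never_fire(self):
        study = pd.DataFrame({"a": ["1", "1"], "b": ["2", "2"]})
        rule = ContradictionRule("r", "cat_cat", "a", "b", {2}, {1})
        _, _, per_rule = contradictions(study, [rule])
        assert per_rule == {"r": 0}

    def test_unknown_variable_skips_rule(self, caplog):
        study = pd.DataFrame({"a": ["1"]})
        rule = ContradictionRule("r", "cat_cat", "a", "zzz", {1}, {1})
        res_log, _, per_rule = contradictions(study, [rule])
        assert per_rule == {}
        assert res_log.grading == "not-applicable"
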