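"""Consistency: Boolean-type checks on single values and value pairs.

Range and value violations compare each data value against the
metadata's admissibility ranges (hard limits), plausibility ranges
(soft limits) and device censoring bounds (detection limits), or
against the set of admissible categories.  Contradiction rules compare
two data values of the same observational unit using one of 16
predicate templates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_model import (
    ContradictionRule,
    IndicatorResult,
    Interval,
    MetadataTable,
    VariableMetadata,
    code_mask,
    is_system_missing,
    numeric_values,
)
from .integrity import _record_ids

__all__ = [
    "limit_deviations",
    "inadmissible_categorical",
    "contradictions",
    "evaluate_rule",
]

logger = logging.getLogger(__name__)


def _typed_values(column: pd.Series, md: VariableMetadata):
    """Parsed values (float or Timestamp) with codes/missing as NaN/NaT."""
    sysmiss = is_system_missing(column)
    codes = code_mask(column, md.all_codes)
    if md.data_type == "datetime":
        vals = pd.to_datetime(column, errors="coerce", format="ISO8601")
    else:
        vals = numeric_values(column)
    vals = vals.where(~(sysmiss | codes))
    return vals, sysmiss | codes


def limit_deviations(
    column: pd.Series,
    md: VariableMetadata,
    record_ids: pd.Series | None = None,
) -> dict[str, IndicatorResult]:
    """Hard-, soft- and detection-limit deviations for one variable.

    Hard-limit violations are inadmissible values; values inside the
    hard limits but outside the soft limits are uncertain (improbable);
    values outside the detection limits indicate censoring and are
    reported separately (a device property, not an admissibility
    violation).  Counts are split above/below; qualified missing/jump
    codes never count as deviations.  The descriptor carries histogram
    data with the limit positions.
    """
    if not any((md.hard_limits, md.soft_limits, md.detection_limits)):
        na = IndicatorResult(
            indicator_id="DQI-3001" if md.is_numeric else "DQI-3002",
            variable=md.var_name, grading="not-applicable",
        )
        return {"hard": na}

    vals, excluded = _typed_values(column, md)
    nonmiss = vals.notna().to_numpy()
    if record_ids is None:
        record_ids = pd.Series(column.index.astype(str), index=column.index)

    hard_id = "DQI-3002" if md.data_type == "datetime" else "DQI-3001"
    soft_id = "DQI-3007" if md.data_type == "datetime" else "DQI-3006"
    out: dict[str, IndicatorResult] = {}

    def split_counts(interval: Interval):
        inside = interval.contains_array(vals)
        below = np.zeros(len(vals), dtype=bool)
        above = np.zeros(len(vals), dtype=bool)
        outside = nonmiss & ~inside
        if outside.any():
            lo_cmp = vals < interval.lower
            lo_eq = (vals == interval.lower) & (not interval.lower_closed)
            below = outside & (lo_cmp | lo_eq).fillna(False).to_numpy()
            above = outside & ~below
        return below, above

    hard_below = hard_above = np.zeros(len(vals), dtype=bool)
    if md.hard_limits is not None:
        hard_below, hard_above = split_counts(md.hard_limits)
        bad = hard_below | hard_above
        out["hard"] = IndicatorResult(
            indicator_id=hard_id,
            variable=md.var_name,
            n_flagged=int(bad.sum()),
            denominator=int(nonmiss.sum()),
            flagged_cells=[
                (record_ids.iloc[i], md.var_name) for i in np.flatnonzero(bad)
            ],
            descriptor={
                "n_below": int(hard_below.sum()),
                "n_above": int(hard_above.sum()),
                "limits": str(md.hard_limits),
            },
        )
    if md.soft_limits is not None:
        s_below, s_above = split_counts(md.soft_limits)
        # uncertain: outside soft but inside hard
        inside_hard = (
            md.hard_limits.contains_array(vals)
            if md.hard_limits is not None
            else nonmiss
        )
        unc_below = s_below & inside_hard
        unc_above = s_above & inside_hard
        bad = unc_below | unc_above
        out["soft"] = IndicatorResult(
            indicator_id=soft_id,
            variable=md.var_name,
            n_flagged=int(bad.sum()),
            denominator=int(nonmiss.sum()),
            flagged_cells=[
                (record_ids.iloc[i], md.var_name) for i in np.flatnonzero(bad)
            ],
            descriptor={
                "n_below": int(unc_below.sum()),
                "n_above": int(unc_above.sum()),
                "limits": str(md.soft_limits),
            },
        )
    if md.detection_limits is not None:
        d_below, d_above = split_counts(md.detection_limits)
        bad = d_below | d_above
        out["detection"] = IndicatorResult(
            indicator_id=hard_id,
            variable=md.var_name,
            n_flagged=int(bad.sum()),
            denominator=int(nonmiss.sum()),
            flagged_cells=[
                (record_ids.iloc[i], md.var_name) for i in np.flatnonzero(bad)
            ],
            descriptor={
                "censoring": True,
                "n_below": int(d_below.sum()),
                "n_above": int(d_above.sum()),
                "limits": str(md.detection_limits),
            },
            grading="ok" if not bad.any() else "issue",
        )

    # histogram descriptor for the report
    if md.is_numeric and nonmiss.any():
        numeric = vals[nonmiss].astype(float)
        counts, edges = np.histogram(numeric, bins=min(30, max(5, int(np.sqrt(nonmiss.sum())))))
        ref = out.get("hard") or next(iter(out.values()))
        ref.descriptor = dict(ref.descriptor or {})
        ref.descriptor["histogram"] = {
            "counts": counts.tolist(),
            "edges": [float(e) for e in edges],
        }
    return out


def inadmissible_categorical(
    column: pd.Series,
    md: VariableMetadata,
    record_ids: pd.Series | None = None,
) -> IndicatorResult:
    """Values outside the admissible categories (qualified codes are
    not violations).  The descriptor tabulates observed vs expected
    levels including the surplus ones."""
    if not md.admissible_categories:
        return IndicatorResult(
            indicator_id="DQI-3003", variable=md.var_name,
            grading="not-applicable",
        )
    sysmiss = is_system_missing(column)
    codes = code_mask(column, md.all_codes)
    relevant = ~(sysmiss | codes)
    if record_ids is None:
        record_ids = pd.Series(column.index.astype(str), index=column.index)

    admissible = np.zeros(len(column), dtype=bool)
    admissible[relevant] = code_mask(
        column[relevant], set(md.admissible_categories)
    ) if relevant.any() else False
    bad = relevant & ~admissible

    observed_levels = (
        column[relevant].astype(str).str.strip().value_counts().to_dict()
    )
    surplus = sorted(
        lev
        for lev in observed_levels
        if not code_mask(pd.Series([lev]), set(md.admissible_categories))[0]
    )
    return IndicatorResult(
        indicator_id="DQI-3003",
        variable=md.var_name,
        n_flagged=int(bad.sum()),
        denominator=int(relevant.sum()),
        flagged_cells=[
            (record_ids.iloc[i], md.var_name) for i in np.flatnonzero(bad)
        ],
        descriptor={
            "observed_levels": observed_levels,
            "expected_levels": {
                str(k): v for k, v in md.admissible_categories.items()
            },
            "surplus_levels": surplus,
        },
    )


# ---------------------------------------------------------------------------
# Contradictions
# ---------------------------------------------------------------------------

def _side_mask(
    column: pd.Series, md: VariableMetadata | None, kind: str, params
) -> np.ndarray:
    """Truth vector of one side condition.

    Value-membership sides (cat/num/date) are False wherever the cell
    is system- or qualified-missing; the 'miss' side is True exactly
    there.
    """
    sysmiss = is_system_missing(column)
    codes = (
        code_mask(column, md.all_codes)
        if md is not None
        else np.zeros(len(column), dtype=bool)
    )
    qualified_missing = sysmiss | codes
    if kind == "miss":
        return qualified_missing
    if kind == "cat":
        hit = code_mask(column, params)
        # code_mask excludes system missing already; exclude coded too
        return hit & ~qualified_missing
    if kind == "num":
        vals = numeric_values(column).where(~qualified_missing)
        return params.contains_array(vals)
    if kind == "date":
        vals = pd.to_datetime(column, errors="coerce", format="ISO8601").where(
            ~qualified_missing
        )
        return params.contains_array(vals)
    raise ValueError(f"unknown predicate side kind {kind!r}")


def evaluate_rule(
    study: pd.DataFrame, rule: ContradictionRule,
    metadata: MetadataTable | None = None,
) -> np.ndarray:
    """Per-unit boolean vector: does the rule's predicate fire?"""
    kind_a, kind_b = rule.side_kinds
    md_a = metadata.get(rule.var_a) if metadata is not None else None
    md_b = metadata.get(rule.var_b) if metadata is not None else None
    mask_a = _side_mask(study[rule.var_a], md_a, kind_a, rule.params_a)
    mask_b = _side_mask(study[rule.var_b], md_b, kind_b, rule.params_b)
    return mask_a & mask_b


def contradictions(
    study: pd.DataFrame,
    rules: list[ContradictionRule],
    metadata: MetadataTable | None = None,
):
    """Evaluate all contradiction rules.

    Returns ``(res_logical, res_empirical, per_rule_counts)``.  Counting
    is per unit per rule; a unit can contribute to several rules.  A
    rule referencing an unknown variable is skipped with a warning, not
    a run failure.
    """
    rid = _record_ids(study, metadata) if metadata is not None else pd.Series(
        study.index.astype(str), index=study.index
    )
    per_rule: dict[str, int] = {}
    cells = {"logical": [], "empirical": []}
    counts = {"logical": 0, "empirical": 0}
    n_rules = {"logical": 0, "empirical": 0}
    for rule in rules:
        if rule.var_a not in study.columns or rule.var_b not in study.columns:
            logger.warning(
                "rule %s references unknown variable(s); skipped", rule.rule_id
            )
            continue
        fired = evaluate_rule(study, rule, metadata)
        per_rule[rule.rule_id] = int(fired.sum())
        counts[rule.rule_class] += int(fired.sum())
        n_rules[rule.rule_class] += 1
        cells[rule.rule_class].extend(
            (rid.iloc[i], f"{rule.var_a}|{rule.var_b}")
            for i in np.flatnonzero(fired)
        )
    res = {}
    for cls, indicator in (("logical", "DQI-3008"), ("empirical", "DQI-3009")):
        res[cls] = IndicatorResult(
            indicator_id=indicator,
            variable="study-level",
            n_flagged=counts[cls],
            denominator=len(study) * n_rules[cls],
            flagged_cells=cells[cls],
            descriptor={
                "per_rule": {
                    r.rule_id: per_rule[r.rule_id]
                    for r in rules
                    if r.rule_class == cls and r.rule_id in per_rule
                }
            },
            grading="not-applicable" if n_rules[cls] == 0 else (
                "issue" if counts[cls] else "ok"
            ),
        )
    return res["logical"], res["empirical"], per_rule
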