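"""Integrity checks: structural and technical compliance of study data.

These run before every other dimension: a deficient technical setup
(unexpected columns, type mismatches, duplicated records) can
invalidate any downstream result, so integrity operations never raise
on malformed study data — they report it.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    IndicatorResult,
    MetadataTable,
    VariableMetadata,
    code_mask,
    is_system_missing,
    numeric_values,
)

__all__ = [
    "ApplicabilityMatrix",
    "applicability_matrix",
    "check_data_type",
    "find_duplicates",
    "check_record_match",
    "check_element_match",
    "check_value_format",
    "CHECK_NAMES",
]

#: Per-variable checks whose applicability the matrix reports.
CHECK_NAMES = (
    "item_missingness",
    "limit_deviations",
    "inadmissible_categorical",
    "univariate_outliers",
    "multivariate_outliers",
    "distribution_descriptor",
    "shape_or_scale",
    "end_digits",
    "margins",
    "varcomp",
    "loess_trend",
)

APPLICABLE = "applicable"
NO_METADATA = "no-metadata"
NO_DATA = "no-data"
TYPE_MISMATCH = "type-mismatch"


@dataclass
class ApplicabilityMatrix:
    """Variable x check grid of {applicable, no-metadata, no-data,
    type-mismatch} verdicts."""

    frame: pd.DataFrame  # index: variables, columns: CHECK_NAMES

    def verdict(self, variable: str, check: str) -> str:
        return self.frame.loc[variable, check]

    def is_applicable(self, variable: str, check: str) -> bool:
        if variable not in self.frame.index:
            return False
        return self.frame.loc[variable, check] == APPLICABLE

    def to_csv(self, path):
        self.frame.to_csv(path, index_label="variable")


# ---------------------------------------------------------------------------
# Type probing
# ---------------------------------------------------------------------------

def _convertible_mask(values: pd.Series, expected: str) -> np.ndarray:
    """Per-cell losslessly-convertible mask for non-missing raw cells."""
    s = values.astype(str).str.strip()
    if expected == "integer":
        num = pd.to_numeric(s, errors="coerce")
        return (num.notna() & (num == np.floor(num))).to_numpy()
    if expected == "float":
        return pd.to_numeric(s, errors="coerce").notna().to_numpy()
    if expected == "datetime":
        ts = pd.to_datetime(s, errors="coerce", format="ISO8601")
        return ts.notna().to_numpy()
    if expected == "string":
        return np.ones(len(s), dtype=bool)
    raise ValueError(f"unknown expected data type {expected!r}")


def check_data_type(
    column: pd.Series,
    expected: str,
    md: VariableMetadata | None = None,
    mismatch_fraction: float = 0.0,
):
    """Classify each non-missing cell as convertible/unconvertible to the
    expected type; qualified missing/jump codes are stripped first.

    Returns ``(cell_ok: ndarray[bool], column_mismatch: bool, n_checked)``
    where ``cell_ok`` is aligned to the column (missing/code cells True).
    The column verdict is a mismatch when the unconvertible fraction
    exceeds ``mismatch_fraction`` (default 0: any unconvertible cell).
    """
    sysmiss = is_system_missing(column)
    codes = code_mask(column, md.all_codes) if md is not None else np.zeros(
        len(column), dtype=bool
    )
    relevant = ~(sysmiss | codes)
    ok = np.ones(len(column), dtype=bool)
    if relevant.any():
        ok[relevant] = _convertible_mask(column[relevant], expected)
    n_checked = int(relevant.sum())
    n_bad = int((~ok[relevant]).sum()) if n_checked else 0
    mismatch = n_checked > 0 and (n_bad / n_checked) > mismatch_fraction
    return ok, mismatch, n_checked


def probe_type(column: pd.Series, md: VariableMetadata | None = None) -> str:
    """Observed type of a raw column, probing integer -> float ->
    datetime -> string; a column is 'integer' only if every non-missing
    value converts losslessly."""
    for candidate in ("integer", "float", "datetime"):
        ok, mismatch, n = check_data_type(column, candidate, md)
        if n == 0:
            return "empty"
        if not mismatch:
            return candidate
    return "string"


_TYPE_COMPATIBLE = {
    # expected -> observed types that are acceptable
    "integer": {"integer", "empty"},
    "float": {"integer", "float", "empty"},
    "datetime": {"datetime", "empty"},
    "string": {"integer", "float", "datetime", "string", "empty"},
}

# metadata each check needs before it can run on a variable
_CHECK_REQUIREMENTS = {
    "item_missingness": lambda md: True,
    "limit_deviations": lambda md: md.is_numeric or md.data_type == "datetime",
    "inadmissible_categorical": lambda md: bool(md.admissible_categories),
    "univariate_outliers": lambda md: md.is_numeric and md.role == "measurement",
    "multivariate_outliers": lambda md: md.is_numeric and md.role == "measurement",
    "distribution_descriptor": lambda md: True,
    "shape_or_scale": lambda md: md.is_numeric and md.distribution is not None,
    "end_digits": lambda md: md.is_numeric and md.role == "measurement",
    "margins": lambda md: md.key_observer is not None and md.is_numeric,
    "varcomp": lambda md: md.key_observer is not None and md.data_type == "float",
    "loess_trend": lambda md: md.key_datetime is not None and md.is_numeric,
}

_LIMIT_PRESENT = {
    "limit_deviations": lambda md: any(
        (md.hard_limits, md.soft_limits, md.detection_limits)
    ),
}


def applicability_matrix(study: pd.DataFrame, metadata: MetadataTable):
    """Cross-check study data against metadata (entry-point diagnostic).

    Returns ``(ApplicabilityMatrix, result_1001, result_1006)``:
    unexpected data elements (variables present in exactly one of study
    or metadata) and data type mismatches (observed type incompatible
    with the declared type).  Never raises on bad data.
    """
    study_vars = list(study.columns)
    meta_vars = metadata.var_names
    all_vars = list(dict.fromkeys(meta_vars + study_vars))

    # DQI-1001: symmetric difference of variable sets
    only_one_side = sorted(
        (set(study_vars) - set(meta_vars)) | (set(meta_vars) - set(study_vars))
    )
    res_1001 = IndicatorResult(
        indicator_id="DQI-1001",
        variable="study-level",
        n_flagged=len(only_one_side),
        denominator=len(all_vars),
        descriptor={"unexpected_elements": only_one_side},
    )

    grid = pd.DataFrame(NO_METADATA, index=all_vars, columns=list(CHECK_NAMES))
    mismatched_vars = []
    mismatch_cells = []
    n_typed = 0
    for var in all_vars:
        md = metadata.get(var)
        if var not in study.columns:
            grid.loc[var, :] = NO_DATA
            continue
        if md is None:
            grid.loc[var, :] = NO_METADATA
            continue
        col = study[var]
        cell_ok, mismatch, n_checked = check_data_type(col, md.data_type, md)
        n_typed += 1
        if mismatch:
            mismatched_vars.append(var)
            bad_idx = np.flatnonzero(~cell_ok)
            rid = _record_ids(study, metadata)
            mismatch_cells.extend((rid.iloc[i], var) for i in bad_idx)
        for check in CHECK_NAMES:
            if not _CHECK_REQUIREMENTS[check](md):
                grid.loc[var, check] = NO_METADATA
                continue
            if check in _LIMIT_PRESENT and not _LIMIT_PRESENT[check](md):
                grid.loc[var, check] = NO_METADATA
                continue
            if mismatch and check != "item_missingness":
                grid.loc[var, check] = TYPE_MISMATCH
            else:
                grid.loc[var, check] = APPLICABLE

    res_1006 = IndicatorResult(
        indicator_id="DQI-1006",
        variable="study-level",
        n_flagged=len(mismatched_vars),
        denominator=n_typed,
        flagged_cells=mismatch_cells,
        descriptor={"mismatched_variables": mismatched_vars},
    )
    return ApplicabilityMatrix(grid), res_1001, res_1006


def _record_ids(study: pd.DataFrame, metadata: MetadataTable | None) -> pd.Series:
    if metadata is not None:
        for name in metadata.id_vars():
            if name in study.columns:
                return study[name].astype(str)
    return pd.Series(study.index.astype(str), index=study.index)


# ---------------------------------------------------------------------------
# Duplicates, record and element matching, value formats
# ---------------------------------------------------------------------------

def find_duplicates(
    frame: pd.DataFrame, keys: list[str] | None = None,
    metadata: MetadataTable | None = None,
) -> IndicatorResult:
    """Duplicated records (beyond the first occurrence of each group) and
    byte-identical column pairs under different names."""
    if keys:
        missing = [k for k in keys if k not in frame.columns]
        if missing:
            raise KeyError(f"duplicate keys not in frame: {missing}")
        dup_mask = frame.duplicated(subset=keys, keep="first")
    else:
        dup_mask = frame.duplicated(keep="first")
    rid = _record_ids(frame, metadata)
    flagged = [(rid.iloc[i], "*") for i in np.flatnonzero(dup_mask.to_numpy())]

    dup_elements = []
    cols = list(frame.columns)
    for a, b in itertools.combinations(cols, 2):
        if frame[a].fillna("\x00").equals(
            frame[b].fillna("\x00").rename(a)
        ):
            dup_elements.append([a, b])
    return IndicatorResult(
        indicator_id="DQI-1003",
        variable="study-level",
        n_flagged=int(dup_mask.sum()),
        denominator=len(frame),
        flagged_cells=flagged,
        descriptor={"duplicated_element_pairs": dup_elements},
    )


def check_record_match(
    frames: dict[str, pd.DataFrame],
    id_var: str,
    roster: list | None = None,
):
    """Record-set checks across data sets.

    Returns ``(result_1002, result_1004)``: IDs missing from / surplus
    to the expected roster, and per frame-pair symmetric differences of
    ID sets.  Without a roster the record-set check degrades to
    duplicate-ID detection with a not-applicable grading.
    """
    id_sets = {}
    for name, frame in frames.items():
        if id_var not in frame.columns:
            raise KeyError(f"id_var {id_var!r} absent from table {name!r}")
        id_sets[name] = set(frame[id_var].astype(str))

    union_ids = set().union(*id_sets.values()) if id_sets else set()
    if roster is not None:
        roster_set = {str(r) for r in roster}
        missing = sorted(roster_set - union_ids)
        surplus = sorted(union_ids - roster_set)
        res_1002 = IndicatorResult(
            indicator_id="DQI-1002",
            n_flagged=len(missing) + len(surplus),
            denominator=len(roster_set),
            descriptor={"missing_ids": missing, "surplus_ids": surplus},
        )
    else:
        dup_ids = sorted(
            {
                i
                for name, frame in frames.items()
                for i in frame[id_var].astype(str)[
                    frame[id_var].astype(str).duplicated()
                ]
            }
        )
        res_1002 = IndicatorResult(
            indicator_id="DQI-1002",
            n_flagged=len(dup_ids),
            denominator=len(union_ids),
            descriptor={"duplicated_ids": dup_ids, "note": "no roster given"},
            grading="not-applicable" if not dup_ids else "issue",
        )

    pair_mismatches = {}
    total = 0
    for (na, sa), (nb, sb) in itertools.combinations(id_sets.items(), 2):
        diff = sorted(sa.symmetric_difference(sb))
        pair_mismatches[f"{na}|{nb}"] = diff
        total += len(diff)
    res_1004 = IndicatorResult(
        indicator_id="DQI-1004",
        n_flagged=total,
        denominator=len(union_ids),
        descriptor={"pairwise_mismatching_ids": pair_mismatches},
        grading="not-applicable" if len(frames) < 2 else
        ("issue" if total else "ok"),
    )
    return res_1002, res_1004


def check_element_match(
    frames: dict[str, pd.DataFrame], metadata: MetadataTable
) -> IndicatorResult:
    """Variables appearing in the wrong source table, in several tables,
    or missing from their declared table."""
    flagged = []
    detail = {}
    n_assessed = 0
    for md in metadata:
        if md.role == "identifier":
            continue
        holders = [name for name, f in frames.items() if md.var_name in f.columns]
        expected = md.source_table
        n_assessed += 1
        if expected is not None:
            if holders != [expected]:
                flagged.append(md.var_name)
                detail[md.var_name] = {
                    "expected_table": expected,
                    "observed_tables": holders,
                }
        else:
            if len(holders) > 1:
                flagged.append(md.var_name)
                detail[md.var_name] = {
                    "expected_table": None,
                    "observed_tables": holders,
                }
    return IndicatorResult(
        indicator_id="DQI-1005",
        n_flagged=len(flagged),
        denominator=n_assessed,
        descriptor={"mismatched_elements": detail},
    )


_DECIMAL_DOT_RE = re.compile(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")


def _format_signature(value: str) -> str:
    out = []
    for ch in value:
        if ch.isdigit():
            if not out or out[-1] != "9":
                out.append("9")
        elif ch.isalpha():
            if not out or out[-1] != "A":
                out.append("A")
        else:
            out.append(ch)
    return "".join(out)


def check_value_format(
    column: pd.Series,
    format_spec: str | None = None,
    var_name: str = "study-level",
    metadata: VariableMetadata | None = None,
) -> IndicatorResult:
    """Value-format homogeneity.

    With ``format_spec`` (a regular expression, or the string
    ``"decimal-dot"``) non-matching non-missing cells are counted.  With
    no spec, the number of distinct inferred formats is reported
    (more than one -> inhomogeneous); both the cell counts and the
    column-level verdict are part of the result.
    """
    sysmiss = is_system_missing(column)
    if metadata is not None:
        sysmiss |= code_mask(column, metadata.all_codes)
    values = column[~sysmiss].astype(str).str.strip()
    rid = _record_ids(column.to_frame(), None)[~sysmiss]
    denominator = len(values)

    if format_spec is not None:
        if format_spec == "decimal-dot":
            ok = values.map(lambda v: bool(_DECIMAL_DOT_RE.match(v)))
        else:
            try:
                pat = re.compile(format_spec)
            except re.error as exc:
                raise ValueError(f"invalid format pattern: {exc}") from exc
            ok = values.map(lambda v: bool(pat.fullmatch(v)))
        bad = ~ok.to_numpy(dtype=bool)
        flagged = [(rid.iloc[i], var_name) for i in np.flatnonzero(bad)]
        return IndicatorResult(
            indicator_id="DQI-1007",
            variable=var_name,
            n_flagged=int(bad.sum()),
            denominator=denominator,
            flagged_cells=flagged,
        )

    sigs = values.map(_format_signature)
    counts = sigs.value_counts()
    n_formats = len(counts)
    if n_formats > 1:
        majority = counts.index[0]
        bad = (sigs != majority).to_numpy()
        flagged = [(rid.iloc[i], var_name) for i in np.flatnonzero(bad)]
        n_flagged = int(bad.sum())
    else:
        flagged, n_flagged = [], 0
    return IndicatorResult(
        indicator_id="DQI-1007",
        variable=var_name,
        n_flagged=n_flagged,
        denominator=denominator,
        flagged_cells=flagged,
        descriptor={"n_formats": n_formats, "formats": counts.to_dict()},
    )
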