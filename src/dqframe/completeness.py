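"""Completeness: missing data at unit, segment and item level.

Missingness is staged: reasons for a unit never entering the study
differ from those for skipping one examination segment, which differ
again from single unanswered items.  Unit- and segment-level
missingness is therefore assessed first and the affected units are
excluded from the item-level denominators, so each stage counts only
what the earlier stages have not already explained.  "Crude"
missingness ignores coded reasons; "qualified" missingness uses the
declared missing/jump code maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    IndicatorResult,
    MetadataTable,
    code_mask,
    is_system_missing,
)
from .integrity import _record_ids

__all__ = [
    "MissingnessBreakdown",
    "unit_missingness",
    "segment_missingness",
    "item_missingness",
    "qualified_rates",
]


@dataclass
class MissingnessBreakdown:
    """Item-level missingness decomposition for one variable.

    Conservation: ``n_observed + n_system_missing + sum(per_code)
    + sum(per_jump) == n_expected``.
    """

    variable: str
    n_observed: int = 0
    n_system_missing: int = 0
    per_code: dict = field(default_factory=dict)
    per_jump: dict = field(default_factory=dict)
    n_expected: int = 0

    @property
    def conserved(self) -> bool:
        return (
            self.n_observed
            + self.n_system_missing
            + sum(self.per_code.values())
            + sum(self.per_jump.values())
            == self.n_expected
        )

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n_observed": self.n_observed,
            "n_system_missing": self.n_system_missing,
            "per_code": {str(k): v for k, v in self.per_code.items()},
            "per_jump": {str(k): v for k, v in self.per_jump.items()},
            "n_expected": self.n_expected,
        }


def _missing_matrix(study: pd.DataFrame, metadata: MetadataTable, variables):
    """Boolean unit x variable matrix: cell missing (system or coded)."""
    cols = {}
    for var in variables:
        if var not in study.columns:
            continue
        md = metadata.get(var)
        miss = is_system_missing(study[var])
        if md is not None:
            miss = miss | code_mask(study[var], md.all_codes)
        cols[var] = miss
    return pd.DataFrame(cols, index=study.index)


def unit_missingness(
    study: pd.DataFrame, metadata: MetadataTable
) -> IndicatorResult:
    """Units whose every measurement variable is missing (system or
    coded).  Identifier and process variables do not count: a record
    with only an examiner ID filled carries no measurements."""
    meas = [v for v in metadata.measurement_vars() if v in study.columns]
    if not meas:
        return IndicatorResult(
            indicator_id="DQI-2001",
            variable="unit-level",
            grading="not-applicable",
        )
    mm = _missing_matrix(study, metadata, meas)
    all_missing = mm.all(axis=1).to_numpy()
    rid = _record_ids(study, metadata)
    flagged = [(rid.iloc[i], "*") for i in np.flatnonzero(all_missing)]
    return IndicatorResult(
        indicator_id="DQI-2001",
        variable="unit-level",
        n_flagged=int(all_missing.sum()),
        denominator=len(study),
        flagged_cells=flagged,
    )


def segment_missingness(
    study: pd.DataFrame, metadata: MetadataTable,
    exclude_units: set | None = None,
) -> dict[str, IndicatorResult]:
    """Per segment: units with every segment variable missing.

    ``exclude_units`` (typically the unit-missing set) are removed from
    the denominator.  The descriptor carries the unit x segment
    participation pattern.
    """
    segments = metadata.by_segment()
    rid = _record_ids(study, metadata)
    exclude = exclude_units or set()
    keep = ~rid.isin([str(u) for u in exclude]).to_numpy()
    results: dict[str, IndicatorResult] = {}
    pattern = pd.DataFrame(index=rid[keep])
    for seg, seg_vars in segments.items():
        present_vars = [v for v in seg_vars if v in study.columns]
        if not present_vars:
            raise ValueError(f"segment {seg!r} has no variables in the study data")
        mm = _missing_matrix(study, metadata, present_vars)
        seg_missing = mm.all(axis=1).to_numpy() & keep
        pattern[seg] = (~mm.all(axis=1).to_numpy()[keep]).astype(int)
        flagged = [(rid.iloc[i], seg) for i in np.flatnonzero(seg_missing)]
        results[seg] = IndicatorResult(
            indicator_id="DQI-2001",
            variable=f"segment:{seg}",
            n_flagged=int(seg_missing.sum()),
            denominator=int(keep.sum()),
            flagged_cells=flagged,
            descriptor={
                "participation_pattern_counts": pattern.groupby(
                    list(pattern.columns)
                ).size().reset_index().to_dict(orient="list")
                if len(pattern.columns)
                else {}
            },
        )
    return results


def item_missingness(
    study: pd.DataFrame,
    metadata: MetadataTable,
    unit_missing: set | None = None,
    segment_missing: dict[str, set] | None = None,
):
    """Item-level missingness with staged denominators.

    Units already flagged as unit-missing are excluded everywhere; for
    each variable, units flagged as missing for that variable's
    segment are excluded too.  Returns ``(breakdowns, res_2001,
    res_2005, res_1008)``: crude missing fields, per-reason counts, and
    system-missing cells in variables that declare missing codes
    (uncertain missingness status).
    """
    unit_missing = {str(u) for u in (unit_missing or set())}
    segment_missing = {
        seg: {str(u) for u in units}
        for seg, units in (segment_missing or {}).items()
    }
    rid = _record_ids(study, metadata)

    breakdowns: dict[str, MissingnessBreakdown] = {}
    crude_cells = []
    uncertain_cells = []
    reason_counts: dict[str, int] = {}
    crude_denominator = 0
    uncertain_denominator = 0

    for md in metadata:
        var = md.var_name
        if var not in study.columns or md.role != "measurement":
            continue
        seg_excl = segment_missing.get(md.segment, set()) if md.segment else set()
        keep = ~rid.isin(unit_missing | seg_excl).to_numpy()
        col = study[var][keep]
        ids = rid[keep]

        sysmiss = is_system_missing(col)
        miss_codes = code_mask(col, set(md.missing_codes))
        jump_codes_m = code_mask(col, set(md.jump_codes))
        observed = ~(sysmiss | miss_codes | jump_codes_m)

        per_code = {}
        for code, label in md.missing_codes.items():
            cnt = int(code_mask(col, {code}).sum())
            if cnt:
                per_code[code] = cnt
                reason_counts[f"{code} ({label})" if label else str(code)] = (
                    reason_counts.get(
                        f"{code} ({label})" if label else str(code), 0
                    )
                    + cnt
                )
        per_jump = {}
        for code in md.jump_codes:
            cnt = int(code_mask(col, {code}).sum())
            if cnt:
                per_jump[code] = cnt

        bd = MissingnessBreakdown(
            variable=var,
            n_observed=int(observed.sum()),
            n_system_missing=int(sysmiss.sum()),
            per_code=per_code,
            per_jump=per_jump,
            n_expected=int(keep.sum()),
        )
        breakdowns[var] = bd

        # jump-coded cells are legitimately skipped by questionnaire
        # routing: they appear in the breakdown but are not crude
        # missing-value defects
        missing_any = sysmiss | miss_codes
        crude_cells.extend((ids.iloc[i], var) for i in np.flatnonzero(missing_any))
        crude_denominator += int(keep.sum())
        if md.missing_codes:
            uncertain_cells.extend(
                (ids.iloc[i], var) for i in np.flatnonzero(sysmiss)
            )
            uncertain_denominator += int(keep.sum())

    res_2001 = IndicatorResult(
        indicator_id="DQI-2001",
        variable="item-level",
        n_flagged=len(crude_cells),
        denominator=crude_denominator,
        flagged_cells=crude_cells,
    )
    res_2005 = IndicatorResult(
        indicator_id="DQI-2005",
        variable="item-level",
        n_flagged=sum(reason_counts.values()),
        denominator=crude_denominator,
        descriptor={"per_reason": reason_counts},
        grading="ok" if not reason_counts else "issue",
    )
    res_1008 = IndicatorResult(
        indicator_id="DQI-1008",
        variable="item-level",
        n_flagged=len(uncertain_cells),
        denominator=uncertain_denominator,
        flagged_cells=uncertain_cells,
        grading="not-applicable" if uncertain_denominator == 0 else (
            "issue" if uncertain_cells else "ok"
        ),
    )
    return breakdowns, res_2001, res_2005, res_1008


def qualified_rates(
    study: pd.DataFrame,
    metadata: MetadataTable,
    roster: list | None = None,
    segment_order: list[str] | None = None,
    refusal_codes: set | None = None,
):
    """Qualified unit-level rates: non-response, refusal, drop-out.

    Non-response counts eligible (rostered) units for which no
    information could be obtained: absent from the study table, or
    present with every measurement system-missing and no qualified
    code.  A unit of all-refusals did respond (the refusal itself is
    information) and counts toward the refusal rate instead.  Drop-out
    requires a declared segment order: a participant who completes a
    prefix of the segments and abandons the rest prematurely;
    intermittent segment missingness is never drop-out.
    """
    meas = [v for v in metadata.measurement_vars() if v in study.columns]
    rid = _record_ids(study, metadata)

    if refusal_codes is None:
        refusal_codes = set()
        for md in metadata:
            for code, label in md.missing_codes.items():
                if "refus" in str(label).lower():
                    refusal_codes.add(code)

    if roster is not None and meas:
        roster_set = {str(r) for r in roster}
        present = set(rid)
        absent = roster_set - present

        sysmiss_all = pd.DataFrame(
            {v: is_system_missing(study[v]) for v in meas}, index=study.index
        ).all(axis=1)
        all_sysmiss_ids = set(rid[sysmiss_all.to_numpy()])

        nonresp = absent | (all_sysmiss_ids & roster_set)
        res_2002 = IndicatorResult(
            indicator_id="DQI-2002",
            variable="unit-level",
            n_flagged=len(nonresp),
            denominator=len(roster_set),
            descriptor={"nonresponding_ids": sorted(nonresp)},
        )

        refusal_units = set()
        if refusal_codes:
            mm = _missing_matrix(study, metadata, meas)
            all_missing = mm.all(axis=1).to_numpy()
            any_refusal = np.zeros(len(study), dtype=bool)
            for v in meas:
                md = metadata[v]
                rc = set(md.missing_codes) & refusal_codes
                if rc:
                    any_refusal |= code_mask(study[v], rc)
            unit_refusal = all_missing & any_refusal
            refusal_units = set(rid[unit_refusal]) & roster_set
        res_2003 = IndicatorResult(
            indicator_id="DQI-2003",
            variable="unit-level",
            n_flagged=len(refusal_units),
            denominator=len(roster_set),
            descriptor={"refusing_ids": sorted(refusal_units)},
        )
    else:
        res_2002 = IndicatorResult(
            indicator_id="DQI-2002", grading="not-applicable",
            descriptor={"note": "no roster given"},
        )
        res_2003 = IndicatorResult(
            indicator_id="DQI-2003", grading="not-applicable",
            descriptor={"note": "no roster given"},
        )

    if segment_order:
        segments = metadata.by_segment()
        missing_by_seg = {}
        for seg in segment_order:
            seg_vars = [v for v in segments.get(seg, []) if v in study.columns]
            if not seg_vars:
                raise ValueError(f"segment {seg!r} in segment_order has no data")
            missing_by_seg[seg] = _missing_matrix(
                study, metadata, seg_vars
            ).all(axis=1).to_numpy()
        present = np.column_stack(
            [~missing_by_seg[seg] for seg in segment_order]
        )
        participant = present.any(axis=1)
        # drop-out: non-empty, non-full prefix of completed segments
        dropout = np.zeros(len(study), dtype=bool)
        for i in np.flatnonzero(participant):
            row = present[i]
            k = int(np.argmin(row)) if not row.all() else len(row)
            # prefix of length k present, rest must be all absent
            dropout[i] = 0 < k < len(row) and not row[k:].any()
        flagged = [(rid.iloc[i], "*") for i in np.flatnonzero(dropout)]
        res_2004 = IndicatorResult(
            indicator_id="DQI-2004",
            variable="unit-level",
            n_flagged=int(dropout.sum()),
            denominator=int(participant.sum()),
            flagged_cells=flagged,
        )
    else:
        res_2004 = IndicatorResult(
            indicator_id="DQI-2004", grading="not-applicable",
            descriptor={"note": "no segment order given"},
        )
    return res_2002, res_2003, res_2004
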