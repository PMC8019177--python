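"""Report orchestration: run all applicable checks, aggregate, render.

:func:`dq_report` is the all-at-once entry point: integrity runs
first, and downstream checks run only where the applicability matrix
permits, because deficits at the integrity level may invalidate any
finding at subsequent stages.  Results are exportable as a
schema-versioned JSON document (machine-readable, with descriptors
under a distinct key), a self-contained static HTML report with CSV
tables, and a flag-annotated copy of the study data.
"""

from __future__ import annotations

import hashlib
import html
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accuracy, completeness, consistency, integrity
from .core_model import (
    ContradictionRule,
    IndicatorResult,
    MetadataTable,
    registry,
)
from .integrity import _record_ids

__all__ = ["RunConfig", "DQReport", "dq_report", "render_report",
           "export_json", "annotate_flags"]

SCHEMA_VERSION = "1.0"
_DIMENSION_ORDER = ("integrity", "completeness", "consistency", "accuracy")


@dataclass
class RunConfig:
    """Run-level configuration (defaults give the all-at-once report)."""

    roster: list | None = None
    segment_order: list[str] | None = None
    outlier_rules: tuple = accuracy.OUTLIER_RULES
    outlier_threshold: int = 1
    min_class_size: int = 10
    icc_threshold: float = 0.05
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    run_accuracy: bool = True
    multivariate_sets: list[list[str]] | None = None
    timestamp: str | None = None  # injected for byte-stable re-renders

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.outlier_rules, list):
            cfg.outlier_rules = tuple(cfg.outlier_rules)
        return cfg

    def to_dict(self) -> dict:
        return {
            "roster": self.roster,
            "segment_order": self.segment_order,
            "outlier_rules": list(self.outlier_rules),
            "outlier_threshold": self.outlier_threshold,
            "min_class_size": self.min_class_size,
            "icc_threshold": self.icc_threshold,
            "covariates": self.covariates,
            "run_accuracy": self.run_accuracy,
            "multivariate_sets": self.multivariate_sets,
        }


@dataclass
class DQReport:
    """Aggregated outcome of one data-quality run."""

    applicability: integrity.ApplicabilityMatrix
    results: list[IndicatorResult]
    breakdowns: dict
    config_hash: str
    seed: int | None = None
    timestamp: str = "1970-01-01T00:00:00Z"

    def by_dimension(self) -> dict[str, list[IndicatorResult]]:
        reg = registry()
        out: dict[str, list[IndicatorResult]] = {
            d: [] for d in _DIMENSION_ORDER
        }
        for r in self.results:
            out[reg[r.indicator_id].dimension].append(r)
        return out

    def summary_grid(self) -> pd.DataFrame:
        """Per dimension x variable grading grid (worst grading wins)."""
        rank = {"ok": 0, "not-applicable": -1, "issue": 1}
        cells: dict[tuple[str, str], str] = {}
        reg = registry()
        for r in self.results:
            dim = reg[r.indicator_id].dimension
            key = (r.variable, dim)
            prev = cells.get(key)
            if prev is None or rank[r.grading] > rank[prev]:
                cells[key] = r.grading
        variables = sorted({v for v, _ in cells})
        grid = pd.DataFrame(
            "not-applicable", index=variables, columns=list(_DIMENSION_ORDER)
        )
        for (var, dim), grading in cells.items():
            grid.loc[var, dim] = grading
        return grid


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def dq_report(
    study_tables,
    metadata: MetadataTable,
    rules: list[ContradictionRule] | None = None,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> DQReport:
    """Run every applicable check and aggregate the results.

    ``study_tables`` is a single DataFrame or a ``name -> DataFrame``
    mapping.  Integrity runs first; completeness, consistency and
    accuracy checks run per variable only where the applicability
    matrix marks them applicable.
    """
    config = config or RunConfig()
    rules = rules or []
    if isinstance(study_tables, pd.DataFrame):
        frames = {"study": study_tables}
    else:
        frames = dict(study_tables)
    if not frames:
        raise ValueError("no study tables given")
    study = pd.concat(frames.values(), axis=0, ignore_index=True) if len(
        frames
    ) > 1 else next(iter(frames.values()))

    results: list[IndicatorResult] = []

    # ---- integrity (always first; never raises on bad data) ----
    matrix, res_1001, res_1006 = integrity.applicability_matrix(study, metadata)
    results += [res_1001, res_1006]
    id_vars = metadata.id_vars()
    id_var = id_vars[0] if id_vars else None
    results.append(integrity.find_duplicates(study, metadata=metadata))
    if id_var is not None and id_var in study.columns:
        res_1002, res_1004 = integrity.check_record_match(
            frames, id_var, roster=config.roster
        )
        results += [res_1002, res_1004]
    results.append(integrity.check_element_match(frames, metadata))
    rid = _record_ids(study, metadata)
    for md in metadata:
        if md.var_name in study.columns and md.data_type in ("float", "integer"):
            res = integrity.check_value_format(
                study[md.var_name], "decimal-dot",
                var_name=md.var_name, metadata=md,
            )
            if res.n_flagged:
                results.append(res)

    # ---- completeness (staged) ----
    res_unit = completeness.unit_missingness(study, metadata)
    results.append(res_unit)
    unit_missing_ids = {r for r, _ in res_unit.flagged_cells}
    seg_results = completeness.segment_missingness(
        study, metadata, exclude_units=unit_missing_ids
    )
    results.extend(seg_results.values())
    segment_missing = {
        seg: {r for r, _ in res.flagged_cells}
        for seg, res in seg_results.items()
    }
    breakdowns, res_2001, res_2005, res_1008 = completeness.item_missingness(
        study, metadata, unit_missing_ids, segment_missing
    )
    results += [res_2001, res_2005, res_1008]
    results += list(
        completeness.qualified_rates(
            study, metadata, roster=config.roster,
            segment_order=config.segment_order,
        )
    )

    # ---- consistency ----
    for md in metadata:
        var = md.var_name
        if matrix.is_applicable(var, "limit_deviations"):
            results.extend(
                consistency.limit_deviations(
                    study[var], md, record_ids=rid
                ).values()
            )
        if matrix.is_applicable(var, "inadmissible_categorical"):
            results.append(
                consistency.inadmissible_categorical(
                    study[var], md, record_ids=rid
                )
            )
    if rules:
        res_log, res_emp, _ = consistency.contradictions(study, rules, metadata)
        results += [res_log, res_emp]

    # ---- accuracy ----
    if config.run_accuracy:
        covars = [
            c for c in config.covariates
            if c in study.columns and c in metadata
        ]
        for md in metadata:
            var = md.var_name
            if var not in study.columns:
                continue
            clean = _clean_numeric(study[var], md)
            if matrix.is_applicable(var, "univariate_outliers"):
                res, _ = accuracy.univariate_outliers(
                    clean, rules=config.outlier_rules,
                    threshold=config.outlier_threshold,
                    record_ids=rid, variable=var,
                )
                results.append(res)
            if matrix.is_applicable(var, "distribution_descriptor"):
                res = IndicatorResult(
                    indicator_id="DQI-4004", variable=var,
                    grading="not-applicable",
                    descriptor=accuracy.distribution_descriptor(
                        clean if md.is_numeric else study[var],
                        categorical=not md.is_numeric,
                    ),
                )
                results.append(res)
            if matrix.is_applicable(var, "shape_or_scale"):
                results.append(
                    accuracy.shape_or_scale(
                        clean, md.distribution, variable=var
                    )
                )
            if matrix.is_applicable(var, "end_digits"):
                results.append(
                    accuracy.end_digits(
                        clean, decimals=md.decimals or 0, variable=var
                    )
                )
            if matrix.is_applicable(var, "margins") and md.key_observer in (
                study.columns
            ):
                work = study.copy()
                work[var] = clean.to_numpy()
                _, res = accuracy.margins(
                    work, var, md.key_observer,
                    covariates=[c for c in covars if c != var],
                    min_class_size=config.min_class_size,
                )
                results.append(res)
            if matrix.is_applicable(var, "varcomp") and md.key_observer in (
                study.columns
            ):
                work = study.copy()
                work[var] = clean.to_numpy()
                results.append(
                    accuracy.varcomp(
                        work, var, md.key_observer,
                        covariates=[c for c in covars if c != var],
                        icc_threshold=config.icc_threshold,
                    )
                )
            if matrix.is_applicable(var, "loess_trend") and md.key_datetime in (
                study.columns
            ):
                work = study.copy()
                work[var] = clean.to_numpy()
                payload = accuracy.loess_trend(
                    work, var, md.key_datetime,
                    class_var=md.key_observer
                    if md.key_observer in study.columns else None,
                    covariates=[c for c in covars if c != var],
                )
                results.append(
                    IndicatorResult(
                        indicator_id="DQI-4003", variable=var,
                        grading="not-applicable", descriptor=payload,
                    )
                )
        mv_sets = config.multivariate_sets
        if mv_sets is None:
            floats = [
                md.var_name for md in metadata
                if md.data_type == "float"
                and matrix.is_applicable(md.var_name, "multivariate_outliers")
            ]
            mv_sets = [floats] if len(floats) >= 2 else []
        for var_set in mv_sets:
            cols = {}
            for v in var_set:
                cols[v] = _clean_numeric(study[v], metadata.get(v))
            try:
                res, _ = accuracy.multivariate_outliers(
                    pd.DataFrame(cols), rules=config.outlier_rules,
                    threshold=config.outlier_threshold, record_ids=rid,
                )
                results.append(res)
            except ValueError:
                pass

    return DQReport(
        applicability=matrix,
        results=results,
        breakdowns={v: b.to_dict() for v, b in breakdowns.items()},
        config_hash=_config_hash(config),
        seed=seed,
        timestamp=config.timestamp or "1970-01-01T00:00:00Z",
    )


def _clean_numeric(column: pd.Series, md) -> pd.Series:
    """Numeric values with codes and hard-limit violations removed."""
    from .core_model import code_mask, numeric_values

    vals = numeric_values(column)
    if md is not None:
        vals = vals.where(~code_mask(column, md.all_codes))
        if md.hard_limits is not None and md.data_type != "datetime":
            vals = vals.where(md.hard_limits.contains_array(vals))
    return vals


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_json(report: DQReport) -> str:
    """Schema-versioned machine-readable export (deterministic bytes).

    Descriptors are carried under the distinct ``descriptor`` key of
    each result so downstream aggregation can ignore them.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "timestamp": report.timestamp,
        "config_hash": report.config_hash,
        "seed": report.seed,
        "applicability": {
            var: dict(zip(report.applicability.frame.columns, row))
            for var, row in report.applicability.frame.iterrows()
        },
        "results": [r.to_dict() for r in report.results],
        "missingness_breakdowns": report.breakdowns,
        "summary": report.summary_grid().to_dict(orient="index"),
    }
    return json.dumps(
        _stringify_keys(doc), sort_keys=True, indent=1, default=_json_default
    )


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    return str(o)


def render_report(report: DQReport, out_dir, plots: bool = True) -> None:
    """Write a static HTML report plus CSV tables and plot images."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.applicability.to_csv(out / "applicability_matrix.csv")
    if plots:
        from . import plots as _plots

        _plots.applicability_heatmap(
            report.applicability, out / "applicability_matrix.png"
        )
        for r in report.results:
            desc = r.descriptor or {}
            if "histogram" in desc and "limits" in desc:
                _plots.limit_histogram(
                    r, out / f"limits_{r.variable}_{r.indicator_id}.png"
                )
            if r.indicator_id in ("DQI-4003", "DQI-4006") and "per_class" in desc:
                _plots.margins_plot(
                    r, out / f"margins_{r.variable}_{r.indicator_id}.png"
                )
    rows = []
    for r in report.results:
        rows.append(
            {
                "indicator_id": r.indicator_id,
                "dimension": registry()[r.indicator_id].dimension,
                "variable": r.variable,
                "n_flagged": r.n_flagged,
                "denominator": r.denominator,
                "percent": "" if r.percent is None else round(r.percent, 1),
                "grading": r.grading,
            }
        )
    results_df = pd.DataFrame(rows)
    results_df.to_csv(out / "indicator_results.csv", index=False)
    report.summary_grid().to_csv(out / "summary_grid.csv", index_label="variable")
    (out / "report.json").write_text(export_json(report))

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Data quality report</title>",
        "<style>body{font-family:sans-serif;margin:2em}"
        "table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 8px}.issue{background:#fdd}.ok{background:#dfd}"
        ".not-applicable{color:#999}</style></head><body>",
        "<h1>Data quality report</h1>",
        f"<p>Generated: {html.escape(report.timestamp)} | config "
        f"{html.escape(report.config_hash)} | seed {report.seed}</p>",
        "<h2>Summary</h2>",
        _grid_html(report.summary_grid()),
    ]
    by_dim = report.by_dimension()
    for dim in _DIMENSION_ORDER:
        parts.append(f"<h2>{dim.capitalize()}</h2>")
        sub = results_df[results_df["dimension"] == dim]
        parts.append(_table_html(sub))
    parts.append("</body></html>")
    (out / "report.html").write_text("".join(parts))


def _grid_html(grid: pd.DataFrame) -> str:
    head = "".join(f"<th>{html.escape(c)}</th>" for c in grid.columns)
    rows = []
    for var, row in grid.iterrows():
        cells = "".join(
            f"<td class='{v}'>{html.escape(str(v))}</td>" for v in row
        )
        rows.append(f"<tr><th>{html.escape(str(var))}</th>{cells}</tr>")
    return (
        f"<table><tr><th>variable</th>{head}</tr>" + "".join(rows) + "</table>"
    )


def _table_html(df: pd.DataFrame) -> str:
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    rows = []
    for _, row in df.iterrows():
        cls = row.get("grading", "")
        cells = "".join(f"<td>{html.escape(str(v))}</td>" for v in row)
        rows.append(f"<tr class='{cls}'>{cells}</tr>")
    return f"<table><tr>{head}</tr>" + "".join(rows) + "</table>"


def annotate_flags(study: pd.DataFrame, report: DQReport,
                   metadata: MetadataTable | None = None) -> pd.DataFrame:
    """Copy of the study data with one annotation column per flagged
    variable listing the indicator IDs firing per cell; original values
    are untouched."""
    annotated = study.copy()
    rid = _record_ids(study, metadata)
    pos_by_id = {r: i for i, r in enumerate(rid)}
    notes: dict[str, dict[int, list[str]]] = {}
    for r in report.results:
        for record_id, var in r.flagged_cells:
            if var not in study.columns:
                continue
            pos = pos_by_id.get(str(record_id))
            if pos is None:
                raise KeyError(
                    f"stale flag coordinate: record {record_id!r} not found"
                )
            notes.setdefault(var, {}).setdefault(pos, []).append(
                r.indicator_id
            )
    for var, per_row in notes.items():
        col = [""] * len(study)
        for pos, ids in per_row.items():
            col[pos] = "|".join(sorted(set(ids)))
        annotated[f"{var}_dq_flags"] = col
    return annotated
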