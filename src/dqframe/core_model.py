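"""Core domain types shared by every data-quality check.

The engine is metadata-driven: each study variable is described by a
:class:`VariableMetadata` record (expected type, admissible ranges or
categories, qualified missing codes, segment membership, process role),
and the metadata decides which checks are applicable to which variable.
Check outcomes are uniformly reported as :class:`IndicatorResult`
records keyed by the indicator registry (:func:`registry`).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "parse_interval",
    "VariableMetadata",
    "MetadataTable",
    "load_metadata",
    "IndicatorRegistry",
    "RegistryEntry",
    "registry",
    "IndicatorResult",
    "ContradictionRule",
    "load_rules",
    "PREDICATE_CODES",
    "MetadataError",
    "IntervalParseError",
]

DIMENSIONS = ("integrity", "completeness", "consistency", "accuracy")
DATA_TYPES = ("integer", "float", "string", "datetime")
ROLES = (
    "measurement",
    "process-examiner",
    "process-device",
    "process-time",
    "identifier",
)


class MetadataError(ValueError):
    """Raised when a metadata table violates a hard requirement."""


class IntervalParseError(ValueError):
    """Raised when an interval literal cannot be parsed."""


# ---------------------------------------------------------------------------
# Interval grammar
# ---------------------------------------------------------------------------

_INTERVAL_RE = re.compile(r"^\s*([\[\(])\s*(.*?)\s*;\s*(.*?)\s*([\]\)])\s*$")


@dataclass(frozen=True)
class Interval:
    """A typed admissibility range with open or closed endpoints.

    Endpoints are floats or :class:`pandas.Timestamp`; ``-inf``/``+inf``
    (or ``pd.Timestamp.min/max`` semantics via unbounded floats) mark
    unbounded sides.  Used for hard, soft and detection limits.
    """

    lower: object
    upper: object
    lower_closed: bool = True
    upper_closed: bool = True

    def __post_init__(self):
        if self.lower > self.upper:
            raise IntervalParseError(
                f"interval lower bound {self.lower!r} exceeds upper bound {self.upper!r}"
            )
        if self.lower == self.upper and not (self.lower_closed and self.upper_closed):
            raise IntervalParseError(
                "degenerate interval must be closed on both sides"
            )

    @property
    def is_datetime(self) -> bool:
        return isinstance(self.lower, pd.Timestamp) or isinstance(
            self.upper, pd.Timestamp
        )

    def contains(self, value) -> bool:
        """Membership of a single finite value, respecting closedness."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        lo = (value > self.lower) or (self.lower_closed and value == self.lower)
        hi = (value < self.upper) or (self.upper_closed and value == self.upper)
        return bool(lo and hi)

    def contains_array(self, values) -> np.ndarray:
        """Vectorised membership; NaN/NaT map to False."""
        arr = pd.Series(values)
        lo = (arr > self.lower) | ((arr == self.lower) if self.lower_closed else False)
        hi = (arr < self.upper) | ((arr == self.upper) if self.upper_closed else False)
        out = (lo & hi).to_numpy(dtype=bool)
        out[arr.isna().to_numpy()] = False
        return out

    def __str__(self) -> str:
        def fmt(v):
            if isinstance(v, pd.Timestamp):
                return v.isoformat()
            if v == float("-inf"):
                return "-Inf"
            if v == float("inf"):
                return "Inf"
            if float(v) == int(v):
                return str(int(v))
            return repr(float(v))

        lb = "[" if self.lower_closed else "("
        ub = "]" if self.upper_closed else ")"
        return f"{lb}{fmt(self.lower)};{fmt(self.upper)}{ub}"


def _parse_endpoint(token: str, kind: str, side: str):
    t = token.strip()
    low = t.lower()
    if low in ("-inf", "-infinity"):
        return float("-inf")
    if low in ("inf", "+inf", "infinity", "+infinity"):
        return float("inf")
    if kind == "datetime":
        try:
            return pd.Timestamp(t)
        except (ValueError, TypeError) as exc:
            raise IntervalParseError(
                f"cannot parse {side} endpoint {token!r} as an ISO-8601 timestamp"
            ) from exc
    try:
        return float(t)
    except ValueError as exc:
        raise IntervalParseError(
            f"cannot parse {side} endpoint {token!r} as a number"
        ) from exc


def parse_interval(text: str, kind: str = "numeric") -> Interval:
    """Parse an interval literal such as ``"[0;200]"`` or ``"(0;Inf)"``.

    The grammar is ``("[" | "(") lower ";" upper ("]" | ")")`` with
    ``-Inf``/``Inf`` allowed on either side.  For ``kind="datetime"``
    endpoints are ISO-8601 timestamps.  The separator is ``;`` so that
    decimal commas can never be mistaken for the delimiter.
    """
    if not isinstance(text, str):
        raise IntervalParseError(f"interval literal must be a string, got {text!r}")
    m = _INTERVAL_RE.match(text)
    if m is None:
        raise IntervalParseError(f"malformed interval literal {text!r}")
    lb, lo_tok, hi_tok, ub = m.groups()
    lower = _parse_endpoint(lo_tok, kind, "lower")
    upper = _parse_endpoint(hi_tok, kind, "upper")
    return Interval(lower, upper, lower_closed=(lb == "["), upper_closed=(ub == "]"))


# ---------------------------------------------------------------------------
# Variable metadata
# ---------------------------------------------------------------------------

#: Fixed metadata column vocabulary (item-level, one row per variable).
METADATA_COLUMNS = (
    "VAR_NAMES",
    "LABEL",
    "DATA_TYPE",
    "HARD_LIMITS",
    "SOFT_LIMITS",
    "DETECTION_LIMITS",
    "VALUE_LABELS",
    "MISSING_LIST",
    "JUMP_LIST",
    "STUDY_SEGMENT",
    "KEY_OBSERVER",
    "KEY_DATETIME",
)
#: Optional extra columns recognised when present.
OPTIONAL_COLUMNS = ("ROLE", "SOURCE_TABLE", "DISTRIBUTION", "DECIMALS")


@dataclass
class VariableMetadata:
    """Expectations for a single study variable."""

    var_name: str
    label: str = ""
    data_type: str = "string"
    hard_limits: Interval | None = None
    soft_limits: Interval | None = None
    detection_limits: Interval | None = None
    admissible_categories: dict | None = None  # code -> label
    missing_codes: dict = field(default_factory=dict)  # code -> reason label
    jump_codes: dict = field(default_factory=dict)
    segment: str | None = None
    role: str = "measurement"
    key_observer: str | None = None  # var name of the examiner variable
    key_datetime: str | None = None  # var name of the timestamp variable
    source_table: str | None = None
    distribution: str | None = None  # expected family: normal/gamma/uniform
    decimals: int | None = None

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise MetadataError(
                f"{self.var_name}: unknown data_type {self.data_type!r}"
            )
        if self.role not in ROLES:
            raise MetadataError(f"{self.var_name}: unknown role {self.role!r}")
        if self.soft_limits is not None and self.hard_limits is not None:
            h, s = self.hard_limits, self.soft_limits
            lo_ok = s.lower > h.lower or (
                s.lower == h.lower and (h.lower_closed or not s.lower_closed)
            )
            hi_ok = s.upper < h.upper or (
                s.upper == h.upper and (h.upper_closed or not s.upper_closed)
            )
            if not (lo_ok and hi_ok):
                raise MetadataError(
                    f"{self.var_name}: soft limits {s} not contained in hard limits {h}"
                )
        if self.admissible_categories:
            overlap = (
                set(self.missing_codes) | set(self.jump_codes)
            ) & set(self.admissible_categories)
            if overlap:
                raise MetadataError(
                    f"{self.var_name}: codes {sorted(overlap)} are both admissible "
                    "categories and missing/jump codes"
                )

    @property
    def all_codes(self) -> set:
        return set(self.missing_codes) | set(self.jump_codes)

    @property
    def is_numeric(self) -> bool:
        return self.data_type in ("integer", "float")


class MetadataTable:
    """Validated collection of :class:`VariableMetadata`, keyed by name."""

    def __init__(self, variables: Iterable[VariableMetadata]):
        self._vars: dict[str, VariableMetadata] = {}
        for v in variables:
            if v.var_name in self._vars:
                raise MetadataError(f"duplicate var_name {v.var_name!r}")
            self._vars[v.var_name] = v

    def __len__(self):
        return len(self._vars)

    def __iter__(self):
        return iter(self._vars.values())

    def __contains__(self, name):
        return name in self._vars

    def __getitem__(self, name) -> VariableMetadata:
        return self._vars[name]

    def get(self, name, default=None):
        return self._vars.get(name, default)

    @property
    def var_names(self) -> list[str]:
        return list(self._vars)

    def by_segment(self) -> dict[str, list[str]]:
        """Measurement variables grouped by study segment."""
        out: dict[str, list[str]] = {}
        for v in self:
            if v.segment and v.role == "measurement":
                out.setdefault(v.segment, []).append(v.var_name)
        return out

    def measurement_vars(self) -> list[str]:
        return [v.var_name for v in self if v.role == "measurement"]

    def process_vars(self) -> list[str]:
        return [v.var_name for v in self if v.role.startswith("process")]

    def id_vars(self) -> list[str]:
        return [v.var_name for v in self if v.role == "identifier"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self:
            rows.append(
                {
                    "VAR_NAMES": v.var_name,
                    "LABEL": v.label,
                    "DATA_TYPE": v.data_type,
                    "HARD_LIMITS": str(v.hard_limits) if v.hard_limits else "",
                    "SOFT_LIMITS": str(v.soft_limits) if v.soft_limits else "",
                    "DETECTION_LIMITS": str(v.detection_limits)
                    if v.detection_limits
                    else "",
                    "VALUE_LABELS": _format_code_map(v.admissible_categories),
                    "MISSING_LIST": _format_code_map(v.missing_codes),
                    "JUMP_LIST": _format_code_map(v.jump_codes),
                    "STUDY_SEGMENT": v.segment or "",
                    "KEY_OBSERVER": v.key_observer or "",
                    "KEY_DATETIME": v.key_datetime or "",
                    "ROLE": v.role,
                    "SOURCE_TABLE": v.source_table or "",
                    "DISTRIBUTION": v.distribution or "",
                    "DECIMALS": "" if v.decimals is None else str(v.decimals),
                }
            )
        return pd.DataFrame(rows)


def _format_code_map(codes: Mapping | None) -> str:
    if not codes:
        return ""
    return " | ".join(f"{c} = {lab}" for c, lab in codes.items())


def _parse_code_map(text, var: str, what: str) -> dict:
    """Parse ``code = label | code = label`` pairs; codes are numbers."""
    if text is None or (isinstance(text, float) and math.isnan(text)) or text == "":
        return {}
    out: dict = {}
    for piece in str(text).split("|"):
        piece = piece.strip()
        if not piece:
            continue
        if "=" in piece:
            code_s, label = piece.split("=", 1)
        else:
            code_s, label = piece, ""
        code_s = code_s.strip()
        try:
            code = float(code_s)
            if code == int(code):
                code = int(code)
        except ValueError:
            warnings.warn(
                f"{var}: cannot parse {what} code {code_s!r}; entry skipped"
            )
            continue
        out[code] = label.strip()
    return out


def _cell(row, col):
    v = row.get(col, "")
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return str(v).strip()


def load_metadata(source) -> MetadataTable:
    """Read an item-level metadata table (CSV/TSV path or DataFrame).

    One row per variable with the documented column names
    (``VAR_NAMES``, ``DATA_TYPE``, limit and code-map columns, ...).
    Unparseable optional fields produce warnings rather than failures;
    a missing ``VAR_NAMES`` or ``DATA_TYPE`` is a hard error.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    if df.empty:
        warnings.warn("metadata table is empty")
        return MetadataTable([])
    for required in ("VAR_NAMES", "DATA_TYPE"):
        if required not in df.columns:
            raise MetadataError(f"metadata table lacks required column {required}")

    # infer roles from KEY_OBSERVER / KEY_DATETIME references when no ROLE col
    observer_vars = set()
    time_vars = set()
    for _, row in df.iterrows():
        if _cell(row, "KEY_OBSERVER"):
            observer_vars.add(_cell(row, "KEY_OBSERVER"))
        if _cell(row, "KEY_DATETIME"):
            time_vars.add(_cell(row, "KEY_DATETIME"))

    records = []
    for _, row in df.iterrows():
        name = _cell(row, "VAR_NAMES")
        if not name:
            raise MetadataError("metadata row with empty VAR_NAMES")
        dtype = _cell(row, "DATA_TYPE").lower()
        kind = "datetime" if dtype == "datetime" else "numeric"

        def limit(col):
            text = _cell(row, col)
            if not text:
                return None
            try:
                return parse_interval(text, kind=kind)
            except IntervalParseError as exc:
                warnings.warn(f"{name}: ignoring {col} ({exc})")
                return None

        role = _cell(row, "ROLE")
        if not role:
            if name in observer_vars:
                role = "process-examiner"
            elif name in time_vars:
                role = "process-time"
            else:
                role = "measurement"
        decimals = _cell(row, "DECIMALS")
        records.append(
            VariableMetadata(
                var_name=name,
                label=_cell(row, "LABEL"),
                data_type=dtype,
                hard_limits=limit("HARD_LIMITS"),
                soft_limits=limit("SOFT_LIMITS"),
                detection_limits=limit("DETECTION_LIMITS"),
                admissible_categories=_parse_code_map(
                    _cell(row, "VALUE_LABELS"), name, "category"
                )
                or None,
                missing_codes=_parse_code_map(
                    _cell(row, "MISSING_LIST"), name, "missing"
                ),
                jump_codes=_parse_code_map(_cell(row, "JUMP_LIST"), name, "jump"),
                segment=_cell(row, "STUDY_SEGMENT") or None,
                role=role,
                key_observer=_cell(row, "KEY_OBSERVER") or None,
                key_datetime=_cell(row, "KEY_DATETIME") or None,
                source_table=_cell(row, "SOURCE_TABLE") or None,
                distribution=_cell(row, "DISTRIBUTION").lower() or None,
                decimals=int(decimals) if decimals else None,
            )
        )
    return MetadataTable(records)


# ---------------------------------------------------------------------------
# Indicator registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistryEntry:
    id: str
    name: str
    dimension: str
    domain: str
    implemented: bool


@dataclass(frozen=True)
class IndicatorRegistry:
    entries: tuple[RegistryEntry, ...]

    def __getitem__(self, indicator_id: str) -> RegistryEntry:
        for e in self.entries:
            if e.id == indicator_id:
                return e
        raise KeyError(indicator_id)

    def __contains__(self, indicator_id: str) -> bool:
        return any(e.id == indicator_id for e in self.entries)

    @property
    def dimensions(self) -> tuple[str, ...]:
        seen = []
        for e in self.entries:
            if e.dimension not in seen:
                seen.append(e.dimension)
        return tuple(seen)

    def implemented_ids(self) -> list[str]:
        return [e.id for e in self.entries if e.implemented]


_REGISTRY_SPEC = [
    # id, name, dimension, domain, implemented
    ("DQI-1001", "Unexpected data elements", "integrity", "structural data set error", True),
    ("DQI-1002", "Unexpected data records", "integrity", "structural data set error", True),
    ("DQI-1003", "Duplicates", "integrity", "structural data set error", True),
    ("DQI-1004", "Data record mismatch", "integrity", "relational data set error", True),
    ("DQI-1005", "Data element mismatch", "integrity", "relational data set error", True),
    ("DQI-1006", "Data type mismatch", "integrity", "value format error", True),
    ("DQI-1007", "Inhomogeneous value formats", "integrity", "value format error", True),
    ("DQI-1008", "Uncertain missingness status", "integrity", "value format error", True),
    ("DQI-2001", "Missing values", "completeness", "crude missingness", True),
    ("DQI-2002", "Non-response rate", "completeness", "qualified missingness", True),
    ("DQI-2003", "Refusal rate", "completeness", "qualified missingness", True),
    ("DQI-2004", "Drop-out rate", "completeness", "qualified missingness", True),
    ("DQI-2005", "Missing due to specified reason", "completeness", "qualified missingness", True),
    ("DQI-3001", "Inadmissible numerical values", "consistency", "range and value violations", True),
    ("DQI-3002", "Inadmissible time-date values", "consistency", "range and value violations", True),
    ("DQI-3003", "Inadmissible categorical values", "consistency", "range and value violations", True),
    ("DQI-3004", "Inadmissible standardized vocabulary", "consistency", "range and value violations", False),
    ("DQI-3005", "Inadmissible precision", "consistency", "range and value violations", False),
    ("DQI-3006", "Uncertain numerical values", "consistency", "range and value violations", True),
    ("DQI-3007", "Uncertain time-date values", "consistency", "range and value violations", True),
    ("DQI-3008", "Logical contradictions", "consistency", "contradictions", True),
    ("DQI-3009", "Empirical contradictions", "consistency", "contradictions", True),
    ("DQI-4001", "Univariate outliers", "accuracy", "unexpected distributions", True),
    ("DQI-4002", "Multivariate outliers", "accuracy", "unexpected distributions", True),
    ("DQI-4003", "Unexpected locations", "accuracy", "unexpected distributions", True),
    ("DQI-4004", "Unexpected shape", "accuracy", "unexpected distributions", True),
    ("DQI-4005", "Unexpected scale", "accuracy", "unexpected distributions", True),
    ("DQI-4006", "Unexpected proportions", "accuracy", "unexpected distributions", True),
    ("DQI-4007", "Unexpected association strength", "accuracy", "unexpected associations", False),
    ("DQI-4008", "Unexpected association direction", "accuracy", "unexpected associations", False),
    ("DQI-4009", "Unexpected association form", "accuracy", "unexpected associations", False),
    ("DQI-4010", "Inter-class reliability", "accuracy", "disagreement of repeated measurements", True),
    ("DQI-4011", "Intra-class reliability", "accuracy", "disagreement of repeated measurements", False),
    ("DQI-4012", "Disagreement with gold standard", "accuracy", "disagreement of repeated measurements", False),
]

_REGISTRY = IndicatorRegistry(
    entries=tuple(RegistryEntry(*row) for row in _REGISTRY_SPEC)
)


def registry() -> IndicatorRegistry:
    """The static indicator registry: 34 indicators across 4 dimensions."""
    return _REGISTRY


# ---------------------------------------------------------------------------
# Indicator results
# ---------------------------------------------------------------------------


@dataclass
class IndicatorResult:
    """Outcome of one check for one variable (or the whole study).

    ``percent`` is ``100 * n_flagged / denominator`` and undefined
    (``None``) when the denominator is zero.  ``flagged_cells`` carries
    ``(record_id, var_name)`` coordinates for cell-level indicators.
    ``descriptor`` holds non-decision payloads (binned counts, smoothed
    series, ...) that a human interprets.
    """

    indicator_id: str
    variable: str = "study-level"
    n_flagged: int = 0
    denominator: int = 0
    flagged_cells: list = field(default_factory=list)
    descriptor: dict | None = None
    grading: str = "ok"  # ok | issue | not-applicable

    def __post_init__(self):
        if self.grading == "ok" and self.n_flagged > 0:
            self.grading = "issue"

    @property
    def percent(self) -> float | None:
        if self.denominator <= 0:
            return None
        return 100.0 * self.n_flagged / self.denominator

    def to_dict(self) -> dict:
        pct = self.percent
        out = {
            "indicator_id": self.indicator_id,
            "variable": self.variable,
            "n_flagged": int(self.n_flagged),
            "denominator": int(self.denominator),
            "percent": None if pct is None else round(pct, 1),
            "grading": self.grading,
            "flagged_cells": [[str(r), str(v)] for r, v in self.flagged_cells],
        }
        if self.descriptor is not None:
            out["descriptor"] = self.descriptor
        return out


# ---------------------------------------------------------------------------
# Contradiction rules
# ---------------------------------------------------------------------------

_SIDE_KINDS = ("cat", "num", "date", "miss")
#: The 16 two-variable predicate templates: each side tests membership in
#: a category set, a numeric interval, a datetime interval, or the
#: qualified-missing state; a rule fires when both sides hold for a unit.
PREDICATE_CODES = tuple(f"{a}_{b}" for a in _SIDE_KINDS for b in _SIDE_KINDS)


@dataclass
class ContradictionRule:
    """A parameterised two-variable contradiction predicate."""

    rule_id: str
    predicate_code: str
    var_a: str
    var_b: str
    params_a: object = None  # set of codes, Interval, or None for 'miss'
    params_b: object = None
    label: str = ""
    rule_class: str = "logical"  # logical | empirical

    def __post_init__(self):
        if self.predicate_code not in PREDICATE_CODES:
            raise MetadataError(
                f"rule {self.rule_id}: unknown predicate code "
                f"{self.predicate_code!r} (must be one of the 16 templates)"
            )
        if self.var_a == self.var_b:
            raise MetadataError(f"rule {self.rule_id}: var_a equals var_b")
        if self.rule_class not in ("logical", "empirical"):
            raise MetadataError(
                f"rule {self.rule_id}: class must be logical or empirical"
            )

    @property
    def side_kinds(self) -> tuple[str, str]:
        a, b = self.predicate_code.split("_")
        return a, b


def _parse_rule_params(text, kind: str):
    if kind == "miss":
        return None
    text = "" if text is None else str(text).strip()
    if kind == "cat":
        vals = set()
        for tok in text.split("|"):
            tok = tok.strip()
            if not tok:
                continue
            try:
                f = float(tok)
                vals.add(int(f) if f == int(f) else f)
            except ValueError:
                vals.add(tok)
        return vals
    return parse_interval(text, kind="datetime" if kind == "date" else "numeric")


def load_rules(source) -> list[ContradictionRule]:
    """Read a contradiction-rule table (CSV path or DataFrame).

    Columns: ``rule_id, predicate_code, var_a, params_a, var_b,
    params_b, class, label``.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    rules = []
    for _, row in df.iterrows():
        code = _cell(row, "predicate_code")
        kind_a, kind_b = (code.split("_") + ["", ""])[:2] if "_" in code else ("", "")
        rules.append(
            ContradictionRule(
                rule_id=_cell(row, "rule_id"),
                predicate_code=code,
                var_a=_cell(row, "var_a"),
                var_b=_cell(row, "var_b"),
                params_a=_parse_rule_params(_cell(row, "params_a"), kind_a),
                params_b=_parse_rule_params(_cell(row, "params_b"), kind_b),
                label=_cell(row, "label"),
                rule_class=_cell(row, "class") or "logical",
            )
        )
    return rules


def rules_to_frame(rules: Sequence[ContradictionRule]) -> pd.DataFrame:
    def fmt(params, kind):
        if kind == "miss" or params is None:
            return ""
        if isinstance(params, Interval):
            return str(params)
        return " | ".join(str(p) for p in sorted(params, key=str))

    rows = []
    for r in rules:
        ka, kb = r.side_kinds
        rows.append(
            {
                "rule_id": r.rule_id,
                "predicate_code": r.predicate_code,
                "var_a": r.var_a,
                "params_a": fmt(r.params_a, ka),
                "var_b": r.var_b,
                "params_b": fmt(r.params_b, kb),
                "class": r.rule_class,
                "label": r.label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Raw-value helpers shared by the checks
# ---------------------------------------------------------------------------


def load_study(path) -> pd.DataFrame:
    """Read a study table as raw strings (empty cells -> NaN).

    All checks operate on the raw textual representation so that type
    probing and code detection are possible even on deficient data.
    """
    return pd.read_csv(
        path, sep=None, engine="python", dtype=str, keep_default_na=False,
        na_values=[""],
    )


def is_system_missing(series: pd.Series) -> np.ndarray:
    """Empty-cell mask on a raw column."""
    s = series.astype("object")
    return (
        s.isna() | s.astype(str).str.strip().isin(["", "NA", "NaN", "nan", "."])
    ).to_numpy()


def numeric_values(series: pd.Series) -> pd.Series:
    """Best-effort numeric coercion; unconvertible cells become NaN."""
    return pd.to_numeric(series, errors="coerce")


def code_mask(series: pd.Series, codes: Iterable) -> np.ndarray:
    """Cells equal to one of the qualified codes (numeric comparison when
    possible, else exact string match)."""
    codes = list(codes)
    if not codes:
        return np.zeros(len(series), dtype=bool)
    num = numeric_values(series)
    numeric_codes = [c for c in codes if isinstance(c, (int, float))]
    mask = num.isin(numeric_codes).to_numpy()
    str_codes = {str(c) for c in codes}
    mask |= series.astype(str).str.strip().isin(str_codes).to_numpy()
    mask &= ~is_system_missing(series)
    return mask
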