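"""Synthetic cohort-study generator with a ground-truth defect ledger.

Emulates the structure of a population-based examination survey: a
somatometric examination (height, weight, waist circumference), a
blood-pressure measurement (systolic/diastolic, with examiner and
examination-date process variables) and a computer-assisted interview
(smoking, marital status, contraceptive intake), for a default of
2154 observational units examined by 5 examiners.

Clean values are drawn inside the soft limits (truncated normals for
measurements), so a zero-defect draw produces zero deterministic
flags.  :func:`inject_issues` then plants defects whose coordinates
and types are logged in a :class:`DefectLedger` — the ground truth
against which every check's recovery is tested.  Only structural
emulation is attempted; no attempt is made to match real survey
marginals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .core_model import (
    ContradictionRule,
    Interval,
    MetadataTable,
    load_metadata,
    parse_interval,
)

__all__ = [
    "GeneratorConfig",
    "DefectSpec",
    "DefectLedger",
    "generate_study",
    "inject_issues",
    "default_metadata_frame",
    "default_rules",
]

MISSING_REFUSAL = 99980
MISSING_NOT_ASSESSABLE = 99981
JUMP_NOT_APPLICABLE = 99983


@dataclass
class DefectSpec:
    """Per-variable defect types and rates (all rates in [0, 1])."""

    type_mismatch: dict = field(default_factory=lambda: {"waist": 0.01})
    system_missing: dict = field(
        default_factory=lambda: {
            "height": 0.02,
            "weight": 0.01,
            "sbp": 0.02,
            "dbp": 0.02,
            "smoking": 0.01,
        }
    )
    coded_missing: dict = field(
        default_factory=lambda: {
            "height": {MISSING_REFUSAL: 0.01},
            "sbp": {MISSING_REFUSAL: 0.015, MISSING_NOT_ASSESSABLE: 0.005},
            "smoking": {MISSING_REFUSAL: 0.01},
            "marital": {MISSING_REFUSAL: 0.005},
        }
    )
    hard_violation: dict = field(
        default_factory=lambda: {"sbp": 0.005, "dbp": 0.005}
    )
    soft_violation: dict = field(
        default_factory=lambda: {"sbp": 0.01, "dbp": 0.01}
    )
    inadmissible: dict = field(default_factory=lambda: {"smoking": 0.01})
    #: rule_id -> number of units forced into the firing combination
    contradiction: dict = field(default_factory=lambda: {"R1": 7, "R2": 5})
    #: variable -> number of planted 6-sigma outliers
    outlier: dict = field(default_factory=dict)
    #: variable -> (examiner class label, shift in units of the SD)
    examiner_shift: dict = field(default_factory=dict)
    #: variable -> fraction of values rounded to end digit 0
    digit_preference: dict = field(default_factory=dict)
    #: variable -> (examiner class label, total drift in SD over the study)
    drift: dict = field(default_factory=dict)

    def validate(self):
        for name in ("type_mismatch", "system_missing", "hard_violation",
                     "soft_violation", "inadmissible", "digit_preference"):
            for var, rate in getattr(self, name).items():
                if not 0 <= rate <= 1:
                    raise ValueError(
                        f"{name} rate for {var!r} outside [0,1]: {rate}"
                    )
        for var, codes in self.coded_missing.items():
            for code, rate in codes.items():
                if not 0 <= rate <= 1:
                    raise ValueError(
                        f"coded_missing rate for {var!r}/{code} outside [0,1]"
                    )


@dataclass
class GeneratorConfig:
    n: int = 2154
    n_examiners: int = 5
    date_start: str = "1997-03-01"
    date_end: str = "2001-06-30"
    defects: DefectSpec = field(default_factory=DefectSpec)
    #: extra roster IDs with no study record (unit nonresponse)
    n_roster_only: int = 0


class DefectLedger:
    """Ground truth of injected defects: one row per affected cell."""

    COLUMNS = ("record_id", "var_name", "defect_type", "true_value")

    def __init__(self, entries=None):
        self.entries = list(entries or [])

    def add(self, record_id, var_name, defect_type, true_value=""):
        self.entries.append(
            (str(record_id), str(var_name), str(defect_type), str(true_value))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=list(self.COLUMNS))

    def count(self, defect_type_prefix: str, var_name: str | None = None) -> int:
        return sum(
            1
            for _, v, d, _ in self.entries
            if d.startswith(defect_type_prefix)
            and (var_name is None or v == var_name)
        )

    def cells(self, defect_type_prefix: str, var_name: str | None = None):
        return {
            (r, v)
            for r, v, d, _ in self.entries
            if d.startswith(defect_type_prefix)
            and (var_name is None or v == var_name)
        }

    def __len__(self):
        return len(self.entries)


# ---------------------------------------------------------------------------
# Variable plan
# ---------------------------------------------------------------------------

# measurement plan: (mean, sd, soft lo/hi, hard lo/hi, decimals, segment)
_CONTINUOUS = {
    "height": (170.0, 10.0, 130.0, 210.0, 100.0, 250.0, 1, "somatometry"),
    "weight": (77.0, 14.0, 40.0, 150.0, 20.0, 300.0, 1, "somatometry"),
    "waist": (90.0, 13.0, 50.0, 150.0, 30.0, 250.0, 1, "somatometry"),
    "sbp": (130.0, 16.0, 90.0, 220.0, 60.0, 300.0, 0, "blood_pressure"),
    "dbp": (80.0, 10.0, 50.0, 130.0, 30.0, 200.0, 0, "blood_pressure"),
}
_CATEGORICAL = {
    "sex": ({0: "female", 1: "male"}, [0.52, 0.48], "interview"),
    "smoking": (
        {0: "never", 1: "former", 2: "current"}, [0.45, 0.25, 0.30],
        "interview",
    ),
    "marital": (
        {1: "married", 2: "single", 3: "divorced", 4: "widowed"},
        [0.55, 0.25, 0.10, 0.10], "interview",
    ),
    "contraceptives": ({0: "no", 1: "yes"}, None, "interview"),
}

_MISSING_LIST = (
    f"{MISSING_REFUSAL} = refusal | {MISSING_NOT_ASSESSABLE} = not assessable"
)


def default_metadata_frame(n_examiners: int = 5) -> pd.DataFrame:
    """Item-level metadata table matching the generated study."""
    rows = [
        dict(VAR_NAMES="id", LABEL="participant pseudonym",
             DATA_TYPE="integer", ROLE="identifier"),
        dict(VAR_NAMES="sex", LABEL="sex", DATA_TYPE="integer",
             VALUE_LABELS="0 = female | 1 = male",
             MISSING_LIST=_MISSING_LIST, STUDY_SEGMENT="interview"),
        dict(VAR_NAMES="age", LABEL="age at examination",
             DATA_TYPE="integer", HARD_LIMITS="[0;120]",
             MISSING_LIST=_MISSING_LIST, STUDY_SEGMENT="interview"),
    ]
    for var, (m, s, slo, shi, hlo, hhi, dec, seg) in _CONTINUOUS.items():
        row = dict(
            VAR_NAMES=var,
            LABEL={"sbp": "systolic blood pressure",
                   "dbp": "diastolic blood pressure",
                   "waist": "waist circumference"}.get(var, var),
            DATA_TYPE="float" if dec > 0 else "integer",
            HARD_LIMITS=f"[{hlo:g};{hhi:g}]",
            SOFT_LIMITS=f"[{slo:g};{shi:g}]",
            MISSING_LIST=_MISSING_LIST,
            STUDY_SEGMENT=seg,
            KEY_OBSERVER="examiner",
            KEY_DATETIME="exam_date",
            DECIMALS=str(dec),
        )
        if var == "height":
            row["DISTRIBUTION"] = "normal"
            row["DETECTION_LIMITS"] = "[100;230]"
        rows.append(row)
    for var, (levels, _, seg) in _CATEGORICAL.items():
        if var == "sex":
            continue
        row = dict(
            VAR_NAMES=var,
            LABEL={"contraceptives": "intake of contraceptives"}.get(var, var),
            DATA_TYPE="integer",
            VALUE_LABELS=" | ".join(f"{c} = {l}" for c, l in levels.items()),
            MISSING_LIST=_MISSING_LIST,
            STUDY_SEGMENT=seg,
        )
        if var == "contraceptives":
            row["JUMP_LIST"] = f"{JUMP_NOT_APPLICABLE} = jump: not applicable"
        rows.append(row)
    rows.append(
        dict(VAR_NAMES="examiner", LABEL="examiner ID", DATA_TYPE="integer",
             VALUE_LABELS=" | ".join(
                 f"{i} = examiner {i}" for i in range(1, n_examiners + 1)
             ),
             ROLE="process-examiner")
    )
    rows.append(
        dict(VAR_NAMES="exam_date", LABEL="examination date",
             DATA_TYPE="datetime", HARD_LIMITS="[1997-01-01;2002-12-31]",
             ROLE="process-time")
    )
    df = pd.DataFrame(rows)
    return df.fillna("")


def default_rules() -> list[ContradictionRule]:
    """The fixture's contradiction rule table.

    R1 (logical): a male participant reporting contraceptive intake.
    R2 (empirical): contraceptive intake reported at age 55 or above.
    """
    return [
        ContradictionRule(
            rule_id="R1", predicate_code="cat_cat",
            var_a="sex", params_a={1},
            var_b="contraceptives", params_b={1},
            label="male with contraceptive intake", rule_class="logical",
        ),
        ContradictionRule(
            rule_id="R2", predicate_code="cat_num",
            var_a="contraceptives", params_a={1},
            var_b="age", params_b=Interval(55.0, 120.0),
            label="contraceptive intake at age 55+", rule_class="empirical",
        ),
    ]


def _rng(seed: int, name: str) -> np.random.Generator:
    # counter-based sub-seeding: one stream per variable/defect so that
    # adding a stream never reshuffles the others
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _trunc_normal(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return st.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _fmt(value: float, decimals: int) -> str:
    if decimals <= 0:
        return str(int(round(value)))
    return f"{value:.{decimals}f}"


def generate_clean(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Defect-free study table (raw strings, one row per unit)."""
    n = config.n
    ids = np.arange(1, n + 1)
    frame = {"id": [str(i) for i in ids]}

    sex = _rng(seed, "sex").choice([0, 1], size=n, p=_CATEGORICAL["sex"][1])
    frame["sex"] = [str(v) for v in sex]
    age = _rng(seed, "age").integers(20, 80, size=n)
    frame["age"] = [str(v) for v in age]

    for var, (m, s, slo, shi, _, _, dec, _) in _CONTINUOUS.items():
        vals = _trunc_normal(_rng(seed, var), n, m, s, slo, shi)
        frame[var] = [_fmt(v, dec) for v in vals]

    for var in ("smoking", "marital"):
        levels, probs, _ = _CATEGORICAL[var]
        draw = _rng(seed, var).choice(list(levels), size=n, p=probs)
        frame[var] = [str(v) for v in draw]

    # contraceptive intake: asked of women only (men get the jump code);
    # only women under 50 report intake
    rng_c = _rng(seed, "contraceptives")
    contra = []
    for i in range(n):
        if sex[i] == 1:
            contra.append(str(JUMP_NOT_APPLICABLE))
        elif age[i] < 50:
            contra.append(str(int(rng_c.random() < 0.30)))
        else:
            contra.append("0")
    frame["contraceptives"] = contra

    frame["examiner"] = [
        str(v)
        for v in _rng(seed, "examiner").integers(
            1, config.n_examiners + 1, size=n
        )
    ]
    t0 = pd.Timestamp(config.date_start).value
    t1 = pd.Timestamp(config.date_end).value
    days = _rng(seed, "exam_date").integers(
        0, (t1 - t0) // 86_400_000_000_000 + 1, size=n
    )
    dates = pd.Timestamp(config.date_start) + pd.to_timedelta(days, unit="D")
    frame["exam_date"] = dates.strftime("%Y-%m-%d").tolist()
    return pd.DataFrame(frame)


_MISMATCH_TOKENS = ("n/a", "12,5", "abc", "--")


def inject_issues(
    clean: pd.DataFrame,
    metadata: MetadataTable,
    rules: list[ContradictionRule],
    spec: DefectSpec,
    seed: int,
) -> tuple[pd.DataFrame, DefectLedger]:
    """Plant defects into a clean study table.

    Every injected value is guaranteed to actually violate the targeted
    rule (hard-violation values are drawn strictly outside the hard
    limits, soft violations strictly between soft and hard limits,
    etc.), and every touched cell is logged.  Cells not in the ledger
    match the clean draw exactly.
    """
    spec.validate()
    dirty = clean.copy()
    ledger = DefectLedger()
    n = len(dirty)
    used: dict[str, set] = {}
    rid = dirty["id"] if "id" in dirty.columns else pd.Series(
        dirty.index.astype(str)
    )

    def pick(var, rng, count, eligible=None):
        pool = np.arange(n) if eligible is None else np.asarray(eligible)
        pool = np.array([i for i in pool if i not in used.setdefault(var, set())])
        count = min(count, len(pool))
        chosen = rng.choice(pool, size=count, replace=False) if count else []
        used[var].update(int(i) for i in chosen)
        return [int(i) for i in chosen]

    def n_from_rate(rng, rate):
        return int(rng.binomial(n, rate))

    for var, rate in spec.type_mismatch.items():
        md = metadata.get(var)
        if md is None or md.data_type == "string":
            raise ValueError(
                f"type-mismatch injection needs a typed variable: {var!r}"
            )
        rng = _rng(seed, f"defect:type_mismatch:{var}")
        for i in pick(var, rng, n_from_rate(rng, rate)):
            ledger.add(rid.iloc[i], var, "type-mismatch", dirty.at[i, var])
            dirty.at[i, var] = _MISMATCH_TOKENS[
                int(rng.integers(len(_MISMATCH_TOKENS)))
            ]

    for var, rate in spec.system_missing.items():
        rng = _rng(seed, f"defect:system_missing:{var}")
        for i in pick(var, rng, n_from_rate(rng, rate)):
            ledger.add(rid.iloc[i], var, "system-missing", dirty.at[i, var])
            dirty.at[i, var] = np.nan

    for var, codes in spec.coded_missing.items():
        md = metadata.get(var)
        for code, rate in codes.items():
            if md is None or code not in md.missing_codes:
                raise ValueError(
                    f"coded-missing injection: {code} is not a declared "
                    f"missing code of {var!r}"
                )
            rng = _rng(seed, f"defect:coded_missing:{var}:{code}")
            for i in pick(var, rng, n_from_rate(rng, rate)):
                ledger.add(
                    rid.iloc[i], var, f"coded-missing:{code}",
                    dirty.at[i, var],
                )
                dirty.at[i, var] = str(code)

    def draw_outside(rng, interval: Interval, inner: Interval | None, decimals):
        """A value strictly violating `interval`, inside `inner` if given."""
        below_lo = (
            float(inner.lower) + 1.0 if inner is not None
            else float(interval.lower) - 40.0
        )
        below_hi = float(interval.lower) - 1.0
        above_lo = float(interval.upper) + 1.0
        above_hi = (
            float(inner.upper) - 1.0 if inner is not None
            else float(interval.upper) + 40.0
        )
        sides = []
        if below_lo <= below_hi:
            sides.append((below_lo, below_hi))
        if above_lo <= above_hi:
            sides.append((above_lo, above_hi))
        lo, hi = sides[int(rng.integers(len(sides)))]
        return float(np.round(rng.uniform(lo, hi), decimals))

    for var, rate in spec.hard_violation.items():
        md = metadata.get(var)
        if md is None or md.hard_limits is None:
            raise ValueError(
                f"hard-violation injection: {var!r} has no hard limits"
            )
        dec = md.decimals or 0
        rng = _rng(seed, f"defect:hard:{var}")
        for i in pick(var, rng, n_from_rate(rng, rate)):
            v = draw_outside(rng, md.hard_limits, None, dec)
            ledger.add(rid.iloc[i], var, "hard-violation", dirty.at[i, var])
            dirty.at[i, var] = _fmt(v, dec)

    for var, rate in spec.soft_violation.items():
        md = metadata.get(var)
        if md is None or md.soft_limits is None or md.hard_limits is None:
            raise ValueError(
                f"soft-violation injection: {var!r} needs hard and soft limits"
            )
        dec = md.decimals or 0
        rng = _rng(seed, f"defect:soft:{var}")
        for i in pick(var, rng, n_from_rate(rng, rate)):
            v = draw_outside(rng, md.soft_limits, md.hard_limits, dec)
            ledger.add(rid.iloc[i], var, "soft-violation", dirty.at[i, var])
            dirty.at[i, var] = _fmt(v, dec)

    for var, rate in spec.inadmissible.items():
        md = metadata.get(var)
        if md is None or not md.admissible_categories:
            raise ValueError(
                f"inadmissible injection: {var!r} has no admissible categories"
            )
        bad_level = max(
            int(c) for c in md.admissible_categories
            if isinstance(c, (int, float))
        ) + 6
        rng = _rng(seed, f"defect:inadmissible:{var}")
        for i in pick(var, rng, n_from_rate(rng, rate)):
            ledger.add(rid.iloc[i], var, "inadmissible", dirty.at[i, var])
            dirty.at[i, var] = str(bad_level)

    sex_num = pd.to_numeric(clean["sex"], errors="coerce") if "sex" in clean else None
    age_num = pd.to_numeric(clean["age"], errors="coerce") if "age" in clean else None
    rules_by_id = {r.rule_id: r for r in rules}
    for rule_id, k in spec.contradiction.items():
        rule = rules_by_id.get(rule_id)
        if rule is None:
            raise ValueError(f"contradiction injection: unknown rule {rule_id!r}")
        rng = _rng(seed, f"defect:contradiction:{rule_id}")
        if rule_id == "R1":
            eligible = np.flatnonzero(
                (sex_num == 1).to_numpy() & (age_num < 55).to_numpy()
            )
            target_var, target_val = "contraceptives", "1"
        elif rule_id == "R2":
            eligible = np.flatnonzero(
                (sex_num == 0).to_numpy() & (age_num >= 55).to_numpy()
            )
            target_var, target_val = "contraceptives", "1"
        else:
            raise ValueError(
                f"contradiction injection not defined for rule {rule_id!r}"
            )
        for i in pick(target_var, rng, k, eligible):
            ledger.add(
                rid.iloc[i], target_var, f"contradiction:{rule_id}",
                dirty.at[i, target_var],
            )
            dirty.at[i, target_var] = target_val

    for var, count in spec.outlier.items():
        m, s = _CONTINUOUS[var][0], _CONTINUOUS[var][1]
        dec = (metadata.get(var).decimals or 0) if metadata.get(var) else 1
        rng = _rng(seed, f"defect:outlier:{var}")
        for i in pick(var, rng, count):
            v = m + 6.0 * s  # guaranteed to fire the six-sigma rule
            ledger.add(rid.iloc[i], var, "outlier", dirty.at[i, var])
            dirty.at[i, var] = _fmt(v, dec)

    for var, (cls, shift_sd) in spec.examiner_shift.items():
        s = _CONTINUOUS[var][1]
        dec = (metadata.get(var).decimals or 0) if metadata.get(var) else 1
        cls_rows = np.flatnonzero(
            (dirty["examiner"].astype(str) == str(cls)).to_numpy()
        )
        num = pd.to_numeric(dirty[var], errors="coerce")
        for i in cls_rows:
            if pd.isna(num.iloc[i]):
                continue
            ledger.add(
                rid.iloc[i], var, f"examiner-shift:{cls}", dirty.at[i, var]
            )
            dirty.at[i, var] = _fmt(float(num.iloc[i]) + shift_sd * s, dec)

    for var, frac in spec.digit_preference.items():
        md = metadata.get(var)
        dec = (md.decimals or 0) if md else 0
        rng = _rng(seed, f"defect:digit:{var}")
        num = pd.to_numeric(dirty[var], errors="coerce")
        candidates = [i for i in np.flatnonzero(num.notna().to_numpy())]
        k = int(round(frac * len(candidates)))
        for i in pick(var, rng, k, candidates):
            # round so the end digit at the declared precision becomes 0
            v = round(float(num.iloc[i]), dec - 1) if dec > 0 else (
                10.0 * round(float(num.iloc[i]) / 10.0)
            )
            ledger.add(rid.iloc[i], var, "digit-preference", dirty.at[i, var])
            dirty.at[i, var] = _fmt(v, dec)

    for var, (cls, total_drift_sd) in spec.drift.items():
        s = _CONTINUOUS[var][1]
        dec = (metadata.get(var).decimals or 0) if metadata.get(var) else 1
        t = pd.to_datetime(dirty["exam_date"], errors="coerce")
        t0, t1 = t.min(), t.max()
        frac_t = (t - t0) / (t1 - t0)
        num = pd.to_numeric(dirty[var], errors="coerce")
        cls_rows = np.flatnonzero(
            (dirty["examiner"].astype(str) == str(cls)).to_numpy()
        )
        for i in cls_rows:
            if pd.isna(num.iloc[i]) or pd.isna(frac_t.iloc[i]):
                continue
            v = float(num.iloc[i]) + total_drift_sd * s * float(frac_t.iloc[i])
            ledger.add(rid.iloc[i], var, f"drift:{cls}", dirty.at[i, var])
            dirty.at[i, var] = _fmt(v, dec)

    return dirty, ledger


def generate_study(
    config: GeneratorConfig | None = None, seed: int = 0
):
    """Generate a complete synthetic study.

    Returns ``(study, metadata, rules, ledger)``: the dirty study table
    (raw strings), the matching :class:`MetadataTable`, the
    contradiction rule list and the ground-truth
    :class:`DefectLedger`.  The same seed always yields identical
    output.
    """
    config = config or GeneratorConfig()
    metadata = load_metadata(default_metadata_frame(config.n_examiners))
    rules = default_rules()
    clean = generate_clean(config, seed)
    dirty, ledger = inject_issues(clean, metadata, rules, config.defects, seed)
    return dirty, metadata, rules, ledger


def roster_for(config: GeneratorConfig, study: pd.DataFrame) -> list[str]:
    """Expected-unit roster: all study IDs plus any roster-only IDs."""
    ids = list(study["id"].astype(str))
    extra = [str(len(ids) + i + 1) for i in range(config.n_roster_only)]
    return ids + extra
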