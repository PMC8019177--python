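import warnings

import pandas as pd
import pytest

from dqframe.fixtures import GeneratorConfig, generate_study, roster_for
from dqframe.reporting import RunConfig, dq_report

SEGMENT_ORDER = ["interview", "somatometry", "blood_pressure"]


@pytest.fixture(scope="session")
def fixture_study():
    """Default synthetic study (n=2154, deterministic defects), seed 20."""
    study, metadata, rules, ledger = generate_study(seed=20)
    return study, metadata, rules, ledger


@pytest.fixture(scope="session")
def fixture_report(fixture_study):
    study, metadata, rules, ledger = fixture_study
    cfg = RunConfig(
        roster=roster_for(GeneratorConfig(), study),
        segment_order=SEGMENT_ORDER,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = dq_report(study, metadata, rules, cfg, seed=20)
    return report


def derive_expected_missingness(study, metadata, ledger):
    """Ground-truth missingness derived from the defect ledger by set
    arithmetic, independent of the completeness implementation.

    Missing cells are exactly the injected system/coded-missing cells
    plus the structural jump cells (contraceptives of male
    participants, minus those overwritten by contradiction injection).
    """
    meas = [v for v in metadata.measurement_vars() if v in study.columns]
    segments = metadata.by_segment()
    ids = study["id"].astype(str).tolist()

    missing_cells = set()
    for r, v, d, _ in ledger.entries:
        if d.startswith(("system-missing", "coded-missing")):
            missing_cells.add((r, v))
    overwritten = ledger.cells("contradiction")
    male_ids = set(study.loc[study["sex"] == "1", "id"].astype(str))
    jump_cells = {
        (r, "contraceptives") for r in male_ids
    } - overwritten
    all_missing_cells = missing_cells | jump_cells

    def unit_all_missing(rid, variables):
        return all((rid, v) in all_missing_cells for v in variables)

    unit_missing = {r for r in ids if unit_all_missing(r, meas)}
    segment_missing = {
        seg: {
            r
            for r in ids
            if r not in unit_missing and unit_all_missing(r, seg_vars)
        }
        for seg, seg_vars in segments.items()
    }
    return {
        "missing_cells": missing_cells,
        "jump_cells": jump_cells,
        "unit_missing": unit_missing,
        "segment_missing": segment_missing,
    }
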