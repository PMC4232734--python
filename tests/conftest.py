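"""Shared fixtures: default config, toy tariff and a hand-costed extract."""

from __future__ import annotations

import textwrap

import pandas as pd
import pytest

from anocost import TariffTable, hes, load_config
from anocost.synth import CohortGenConfig


def run_costing(records: pd.DataFrame, tariff: TariffTable):
    """Full filtering -> grouping -> costing chain used by the oracles."""
    invasive, in_situ = hes.filter_records(records)
    cohorts = pd.concat([invasive, in_situ], ignore_index=True)
    spells = hes.cost_spells(
        hes.group_spells(cohorts[cohorts["setting"] == "INPATIENT"]), tariff
    )
    attendances = hes.cost_attendances(
        cohorts[cohorts["setting"] == "OUTPATIENT"], tariff
    )
    return spells, attendances


def degenerate_config(n: int = 40) -> CohortGenConfig:
    """Generator settings with all randomness switched off except branch
    draws with probability 0 or 1, so totals match ground truth exactly."""
    return CohortGenConfig(
        n_patients=n,
        sex_ratio=1.0,
        mean_spells_per_patient=1.0,
        mean_attendances_per_patient=2.0,
        mean_los_days=4.0,
        admission_mix={"ELECTIVE": 1.0, "DAY_CASE": 0.0, "NON_ELECTIVE": 0.0},
        p_excess_bed_days={"ELECTIVE": 0.0, "DAY_CASE": 0.0, "NON_ELECTIVE": 0.0},
        diagnosis_mix={"C211": 1.0},
        hrg_mix={"FZ20B": 1.0},
        tfc_mix={"370": 1.0},
        p_chemo_unbundled=1.0,
        p_radio_unbundled=0.0,
        count_model="fixed",
        los_model="fixed",
        seed=11,
    )


@pytest.fixture()
def base_config():
    return load_config()


@pytest.fixture(scope="session")
def toy_tariff() -> TariffTable:
    """Small tariff used by the hand-costed fixture tests."""
    return TariffTable(
        inpatient={
            "AA01": {"elective": 1000.0, "non_elective": 1800.0, "day_case": 500.0,
                     "trim_point": 3.0, "excess_per_diem": 200.0},
            "BB02": {"elective": 2000.0, "non_elective": 3000.0, "day_case": 800.0,
                     "trim_point": 10.0, "excess_per_diem": 250.0},
        },
        outpatient={"104": 150.0, "WF01A": 140.0},
        unbundled={"SB12Z": 350.0, "SC22Z": 110.0, "XX90Z": 75.0},
    )


#: Ten-record extract covering spell merging, provider splits, excess bed
#: days, day cases, outpatient rules, an in-situ patient, a
#: tertiary-diagnosis-only outpatient (dropped) and a malformed code
#: (excluded).  Hand-costed expectations live in tests/test_hes.py.
FIXTURE_RECORDS_CSV = textwrap.dedent(
    """\
    patient_id,sex,age,provider,admission_date,discharge_date,admission_method,setting,diag1,diag2,diag3,procedures,hrg,tfc,unbundled,year
    p1,F,60,PRV1,2009-01-01,2009-01-02,ELECTIVE,INPATIENT,C211,,,,AA01,,SB12Z,2009
    p1,F,60,PRV1,2009-01-02,2009-01-06,ELECTIVE,INPATIENT,C211,,,,BB02,,,2009
    p1,F,60,PRV1,2009-03-01,2009-03-02,NON_ELECTIVE,INPATIENT,C210,,,,AA01,,SC22Z,2009
    p2,M,70,PRV2,2009-05-10,2009-05-10,DAY_CASE,INPATIENT,K602,C218,,,AA01,,XX90Z,2009
    p2,M,70,PRV3,2009-05-10,2009-05-12,ELECTIVE,INPATIENT,C218,,,,BB02,,,2009
    p3,F,55,PRV1,2010-02-01,2010-02-20,ELECTIVE,INPATIENT,D013,,,,BB02,,,2010
    p4,M,66,PRV1,2009-06-01,2009-06-01,DAY_CASE,OUTPATIENT,C211,,,,WF01A,104,,2009
    p4,M,66,PRV1,2009-07-01,2009-07-01,DAY_CASE,OUTPATIENT,,C211,,,WF01A,,SC22Z,2009
    p5,F,58,PRV1,2009-08-01,2009-08-01,DAY_CASE,OUTPATIENT,Z511,,C211,,WF01A,104,,2009
    p6,M,62,PRV4,2009-09-01,2009-09-02,ELECTIVE,INPATIENT,C2,,,,AA01,,,2009
    """
)


@pytest.fixture(scope="session")
def fixture_records_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("hes") / "records.csv"
    path.write_text(FIXTURE_RECORDS_CSV)
    return path
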