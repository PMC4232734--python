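"""Episode filtering, spell grouping, tariff costing and summaries."""

import numpy as np
import pandas as pd
import pytest

from anocost.hes import (
    TariffTable,
    annual_summary,
    cost_attendances,
    cost_spell,
    cost_spells,
    filter_records,
    group_spells,
    read_records,
)
from anocost.markov import ValidationError


def make_record(**overrides) -> dict:
    base = dict(
        patient_id="p1", sex="F", age=60, provider="PRV1",
        admission_date="2009-01-01", discharge_date="2009-01-05",
        admission_method="ELECTIVE", setting="INPATIENT",
        diag1="C211", diag2="", diag3="", procedures="", hrg="AA01",
        tfc="", unbundled="", year="2009",
    )
    base.update(overrides)
    return base


class TestFilterRecords:
    def test_tertiary_diagnosis_keeps_inpatient(self):
        records = pd.DataFrame([make_record(diag1="K602", diag2="", diag3="C211")])
        invasive, in_situ = filter_records(records)
        assert len(invasive) == 1 and len(in_situ) == 0

    def test_tertiary_diagnosis_drops_outpatient(self):
        records = pd.DataFrame(
            [make_record(setting="OUTPATIENT", diag1="Z511", diag2="", diag3="C211")]
        )
        invasive, in_situ = filter_records(records)
        assert len(invasive) == 0 and len(in_situ) == 0

    def test_in_situ_code_partitions_separately(self):
        records = pd.DataFrame(
            [make_record(diag1="D013"), make_record(diag1="C210")]
        )
        invasive, in_situ = filter_records(records)
        assert list(invasive["diag1"]) == ["C210"]
        assert list(in_situ["diag1"]) == ["D013"]

    def test_invasive_takes_precedence_over_in_situ(self):
        records = pd.DataFrame([make_record(diag1="D013", diag2="C211")])
        invasive, in_situ = filter_records(records)
        assert len(invasive) == 1 and len(in_situ) == 0

    def test_malformed_code_excluded(self, caplog):
        records = pd.DataFrame([make_record(diag1="C2")])  # too short
        with caplog.at_level("WARNING"):
            invasive, in_situ = filter_records(records)
        assert invasive.empty and in_situ.empty
        assert "malformed" in caplog.text

    def test_unrelated_diagnoses_dropped(self):
        records = pd.DataFrame([make_record(diag1="K602")])
        invasive, in_situ = filter_records(records)
        assert invasive.empty and in_situ.empty

    def test_empty_input_gives_empty_partitions(self):
        records = pd.DataFrame(columns=list(make_record()))
        invasive, in_situ = filter_records(records)
        assert invasive.empty and in_situ.empty


class TestGroupSpells:
    def test_contiguous_fces_merge_into_one_spell(self):
        fces = pd.DataFrame([
            make_record(admission_date="2009-01-01", discharge_date="2009-01-03"),
            make_record(admission_date="2009-01-03", discharge_date="2009-01-08",
                        hrg="BB02"),
        ]).assign(cohort="invasive")
        spells = group_spells(fces)
        assert len(spells) == 1
        assert spells.loc[0, "core_hrg"] == "AA01"  # first FCE's HRG
        assert spells.loc[0, "length_of_stay"] == 7
        assert spells.loc[0, "n_fces"] == 2

    def test_different_providers_stay_separate(self):
        fces = pd.DataFrame([
            make_record(provider="PRV1"),
            make_record(provider="PRV2"),
        ]).assign(cohort="invasive")
        assert len(group_spells(fces)) == 2

    def test_single_fce_spell_length_of_stay(self):
        fces = pd.DataFrame([
            make_record(admission_date="2009-02-01", discharge_date="2009-02-04")
        ]).assign(cohort="invasive")
        spells = group_spells(fces)
        assert len(spells) == 1
        assert spells.loc[0, "length_of_stay"] == 3

    def test_disjoint_windows_make_two_spells(self):
        fces = pd.DataFrame([
            make_record(admission_date="2009-01-01", discharge_date="2009-01-03"),
            make_record(admission_date="2009-02-01", discharge_date="2009-02-02"),
        ]).assign(cohort="invasive")
        assert len(group_spells(fces)) == 2

    def test_contradictory_dates_swapped_with_warning(self, caplog):
        fces = pd.DataFrame([
            make_record(admission_date="2009-01-05", discharge_date="2009-01-01")
        ]).assign(cohort="invasive")
        with caplog.at_level("WARNING"):
            spells = group_spells(fces)
        assert spells.loc[0, "length_of_stay"] == 4
        assert "discharge before admission" in caplog.text

    def test_unbundled_codes_pooled_across_member_fces(self):
        fces = pd.DataFrame([
            make_record(admission_date="2009-01-01", discharge_date="2009-01-03",
                        unbundled="SB12Z"),
            make_record(admission_date="2009-01-03", discharge_date="2009-01-05",
                        unbundled="SC22Z"),
        ]).assign(cohort="invasive")
        spells = group_spells(fces)
        assert spells.loc[0, "unbundled"] == "SB12Z;SC22Z"

    def test_outpatient_rows_rejected(self):
        fces = pd.DataFrame([make_record(setting="OUTPATIENT")])
        with pytest.raises(ValidationError):
            group_spells(fces)


class TestCostSpell:
    def test_elective_no_excess_is_tariff_price(self, toy_tariff):
        spell = {"core_hrg": "AA01", "admission_method": "ELECTIVE",
                 "length_of_stay": 2, "unbundled": ""}
        breakdown = cost_spell(spell, toy_tariff)
        assert breakdown["cost_bundled"] == 1000.0
        assert breakdown["cost_total"] == 1000.0

    def test_excess_bed_days_charged_per_diem(self, toy_tariff):
        # 3 excess days at £200/day on a £1,000 HRG -> 1,600
        spell = {"core_hrg": "AA01", "admission_method": "ELECTIVE",
                 "length_of_stay": 6, "unbundled": ""}
        breakdown = cost_spell(spell, toy_tariff)
        assert breakdown["excess_bed_days"] == 3
        assert breakdown["cost_bundled"] == 1600.0

    def test_chemo_unbundled_priced_from_reference_cost(self, toy_tariff):
        spell = {"core_hrg": "AA01", "admission_method": "DAY_CASE",
                 "length_of_stay": 0, "unbundled": "SB12Z"}
        breakdown = cost_spell(spell, toy_tariff)
        assert breakdown["cost_chemo"] == 350.0
        assert breakdown["cost_bundled"] == 500.0

    def test_breakdown_components_sum_to_total(self, toy_tariff):
        spell = {"core_hrg": "BB02", "admission_method": "NON_ELECTIVE",
                 "length_of_stay": 14, "unbundled": "SB12Z;SC22Z;XX90Z"}
        b = cost_spell(spell, toy_tariff)
        parts = b["cost_bundled"] + b["cost_chemo"] + b["cost_radio"] + b["cost_unbundled_other"]
        assert b["cost_total"] == pytest.approx(parts)

    def test_missing_hrg_errors_with_code(self, toy_tariff):
        spell = {"core_hrg": "ZZ99", "admission_method": "ELECTIVE",
                 "length_of_stay": 1, "unbundled": ""}
        with pytest.raises(ValidationError, match="ZZ99"):
            cost_spell(spell, toy_tariff)


class TestAnnualSummary:
    @staticmethod
    def one_spell_frame(cost=500.0, year="2009", pid="p1"):
        return pd.DataFrame([{
            "patient_id": pid, "sex": "F", "cohort": "invasive", "year": year,
            "cost_bundled": cost, "cost_unbundled_other": 0.0,
            "cost_chemo": 0.0, "cost_radio": 0.0, "cost_total": cost,
        }])

    def test_cost_per_patient_single_patient(self):
        per_year, _ = annual_summary(self.one_spell_frame(), None)
        assert per_year.loc[0, "cost_per_patient"] == 500.0

    def test_partial_year_scaling(self):
        per_year, _ = annual_summary(
            self.one_spell_frame(cost=300.0), None,
            partial_year_factor=1.33, partial_years=("2009",),
        )
        assert per_year.loc[0, "cost_total"] == pytest.approx(399.0)
        # patient numbers scale too, so cost per patient is unchanged
        assert per_year.loc[0, "cost_per_patient"] == pytest.approx(300.0)

    def test_zero_patients_reported_absent_not_zero(self):
        per_year, means = annual_summary(pd.DataFrame(), pd.DataFrame())
        assert per_year.empty
        assert "cost_per_patient" in per_year.columns

    def test_strata_totals_sum_to_grand_total(self):
        spells = pd.concat([
            self.one_spell_frame(500.0, "2009", "p1"),
            self.one_spell_frame(700.0, "2010", "p2"),
        ])
        per_year, _ = annual_summary(spells, None)
        assert per_year["cost_total"].sum() == pytest.approx(1200.0)

    def test_means_divide_mean_cost_by_mean_patients(self):
        spells = pd.concat([
            self.one_spell_frame(500.0, "2009", "p1"),
            self.one_spell_frame(700.0, "2010", "p1"),
        ])
        _, means = annual_summary(spells, None)
        assert means.loc[0, "cost_total"] == pytest.approx(600.0)
        assert means.loc[0, "cost_per_patient"] == pytest.approx(600.0)


class TestHandCostedFixture:
    """Ten-record extract costed by hand; totals must match to the penny.

    Spells after filtering and grouping:
      p1 F 2009: [AA01 elective, 2 FCEs, LOS 5, trim 3 -> 1000+2*200=1400,
                  chemo 350] = 1750; [AA01 non-elective, LOS 1 -> 1800,
                  radio 110] = 1910
      p2 M 2009: [AA01 day case -> 500, other 75] = 575; [BB02 elective,
                  LOS 2 -> 2000] (separate provider)
      p3 F 2010 (in situ): [BB02 elective, LOS 19, trim 10 -> 2000+9*250
                  = 4250]
    Attendances: p4 M 2009: 150 (TFC 104) and 140 (WF01A) + radio 110.
    p5's tertiary-only outpatient record and p6's malformed code drop out.
    """

    @pytest.fixture()
    def summaries(self, fixture_records_path, toy_tariff):
        records = read_records(fixture_records_path)
        invasive, in_situ = filter_records(records)
        cohorts = pd.concat([invasive, in_situ], ignore_index=True)
        spells = cost_spells(
            group_spells(cohorts[cohorts["setting"] == "INPATIENT"]), toy_tariff
        )
        attendances = cost_attendances(
            cohorts[cohorts["setting"] == "OUTPATIENT"], toy_tariff
        )
        return spells, attendances

    def test_spell_set_matches_hand_grouping(self, summaries):
        spells, _ = summaries
        assert len(spells) == 5
        assert sorted(spells["cost_total"]) == [575.0, 1750.0, 1910.0, 2000.0, 4250.0]

    def test_annual_summary_to_the_penny(self, summaries):
        spells, attendances = summaries
        per_year, _ = annual_summary(spells, attendances)
        table = per_year.set_index(["year", "sex", "cohort", "setting"])
        assert table.loc[("2009", "F", "invasive", "INPATIENT"), "cost_total"] == 3660.0
        assert table.loc[("2009", "M", "invasive", "INPATIENT"), "cost_total"] == 2575.0
        assert table.loc[("2009", "M", "invasive", "OUTPATIENT"), "cost_total"] == 400.0
        assert table.loc[("2010", "F", "in_situ", "INPATIENT"), "cost_total"] == 4250.0
        assert table.loc[("2009", "M", "invasive", "OUTPATIENT"), "cost_radio"] == 110.0

    def test_partial_year_scaling_applies_to_flagged_year_only(self, summaries):
        spells, attendances = summaries
        per_year, _ = annual_summary(
            spells, attendances, partial_year_factor=1.33, partial_years=("2010",)
        )
        table = per_year.set_index(["year", "sex", "cohort", "setting"])
        assert table.loc[("2010", "F", "in_situ", "INPATIENT"), "cost_total"] == pytest.approx(4250.0 * 1.33)
        assert table.loc[("2009", "F", "invasive", "INPATIENT"), "cost_total"] == 3660.0


def test_tariff_csv_round_trip(tmp_path, toy_tariff):
    path = tmp_path / "tariff.csv"
    toy_tariff.to_csv(path)
    loaded = TariffTable.from_csv(path)
    assert loaded.inpatient == toy_tariff.inpatient
    assert loaded.outpatient == toy_tariff.outpatient
    assert loaded.unbundled == toy_tariff.unbundled
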