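"""Synthetic inputs: calibration target curves and HES-style cohorts.

Real calibration curves come from long-term trial follow-up and real
episode data from a national extract, neither of which is
redistributable.  This module generates stand-ins whose ground truth is
known by construction:

* :func:`generate_calibration_curves` samples the model's own outcome
  curves at chosen months, optionally perturbed by truncated Gaussian
  noise, for parameter-recovery experiments;
* :func:`generate_fce_records` draws a patient-level hospital cohort
  (spells, lengths of stay, admission mix, diagnoses, unbundled
  chemo/radiotherapy, outpatient attendances) whose expected activity
  and tariff costs have closed form, returned alongside the records for
  oracle testing.

Defaults follow the published descriptive statistics of anal cancer
hospital activity (three spells per inpatient per year, four-day mean
stay, 85% elective admissions of which 33% day case, about 10%/3%
elective/non-elective excess-bed-day spells), with no claim of
reproducing national totals.  Spell counts are Poisson and stay lengths
geometric — the simplest distributions consistent with the reported
means; ``count_model="fixed"`` / ``los_model="fixed"`` switch both to
their deterministic counterparts so degenerate cohorts match their
ground truth exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationTarget
from .hes import TariffTable, classify_unbundled
from .markov import (
    MonthlyProbabilities,
    ValidationError,
    build_transition_matrix,
    cumulative_outcomes,
    run_cohort,
)


def generate_calibration_curves(
    true_probs: MonthlyProbabilities,
    months: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CalibrationTarget:
    """Sample the model's mortality and relapse curves as a target.

    With ``noise_sd > 0``, independent Gaussian noise is added to each
    point, after which both series are clipped to [0, 1] and
    re-monotonised with a running maximum.  ``noise_sd = 0`` returns the
    exact model curves, so calibrating against them has a zero-objective
    optimum at ``true_probs``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    months = np.asarray(months, dtype=int)
    trace = run_cohort(build_transition_matrix(true_probs), n_cycles=int(months.max()))
    cum_mort, cum_rel = cumulative_outcomes(trace)
    mort, rel = cum_mort[months], cum_rel[months]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mort = mort + rng.normal(0.0, noise_sd, size=mort.shape)
        rel = rel + rng.normal(0.0, noise_sd, size=rel.shape)
        mort = np.maximum.accumulate(np.clip(mort, 0.0, 1.0))
        rel = np.maximum.accumulate(np.clip(rel, 0.0, 1.0))
    return CalibrationTarget(months=months, cum_mortality=mort, cum_relapse=rel)


def default_tariff() -> TariffTable:
    """A small illustrative tariff (synthetic prices, not the national
    tariff): anal disorder and anal/large-intestine procedure HRGs,
    follow-up attendance codes and unbundled chemo/radiotherapy codes."""
    return TariffTable(
        inpatient={
            "FZ20A": {"elective": 1200.0, "non_elective": 2100.0, "day_case": 600.0,
                      "trim_point": 8.0, "excess_per_diem": 225.0},
            "FZ20B": {"elective": 800.0, "non_elective": 1500.0, "day_case": 450.0,
                      "trim_point": 5.0, "excess_per_diem": 200.0},
            "FZ54A": {"elective": 2600.0, "non_elective": 3900.0, "day_case": 900.0,
                      "trim_point": 12.0, "excess_per_diem": 250.0},
        },
        outpatient={"104": 150.0, "370": 120.0, "WF01A": 140.0},
        unbundled={"SB12Z": 350.0, "SB15Z": 280.0, "SC22Z": 110.0, "SC97Z": 95.0},
    )


@dataclass(frozen=True)
class CohortGenConfig:
    """Settings of the synthetic HES cohort generator."""

    n_patients: int = 1000
    sex_ratio: float = 0.59  # fraction female
    mean_spells_per_patient: float = 3.0
    mean_attendances_per_patient: float = 2.3
    mean_los_days: float = 4.0
    admission_mix: dict[str, float] = field(
        default_factory=lambda: {"ELECTIVE": 0.52, "DAY_CASE": 0.33, "NON_ELECTIVE": 0.15}
    )
    p_excess_bed_days: dict[str, float] = field(
        default_factory=lambda: {"ELECTIVE": 0.10, "DAY_CASE": 0.0, "NON_ELECTIVE": 0.03}
    )
    mean_excess_days: float = 3.0
    diagnosis_mix: dict[str, float] = field(
        default_factory=lambda: {
            "C210": 0.25, "C211": 0.45, "C212": 0.05, "C218": 0.15, "D013": 0.10,
        }
    )
    hrg_mix: dict[str, float] = field(
        default_factory=lambda: {"FZ20A": 0.5, "FZ20B": 0.3, "FZ54A": 0.2}
    )
    tfc_mix: dict[str, float] = field(default_factory=lambda: {"104": 0.3, "370": 0.7})
    p_chemo_unbundled: float = 0.115
    p_radio_unbundled: float = 0.08
    chemo_code: str = "SB12Z"
    radio_code: str = "SC22Z"
    p_multi_fce: float = 0.2
    years: tuple[str, ...] = ("2008", "2009", "2010")
    partial_year: str | None = None  # year with only nine months of activity
    count_model: str = "poisson"  # or "fixed"
    los_model: str = "geometric"  # or "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        for name in ("sex_ratio", "p_chemo_unbundled", "p_radio_unbundled", "p_multi_fce"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("admission_mix", "diagnosis_mix", "hrg_mix", "tfc_mix"):
            mix = getattr(self, name)
            if any(not 0.0 <= v <= 1.0 for v in mix.values()):
                raise ValidationError(f"{name} fractions must lie in [0, 1]")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")
        if any(not 0.0 <= v <= 1.0 for v in self.p_excess_bed_days.values()):
            raise ValidationError("p_excess_bed_days fractions must lie in [0, 1]")
        if self.count_model not in ("poisson", "fixed"):
            raise ValidationError("count_model must be 'poisson' or 'fixed'")
        if self.los_model not in ("geometric", "fixed"):
            raise ValidationError("los_model must be 'geometric' or 'fixed'")
        if self.partial_year is not None and self.partial_year not in self.years:
            raise ValidationError("partial_year must be one of years")


_PARTIAL_FRACTION = 0.75  # nine of twelve months of activity
PARTIAL_YEAR_FACTOR = 1.33  # annualisation factor applied downstream


def _draw_counts(rng, mean: float, n: int, model: str) -> np.ndarray:
    if model == "fixed":
        return np.full(n, int(round(mean)))
    return rng.poisson(mean, size=n)


def _draw_los(rng, mean: float, n: int, model: str) -> np.ndarray:
    if model == "fixed":
        return np.full(n, int(round(mean)))
    return rng.geometric(1.0 / max(mean, 1.0), size=n)


def _expected_bundled_per_spell(config: CohortGenConfig, tariff: TariffTable) -> float:
    price_key = {"ELECTIVE": "elective", "NON_ELECTIVE": "non_elective", "DAY_CASE": "day_case"}
    total = 0.0
    mean_excess = (
        config.mean_excess_days if config.los_model == "geometric"
        else round(config.mean_excess_days)
    )
    for hrg, p_hrg in config.hrg_mix.items():
        row = tariff.inpatient[hrg]
        for method, p_adm in config.admission_mix.items():
            expected_excess = config.p_excess_bed_days[method] * mean_excess
            total += p_hrg * p_adm * (
                row[price_key[method]] + expected_excess * row["excess_per_diem"]
            )
    return total


def ground_truth_expectations(config: CohortGenConfig, tariff: TariffTable) -> dict:
    """Closed-form expected activity and cost totals implied by the
    config and tariff, on the annualised (post partial-year scaling)
    basis produced by the costing pipeline's summary."""
    n = config.n_patients
    # expected events per patient summed over the study years, on the
    # annualised basis (partial year thinned to 9/12 then scaled by 1.33)
    def _per_year_count(mean: float, frac: float) -> float:
        thinned = mean * frac
        return float(round(thinned)) if config.count_model == "fixed" else thinned

    exp_spells = 0.0
    exp_attendances = 0.0
    for y in config.years:
        frac = _PARTIAL_FRACTION if y == config.partial_year else 1.0
        scale = PARTIAL_YEAR_FACTOR if y == config.partial_year else 1.0
        exp_spells += n * scale * _per_year_count(config.mean_spells_per_patient, frac)
        exp_attendances += n * scale * _per_year_count(
            config.mean_attendances_per_patient, frac
        )
    bundled_per_spell = _expected_bundled_per_spell(config, tariff)
    chemo_per_spell = config.p_chemo_unbundled * tariff.unbundled[config.chemo_code]
    radio_per_spell = config.p_radio_unbundled * tariff.unbundled[config.radio_code]
    att_price = sum(p * tariff.outpatient[tfc] for tfc, p in config.tfc_mix.items())

    def _p_any(mean: float) -> float:
        if config.count_model == "fixed":
            return 1.0 if round(mean) >= 1 else 0.0
        return 1.0 - float(np.exp(-mean))

    # expected patient-years with >=1 event, on the annualised basis
    inpat_py = 0.0
    outpat_py = 0.0
    for y in config.years:
        frac = _PARTIAL_FRACTION if y == config.partial_year else 1.0
        scale = PARTIAL_YEAR_FACTOR if y == config.partial_year else 1.0
        inpat_py += scale * _p_any(config.mean_spells_per_patient * frac)
        outpat_py += scale * _p_any(config.mean_attendances_per_patient * frac)

    p_in_situ = config.diagnosis_mix.get("D013", 0.0)
    out = {}
    for cohort, p_cohort in (("invasive", 1 - p_in_situ), ("in_situ", p_in_situ)):
        out[cohort] = {
            "expected_spells": p_cohort * exp_spells,
            "expected_attendances": p_cohort * exp_attendances,
            "expected_inpatient_patient_years": p_cohort * n * inpat_py,
            "expected_outpatient_patient_years": p_cohort * n * outpat_py,
            "inpatient": {
                "cost_bundled": p_cohort * exp_spells * bundled_per_spell,
                "cost_chemo": p_cohort * exp_spells * chemo_per_spell,
                "cost_radio": p_cohort * exp_spells * radio_per_spell,
                "cost_unbundled_other": 0.0,
                "cost_total": p_cohort * exp_spells
                * (bundled_per_spell + chemo_per_spell + radio_per_spell),
            },
            "outpatient": {
                "cost_bundled": p_cohort * exp_attendances * att_price,
                "cost_chemo": 0.0,
                "cost_radio": 0.0,
                "cost_unbundled_other": 0.0,
                "cost_total": p_cohort * exp_attendances * att_price,
            },
        }
    return out


def generate_fce_records(
    config: CohortGenConfig, tariff: TariffTable | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic FCE/attendance extract and its ground truth.

    Each patient carries one anal cancer diagnosis code, a sex, an age
    and a provider, and contributes independent spells (and outpatient
    attendances) in each study year.  Spells occupy disjoint ~monthly
    windows so the spell grouper cannot accidentally merge them; a
    fraction of spells is split into two contiguous FCEs to exercise
    FCE-to-spell aggregation.  Excess bed days, when drawn, place the
    stay at the HRG trim point plus the drawn excess, so recomputed
    excess-bed-day counts equal the drawn values.

    Returns the record table (schema of :data:`anocost.hes.RECORD_COLUMNS`)
    and the :func:`ground_truth_expectations` dictionary.
    """
    if tariff is None:
        tariff = default_tariff()
    unknown_hrgs = set(config.hrg_mix) - set(tariff.inpatient)
    if unknown_hrgs:
        raise ValidationError(f"hrg_mix codes missing from tariff: {sorted(unknown_hrgs)}")
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []

    diag_codes = list(config.diagnosis_mix)
    diag_p = np.array([config.diagnosis_mix[c] for c in diag_codes])
    hrg_codes = list(config.hrg_mix)
    hrg_p = np.array([config.hrg_mix[c] for c in hrg_codes])
    tfc_codes = list(config.tfc_mix)
    tfc_p = np.array([config.tfc_mix[c] for c in tfc_codes])
    adm_methods = list(config.admission_mix)
    adm_p = np.array([config.admission_mix[m] for m in adm_methods])
    providers = [f"PRV{i}" for i in range(1, 6)]

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        sex = "F" if rng.random() < config.sex_ratio else "M"
        age = int(np.clip(round(rng.normal(64, 10)), 18, 95))
        provider = providers[rng.integers(len(providers))]
        diag = diag_codes[rng.choice(len(diag_codes), p=diag_p)]
        for year in config.years:
            partial = year == config.partial_year
            months_open = 9 if partial else 12
            spell_mean = config.mean_spells_per_patient * (
                _PARTIAL_FRACTION if partial else 1.0
            )
            att_mean = config.mean_attendances_per_patient * (
                _PARTIAL_FRACTION if partial else 1.0
            )
            n_spells = min(int(_draw_counts(rng, spell_mean, 1, config.count_model)[0]), months_open)
            n_att = int(_draw_counts(rng, att_mean, 1, config.count_model)[0])
            for s in range(n_spells):
                method = adm_methods[rng.choice(len(adm_methods), p=adm_p)]
                hrg = hrg_codes[rng.choice(len(hrg_codes), p=hrg_p)]
                trim = tariff.inpatient[hrg]["trim_point"]
                if method == "DAY_CASE":
                    los = 0
                else:
                    base = int(_draw_los(rng, config.mean_los_days, 1, config.los_model)[0])
                    los = min(base, int(trim))
                    if rng.random() < config.p_excess_bed_days[method]:
                        excess = int(
                            _draw_los(rng, config.mean_excess_days, 1, config.los_model)[0]
                        )
                        los = int(trim) + excess
                admission = dt.date(int(year), 1, 1) + dt.timedelta(
                    days=int(30 * s + rng.integers(0, 3))
                )
                discharge = admission + dt.timedelta(days=los)
                unbundled = []
                if rng.random() < config.p_chemo_unbundled:
                    unbundled.append(config.chemo_code)
                if rng.random() < config.p_radio_unbundled:
                    unbundled.append(config.radio_code)
                base_row = {
                    "patient_id": pid, "sex": sex, "age": age, "provider": provider,
                    "admission_method": method, "setting": "INPATIENT",
                    "diag1": diag, "diag2": "", "diag3": "",
                    "procedures": "", "hrg": hrg, "tfc": "", "year": year,
                }
                if los >= 2 and rng.random() < config.p_multi_fce:
                    split = admission + dt.timedelta(days=int(rng.integers(1, los)))
                    rows.append({**base_row, "admission_date": admission.isoformat(),
                                 "discharge_date": split.isoformat(),
                                 "unbundled": ";".join(unbundled)})
                    rows.append({**base_row, "admission_date": split.isoformat(),
                                 "discharge_date": discharge.isoformat(), "unbundled": ""})
                else:
                    rows.append({**base_row, "admission_date": admission.isoformat(),
                                 "discharge_date": discharge.isoformat(),
                                 "unbundled": ";".join(unbundled)})
            for a in range(n_att):
                tfc = tfc_codes[rng.choice(len(tfc_codes), p=tfc_p)]
                day = dt.date(int(year), 1, 1) + dt.timedelta(
                    days=int(rng.integers(0, months_open * 30))
                )
                rows.append({
                    "patient_id": pid, "sex": sex, "age": age, "provider": provider,
                    "admission_date": day.isoformat(), "discharge_date": day.isoformat(),
                    "admission_method": "DAY_CASE", "setting": "OUTPATIENT",
                    "diag1": diag, "diag2": "", "diag3": "",
                    "procedures": "", "hrg": "WF01A", "tfc": tfc,
                    "unbundled": "", "year": year,
                })

    from .hes import RECORD_COLUMNS

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, ground_truth_expectations(config, tariff)
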