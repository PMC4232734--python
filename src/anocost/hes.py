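"""Hospital-episode costing pipeline on HES-style records.

Emulates the retrospective costing of anal cancer hospital activity in
England: finished consultant episodes (FCEs) are filtered on anal
cancer ICD-10 diagnoses, inpatient FCEs are aggregated into spells of
care (admission to discharge), each spell is priced from a national
tariff table by admission type with excess-bed-day adjustments and
separately priced unbundled chemotherapy/radiotherapy components, and
annual per-patient summaries are produced with partial-year scaling.

The proprietary HRG4 grouper is replaced by a transparent rule: FCEs of
the same patient and provider with overlapping or contiguous admission
windows form one spell, whose core HRG is the first FCE's HRG.  Spell
date windows are half-open ISO-8601 intervals ``[admission,
discharge)``.  Unbundled HRGs are tagged chemotherapy / radiotherapy /
other by code prefix (``SB`` / ``SC``).
"""

from __future__ import annotations

import functools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import ValidationError

logger = logging.getLogger(__name__)

#: ICD-10 codes for invasive anal cancer (anus unspecified, anal canal,
#: cloacogenic zone, overlapping lesion of rectum/anus/anal canal).
INVASIVE_CODES = frozenset({"C210", "C211", "C212", "C218"})
#: Carcinoma in situ of anus and anal canal.
IN_SITU_CODE = "D013"

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9X]?$")

RECORD_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "provider",
    "admission_date",
    "discharge_date",
    "admission_method",
    "setting",
    "diag1",
    "diag2",
    "diag3",
    "procedures",
    "hrg",
    "tfc",
    "unbundled",
    "year",
]

ADMISSION_METHODS = ("ELECTIVE", "NON_ELECTIVE", "DAY_CASE")

COST_COLUMNS = ["cost_bundled", "cost_unbundled_other", "cost_chemo", "cost_radio"]

CHEMO_PREFIX = "SB"
RADIO_PREFIX = "SC"


def classify_unbundled(code: str) -> str:
    """Tag an unbundled HRG code as CHEMO, RADIO or OTHER by prefix."""
    if code.startswith(CHEMO_PREFIX):
        return "CHEMO"
    if code.startswith(RADIO_PREFIX):
        return "RADIO"
    return "OTHER"


@dataclass(frozen=True)
class TariffTable:
    """Prices for core spells, outpatient attendances and unbundled HRGs.

    ``inpatient`` maps HRG code to (elective, non-elective, day-case
    price, trim point in days, excess-bed-day per diem); ``outpatient``
    maps TFC or outpatient HRG code to an attendance price;
    ``unbundled`` maps unbundled HRG code to its national average
    reference cost.
    """

    inpatient: dict[str, dict[str, float]] = field(default_factory=dict)
    outpatient: dict[str, float] = field(default_factory=dict)
    unbundled: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for hrg, row in self.inpatient.items():
            for key in ("elective", "non_elective", "day_case", "trim_point", "excess_per_diem"):
                if row.get(key, 0.0) < 0:
                    raise ValidationError(f"tariff {hrg}: {key} must be >= 0")
        if any(v < 0 for v in self.outpatient.values()):
            raise ValidationError("outpatient tariff prices must be >= 0")
        if any(v < 0 for v in self.unbundled.values()):
            raise ValidationError("unbundled reference costs must be >= 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TariffTable":
        """Load a combined tariff CSV.

        Columns: ``kind`` (inpatient | outpatient | unbundled), ``code``,
        and for inpatient rows ``elective, non_elective, day_case,
        trim_point, excess_per_diem``; outpatient and unbundled rows use
        the ``price`` column.
        """
        df = pd.read_csv(path)
        inpatient: dict[str, dict[str, float]] = {}
        outpatient: dict[str, float] = {}
        unbundled: dict[str, float] = {}
        for row in df.itertuples():
            code = str(row.code)
            if row.kind == "inpatient":
                inpatient[code] = {
                    "elective": float(row.elective),
                    "non_elective": float(row.non_elective),
                    "day_case": float(row.day_case),
                    "trim_point": float(row.trim_point),
                    "excess_per_diem": float(row.excess_per_diem),
                }
            elif row.kind == "outpatient":
                outpatient[code] = float(row.price)
            elif row.kind == "unbundled":
                unbundled[code] = float(row.price)
            else:
                raise ValidationError(f"unknown tariff row kind {row.kind!r}")
        return cls(inpatient=inpatient, outpatient=outpatient, unbundled=unbundled)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for code, row in self.inpatient.items():
            rows.append({"kind": "inpatient", "code": code, "price": np.nan, **row})
        for code, price in self.outpatient.items():
            rows.append({"kind": "outpatient", "code": code, "price": price})
        for code, price in self.unbundled.items():
            rows.append({"kind": "unbundled", "code": code, "price": price})
        columns = [
            "kind", "code", "elective", "non_elective", "day_case",
            "trim_point", "excess_per_diem", "price",
        ]
        pd.DataFrame(rows).reindex(columns=columns).to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read an FCE/attendance extract CSV into the documented schema."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"records CSV missing columns: {sorted(missing)}")
    df = df[RECORD_COLUMNS].copy()
    for col in ("admission_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
    df["age"] = pd.to_numeric(df["age"])
    return df


def _diag_matches(record: pd.Series, setting_cols: list[str], codes) -> bool:
    return any(record[c] in codes for c in setting_cols)


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into invasive and in-situ anal cancer subsets.

    Inpatient records qualify on any of the primary, secondary or
    tertiary diagnosis fields; outpatient records on primary or
    secondary only, reflecting the more disease-specific coding of
    post-treatment care.  Records carrying a malformed diagnosis code
    are excluded with a logged warning; invasive codes take precedence,
    so a record with both an invasive and the in-situ code is invasive.
    """
    if records.empty:
        empty = records.iloc[0:0].copy()
        return empty.assign(cohort=pd.Series(dtype=str)), empty.assign(
            cohort=pd.Series(dtype=str)
        )
    is_inpatient = (records["setting"] == "INPATIENT").to_numpy()
    invasive_mask = np.zeros(len(records), dtype=bool)
    in_situ_mask = np.zeros(len(records), dtype=bool)
    malformed = np.zeros(len(records), dtype=bool)
    for col in ("diag1", "diag2", "diag3"):
        diags = records[col].fillna("").astype(str)
        nonempty = (diags != "").to_numpy()
        considered = nonempty if col != "diag3" else nonempty & is_inpatient
        valid = diags.str.match(_ICD10_RE).to_numpy()
        malformed |= considered & ~valid
        invasive_mask |= considered & diags.isin(INVASIVE_CODES).to_numpy()
        in_situ_mask |= considered & (diags == IN_SITU_CODE).to_numpy()
    if malformed.any():
        for pid in records.loc[malformed, "patient_id"]:
            logger.warning("excluding record %s: malformed ICD-10 code", pid)
    invasive_mask &= ~malformed
    in_situ_mask &= ~malformed & ~invasive_mask
    invasive = records.loc[invasive_mask].copy()
    invasive["cohort"] = "invasive"
    in_situ = records.loc[in_situ_mask].copy()
    in_situ["cohort"] = "in_situ"
    return invasive, in_situ


def group_spells(fces: pd.DataFrame) -> pd.DataFrame:
    """Aggregate inpatient FCEs into spells of care.

    FCEs of the same patient and provider whose half-open admission
    windows overlap or touch are merged into one spell, scanned in
    admission-date order (ties broken by discharge date, earliest
    admission defines the spell).  The spell inherits the first FCE's
    HRG, admission method, sex, cohort and year; unbundled codes are
    pooled across member FCEs.
    """
    if fces.empty:
        return pd.DataFrame(
            columns=[
                "patient_id", "provider", "sex", "cohort", "year",
                "admission_method", "core_hrg", "admission_date",
                "discharge_date", "length_of_stay", "n_fces", "unbundled",
            ]
        )
    if (fces["setting"] != "INPATIENT").any():
        raise ValidationError("group_spells expects inpatient FCEs only")
    if not pd.api.types.is_datetime64_any_dtype(fces["admission_date"]):
        fces = fces.copy()
        for col in ("admission_date", "discharge_date"):
            fces[col] = pd.to_datetime(fces[col], format="%Y-%m-%d")
    bad = fces["admission_date"] > fces["discharge_date"]
    if bad.any():
        logger.warning(
            "%d FCE(s) with discharge before admission; dates swapped", int(bad.sum())
        )
        fces = fces.copy()
        adm = fces.loc[bad, "admission_date"].copy()
        fces.loc[bad, "admission_date"] = fces.loc[bad, "discharge_date"]
        fces.loc[bad, "discharge_date"] = adm

    ordered = fces.sort_values(
        ["patient_id", "provider", "admission_date", "discharge_date"],
        kind="mergesort",
    )
    spells = []
    current = None
    for rec in ordered.itertuples():
        if (
            current is not None
            and rec.patient_id == current["patient_id"]
            and rec.provider == current["provider"]
            and rec.admission_date <= current["discharge_date"]
        ):
            current["discharge_date"] = max(current["discharge_date"], rec.discharge_date)
            current["n_fces"] += 1
            if rec.unbundled:
                current["unbundled"].append(rec.unbundled)
        else:
            if current is not None:
                spells.append(current)
            current = {
                "patient_id": rec.patient_id,
                "provider": rec.provider,
                "sex": rec.sex,
                "cohort": getattr(rec, "cohort", ""),
                "year": rec.year,
                "admission_method": rec.admission_method,
                "core_hrg": rec.hrg,
                "admission_date": rec.admission_date,
                "discharge_date": rec.discharge_date,
                "n_fces": 1,
                "unbundled": [rec.unbundled] if rec.unbundled else [],
            }
    spells.append(current)
    out = pd.DataFrame(spells)
    out["length_of_stay"] = (out["discharge_date"] - out["admission_date"]).dt.days
    out["unbundled"] = out["unbundled"].map(";".join)
    return out


def cost_spell(spell, tariff: TariffTable) -> dict[str, float]:
    """Price one spell: core tariff by admission type plus excess bed
    days beyond the HRG trim point, plus unbundled components from
    reference costs, tagged chemo / radio / other."""
    hrg = spell["core_hrg"]
    if hrg not in tariff.inpatient:
        raise ValidationError(f"HRG {hrg!r} missing from tariff")
    row = tariff.inpatient[hrg]
    method = spell["admission_method"]
    if method not in ADMISSION_METHODS:
        raise ValidationError(f"unknown admission method {method!r}")
    price_key = {"ELECTIVE": "elective", "NON_ELECTIVE": "non_elective", "DAY_CASE": "day_case"}
    excess = max(0.0, float(spell["length_of_stay"]) - row["trim_point"])
    breakdown = {
        "cost_bundled": row[price_key[method]] + excess * row["excess_per_diem"],
        "cost_unbundled_other": 0.0,
        "cost_chemo": 0.0,
        "cost_radio": 0.0,
        "excess_bed_days": excess,
    }
    codes = [c for c in str(spell["unbundled"]).split(";") if c]
    for code in codes:
        if code not in tariff.unbundled:
            raise ValidationError(f"unbundled HRG {code!r} missing from reference costs")
        tag = classify_unbundled(code)
        key = {"CHEMO": "cost_chemo", "RADIO": "cost_radio", "OTHER": "cost_unbundled_other"}[tag]
        breakdown[key] += tariff.unbundled[code]
    breakdown["cost_total"] = sum(breakdown[k] for k in COST_COLUMNS)
    return breakdown


def cost_spells(spells: pd.DataFrame, tariff: TariffTable) -> pd.DataFrame:
    """Vectorised :func:`cost_spell` over a spell table."""
    if spells.empty:
        out = spells.copy()
        for col in COST_COLUMNS + ["cost_total", "excess_bed_days"]:
            out[col] = pd.Series(dtype=float)
        return out
    out = spells.reset_index(drop=True).copy()
    missing = set(out["core_hrg"]) - set(tariff.inpatient)
    if missing:
        raise ValidationError(f"HRG(s) missing from tariff: {sorted(missing)}")
    bad_method = set(out["admission_method"]) - set(ADMISSION_METHODS)
    if bad_method:
        raise ValidationError(f"unknown admission method(s): {sorted(bad_method)}")
    price_key = {"ELECTIVE": "elective", "NON_ELECTIVE": "non_elective", "DAY_CASE": "day_case"}
    core = np.array(
        [
            tariff.inpatient[hrg][price_key[method]]
            for hrg, method in zip(out["core_hrg"], out["admission_method"])
        ]
    )
    trim = out["core_hrg"].map(lambda h: tariff.inpatient[h]["trim_point"]).to_numpy()
    per_diem = out["core_hrg"].map(lambda h: tariff.inpatient[h]["excess_per_diem"]).to_numpy()
    excess = np.clip(out["length_of_stay"].to_numpy(dtype=float) - trim, 0.0, None)
    out["excess_bed_days"] = excess
    out["cost_bundled"] = core + excess * per_diem

    @functools.lru_cache(maxsize=None)
    def _unbundled_breakdown(codes: str) -> tuple[float, float, float]:
        chemo = radio = other = 0.0
        for code in codes.split(";"):
            if not code:
                continue
            if code not in tariff.unbundled:
                raise ValidationError(f"unbundled HRG {code!r} missing from reference costs")
            tag = classify_unbundled(code)
            if tag == "CHEMO":
                chemo += tariff.unbundled[code]
            elif tag == "RADIO":
                radio += tariff.unbundled[code]
            else:
                other += tariff.unbundled[code]
        return chemo, radio, other

    parts = np.array([_unbundled_breakdown(str(c)) for c in out["unbundled"]])
    out["cost_chemo"] = parts[:, 0]
    out["cost_radio"] = parts[:, 1]
    out["cost_unbundled_other"] = parts[:, 2]
    out["cost_total"] = out[COST_COLUMNS].sum(axis=1)
    return out


def cost_attendances(attendances: pd.DataFrame, tariff: TariffTable) -> pd.DataFrame:
    """Price outpatient attendances by TFC (falling back to the
    attendance HRG), plus any unbundled components."""
    out = attendances.reset_index(drop=True).copy()
    if out.empty:
        for col in COST_COLUMNS + ["cost_total"]:
            out[col] = pd.Series(dtype=float)
        return out

    def _price(tfc: str, hrg: str) -> float:
        code = tfc if tfc in tariff.outpatient else hrg
        if code not in tariff.outpatient:
            raise ValidationError(
                f"attendance code {tfc!r}/{hrg!r} missing from outpatient tariff"
            )
        return tariff.outpatient[code]

    @functools.lru_cache(maxsize=None)
    def _unbundled(codes: str) -> tuple[float, float, float]:
        chemo = radio = other = 0.0
        for code in codes.split(";"):
            if not code:
                continue
            if code not in tariff.unbundled:
                raise ValidationError(f"unbundled HRG {code!r} missing from reference costs")
            tag = classify_unbundled(code)
            if tag == "CHEMO":
                chemo += tariff.unbundled[code]
            elif tag == "RADIO":
                radio += tariff.unbundled[code]
            else:
                other += tariff.unbundled[code]
        return chemo, radio, other

    out["cost_bundled"] = [
        _price(str(t), str(h)) for t, h in zip(out["tfc"], out["hrg"])
    ]
    parts = np.array([_unbundled(str(c)) for c in out["unbundled"]])
    out["cost_chemo"] = parts[:, 0]
    out["cost_radio"] = parts[:, 1]
    out["cost_unbundled_other"] = parts[:, 2]
    out["cost_total"] = out[COST_COLUMNS].sum(axis=1)
    return out


def annual_summary(
    costed_spells: pd.DataFrame,
    costed_attendances: pd.DataFrame,
    partial_year_factor: float = 1.33,
    partial_years: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annual activity and cost summary by year, sex, cohort and setting.

    Partial reporting years (e.g. nine months of data) have their costs,
    event counts and patient counts scaled up by ``partial_year_factor``
    assuming no seasonality.  Returns the per-year table and a
    study-period means table; mean annual cost per patient divides the
    mean annual cost by the mean annual patient count.  Strata with zero
    patients report an absent (NaN) cost per patient.
    """
    if partial_year_factor < 1:
        raise ValidationError("partial_year_factor must be >= 1")
    frames = []
    for df, setting in ((costed_spells, "INPATIENT"), (costed_attendances, "OUTPATIENT")):
        if df is None or df.empty:
            continue
        tmp = df.copy()
        tmp["setting"] = setting
        frames.append(tmp[["year", "sex", "cohort", "setting", "patient_id"] + COST_COLUMNS + ["cost_total"]])
    columns = [
        "year", "sex", "cohort", "setting", "n_patients", "n_events",
    ] + COST_COLUMNS + ["cost_total", "cost_per_patient"]
    if not frames:
        return pd.DataFrame(columns=columns), pd.DataFrame(
            columns=[c for c in columns if c != "year"]
        )
    events = pd.concat(frames, ignore_index=True)
    grouped = (
        events.groupby(["year", "sex", "cohort", "setting"])
        .agg(
            n_patients=("patient_id", "nunique"),
            n_events=("patient_id", "size"),
            **{col: (col, "sum") for col in COST_COLUMNS + ["cost_total"]},
        )
        .reset_index()
    )
    grouped = grouped.astype({"n_patients": float, "n_events": float})
    partial = grouped["year"].isin(partial_years)
    scale_cols = ["n_patients", "n_events"] + COST_COLUMNS + ["cost_total"]
    grouped.loc[partial, scale_cols] = grouped.loc[partial, scale_cols] * partial_year_factor
    grouped["cost_per_patient"] = np.where(
        grouped["n_patients"] > 0, grouped["cost_total"] / grouped["n_patients"], np.nan
    )
    means = (
        grouped.groupby(["sex", "cohort", "setting"])
        .agg(
            n_patients=("n_patients", "mean"),
            n_events=("n_events", "mean"),
            **{col: (col, "mean") for col in COST_COLUMNS + ["cost_total"]},
        )
        .reset_index()
    )
    means["cost_per_patient"] = np.where(
        means["n_patients"] > 0, means["cost_total"] / means["n_patients"], np.nan
    )
    return grouped, means
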