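"""Decision-tree expected costs along the anal cancer treatment pathway.

Populates the Markov model's :class:`~anocost.markov.CostSchedule` from
unit costs and pathway proportions: referral/diagnosis and staging
(including pre-treatment colostomy), primary treatment by arm
(chemoradiotherapy with mitomycin C and 5-FU, or radiotherapy alone),
the follow-up appointment/scan programme, the expected one-off salvage
cost on relapse, and the blended post-relapse monthly cost.

Primary-treatment unit costs depend on the mode of admission (elective
inpatient, day case, non-elective); expected costs are taken over the
admission mix.  All expected costs are affine in every unit cost with
non-negative coefficients, which underpins the tornado-diagram sanity
properties of the sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Literal, Mapping

import numpy as np

from .markov import ValidationError

Arm = Literal["CRT", "RT"]

ADMISSION_TYPES = ("elective", "day_case", "non_elective")


@dataclass(frozen=True)
class UnitCosts:
    """Admission-independent unit costs, GBP at 2010/11 tariff prices.

    ``mri``/``ct``/``fna``/``eua_biopsy`` are the diagnostic and staging
    interventions; ``followup_mri``/``followup_ct`` are the same scan
    types delivered during the follow-up programme (kept separate so the
    staging and follow-up cost blocks can be varied independently in the
    one-way sensitivity analysis); ``palliative_monthly`` is the monthly
    cost of palliative care.
    """

    mri: float
    ct: float
    fna: float
    eua_biopsy: float
    mitomycin_c: float
    followup_appointment: float
    followup_mri: float
    followup_ct: float
    salvage_apr: float
    reconstruction: float
    colostomy: float
    palliative_monthly: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"unit cost {f.name} must be >= 0")


@dataclass(frozen=True)
class AdmissionCosts:
    """Primary-treatment unit costs for one admission type (GBP)."""

    rt_planning: float
    picc_insertion: float
    fu5_procure: float
    fu5_deliver_initial: float
    fu5_deliver_subsequent: float
    rt_delivery: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"admission cost {f.name} must be >= 0")


@dataclass(frozen=True)
class PathwayProportions:
    """Branch probabilities of the costing decision trees.

    ``admission_mix`` maps admission type to the fraction of primary
    treatments delivered under it and must sum to one.
    """

    p_crt: float
    p_advanced: float
    p_salvage: float
    p_colostomy: float
    p_fna: float
    admission_mix: Mapping[str, float]

    def __post_init__(self) -> None:
        for name in ("p_crt", "p_advanced", "p_salvage", "p_colostomy", "p_fna"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
        mix = dict(self.admission_mix)
        unknown = set(mix) - set(ADMISSION_TYPES)
        if unknown:
            raise ValidationError(f"unknown admission types in mix: {sorted(unknown)}")
        if any(not 0.0 <= v <= 1.0 for v in mix.values()):
            raise ValidationError("admission_mix fractions must lie in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValidationError("admission_mix must sum to 1")
        object.__setattr__(self, "admission_mix", mix)


@dataclass(frozen=True)
class FollowUpIntensity:
    """Counts of appointments and scans over one follow-up programme."""

    appointments: float
    mri_scans: float
    ct_scans: float
    risk_level: Literal["LOW", "HIGH"] = "LOW"

    def __post_init__(self) -> None:
        for name in ("appointments", "mri_scans", "ct_scans"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def diagnosis_cost(costs: UnitCosts, props: PathwayProportions) -> float:
    """Expected referral/diagnosis cost: EUA with biopsy, staging MRI and
    CT for everyone, fine-needle aspiration of inguinal nodes where
    applicable (fraction ``p_fna``)."""
    return costs.eua_biopsy + costs.mri + costs.ct + props.p_fna * costs.fna


def staging_cost(costs: UnitCosts, props: PathwayProportions) -> float:
    """Expected diagnosis + staging cost, including the pre-treatment
    defunctioning colostomy branch taken by a fraction ``p_colostomy``."""
    return diagnosis_cost(costs, props) + props.p_colostomy * costs.colostomy


def _arm_cost_for_admission(
    ac: AdmissionCosts,
    arm: Arm,
    n_fu5_cycles: int,
    n_rt_fractions: int,
    mitomycin_c: float,
) -> float:
    cost = ac.rt_planning + n_rt_fractions * ac.rt_delivery
    if arm == "CRT":
        cost += (
            ac.picc_insertion
            + ac.fu5_procure
            + ac.fu5_deliver_initial
            + (n_fu5_cycles - 1) * ac.fu5_deliver_subsequent
            + mitomycin_c
        )
    return cost


def primary_treatment_cost(
    admission_costs: Mapping[str, AdmissionCosts],
    arm: Arm,
    admission_mix: Mapping[str, float],
    n_fu5_cycles: int,
    n_rt_fractions: int,
    mitomycin_c: float = 0.0,
) -> float:
    """Expected primary-treatment cost for one arm.

    The RT arm comprises radiotherapy planning plus ``n_rt_fractions``
    delivered fractions; the CRT arm additionally receives a PICC line,
    mitomycin C and ``n_fu5_cycles`` cycles of 5-FU (one initial, the
    rest subsequent deliveries).  Unit costs are selected per admission
    type and averaged over the admission mix.
    """
    if arm not in ("CRT", "RT"):
        raise ValidationError(f"unknown treatment arm {arm!r}")
    if n_fu5_cycles < 1 or n_rt_fractions < 1:
        raise ValidationError("n_fu5_cycles and n_rt_fractions must be >= 1")
    total = 0.0
    for adm_type, weight in admission_mix.items():
        if weight == 0:
            continue
        if adm_type not in admission_costs:
            raise ValidationError(f"no admission cost table for {adm_type!r}")
        total += weight * _arm_cost_for_admission(
            admission_costs[adm_type], arm, n_fu5_cycles, n_rt_fractions, mitomycin_c
        )
    return total


def followup_total(costs: UnitCosts, intensity: FollowUpIntensity) -> float:
    """Total cost of one completed follow-up programme."""
    return (
        intensity.appointments * costs.followup_appointment
        + intensity.mri_scans * costs.followup_mri
        + intensity.ct_scans * costs.followup_ct
    )


def followup_schedule(
    costs: UnitCosts,
    intensity: FollowUpIntensity,
    horizon_months: int,
    programme_months: int = 120,
) -> np.ndarray:
    """Distribute the follow-up programme cost over monthly cycles.

    Appointments and scans are spread over the programme with yearly
    weights ``1 / year_index`` (uniform within a year), front-loading
    the first post-treatment year where the bulk of review activity
    sits; the vector conserves the programme total exactly.
    """
    if horizon_months < programme_months:
        raise ValidationError("horizon must cover the follow-up programme")
    months = np.arange(programme_months)
    weights = 1.0 / (months // 12 + 1)
    vector = np.zeros(horizon_months)
    total = followup_total(costs, intensity)
    if total > 0:
        vector[:programme_months] = total * weights / weights.sum()
    return vector


def post_relapse_monthly_cost(
    costs: UnitCosts,
    props: PathwayProportions,
    high_risk: FollowUpIntensity,
    programme_months: int = 120,
) -> float:
    """Constant monthly cost in the post-relapse state.

    The Markov model is memory-less, so the post-relapse cost is a
    blend: salvage patients accrue the average monthly cost of a
    completed high-risk follow-up programme, the rest accrue the
    monthly palliative care cost.
    """
    high_monthly = followup_total(costs, high_risk) / programme_months
    return props.p_salvage * high_monthly + (1.0 - props.p_salvage) * costs.palliative_monthly


def relapse_oneoff_cost(costs: UnitCosts, props: PathwayProportions) -> float:
    """Expected one-off cost on entering the relapse tunnel: the salvage
    fraction undergoes abdominoperineal resection plus reconstructive
    surgery."""
    return props.p_salvage * (costs.salvage_apr + costs.reconstruction)


def advanced_disease_cost(
    costs: UnitCosts, props: PathwayProportions, duration_months: float
) -> float:
    """Expected upfront cost for patients presenting with advanced
    disease: diagnosis followed by palliative care for an expected
    duration (months)."""
    if duration_months < 0:
        raise ValidationError("palliative duration must be >= 0")
    return diagnosis_cost(costs, props) + duration_months * costs.palliative_monthly
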