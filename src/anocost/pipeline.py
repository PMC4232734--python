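"""End-to-end cost model: pathway decision trees feeding the Markov engine.

Ties together the pathway costing trees, the cohort model and the
pricing scenario to produce the headline quantity of the analysis: the
average ten-year cost of treating one squamous cell anal cancer case
from referral, blended over treatment arms and the advanced-presentation
palliative branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config as cfgmod
from . import pathway
from .markov import (
    CohortTrace,
    CostResult,
    CostSchedule,
    build_transition_matrix,
    run_cohort,
)

#: Follow-up intensity used by each primary treatment arm.  Patients
#: treated with radiotherapy alone (typically those unable to tolerate
#: full chemoradiotherapy) are followed up on the high-risk programme.
ARM_RISK_LEVEL = {"CRT": "LOW", "RT": "HIGH"}


@dataclass(frozen=True)
class ArmResult:
    arm: str
    upfront_cost: float
    trace: CohortTrace
    costs: CostResult


@dataclass(frozen=True)
class ModelResult:
    """Blended per-case cost and its components for one pricing scenario."""

    inflation_on: bool
    inflation_rate: float
    p_crt: float
    total_per_case: float
    curative_total: float
    advanced_total: float
    arms: dict[str, ArmResult]

    def per_year_blended(self) -> np.ndarray:
        """Per-year curative costs blended over arms (GBP/case-year)."""
        return (
            self.p_crt * self.arms["CRT"].costs.per_year
            + (1.0 - self.p_crt) * self.arms["RT"].costs.per_year
        )


def build_cost_schedule(cfg: dict, arm: str, inflation_on: bool) -> CostSchedule:
    """Assemble the Markov cost schedule of one arm from the config."""
    costs = cfgmod.unit_costs_from_config(cfg)
    props = cfgmod.proportions_from_config(cfg)
    admission = cfgmod.admission_costs_from_config(cfg)
    n_cycles = int(cfgmod.get_path(cfg, "model.n_cycles"))
    programme = int(cfgmod.get_path(cfg, "followup.programme_months"))
    intensity = cfgmod.followup_intensity_from_config(cfg, ARM_RISK_LEVEL[arm])
    high = cfgmod.followup_intensity_from_config(cfg, "HIGH")

    upfront = pathway.staging_cost(costs, props) + pathway.primary_treatment_cost(
        admission,
        arm,
        props.admission_mix,
        int(cfgmod.get_path(cfg, "primary_treatment.n_fu5_cycles")),
        int(cfgmod.get_path(cfg, "primary_treatment.n_rt_fractions")),
        mitomycin_c=costs.mitomycin_c,
    )
    rate = float(cfgmod.get_path(cfg, "model.annual_inflation")) if inflation_on else 0.0
    return CostSchedule(
        upfront_cost=upfront,
        followup_monthly=pathway.followup_schedule(costs, intensity, n_cycles, programme),
        post_relapse_monthly=pathway.post_relapse_monthly_cost(costs, props, high, programme),
        salvage_oneoff=pathway.relapse_oneoff_cost(costs, props),
        inflation_rate=rate,
    )


def run_arm(cfg: dict, arm: str, inflation_on: bool) -> ArmResult:
    """Run staging + primary treatment + Markov follow-up for one arm."""
    from .markov import accumulate_costs

    probs = cfgmod.probabilities_from_config(cfg)
    n_cycles = int(cfgmod.get_path(cfg, "model.n_cycles"))
    schedule = build_cost_schedule(cfg, arm, inflation_on)
    trace = run_cohort(build_transition_matrix(probs), n_cycles=n_cycles)
    costs = accumulate_costs(trace, schedule)
    return ArmResult(arm=arm, upfront_cost=schedule.upfront_cost, trace=trace, costs=costs)


def run_model(cfg: dict, inflation_on: bool) -> ModelResult:
    """Average per-case cost over the ten-year horizon.

    Curative patients are blended over the CRT and RT arms by the CRT
    proportion; the advanced-presentation fraction takes the upfront
    palliative branch instead of the curative pathway.
    """
    costs = cfgmod.unit_costs_from_config(cfg)
    props = cfgmod.proportions_from_config(cfg)
    arms = {arm: run_arm(cfg, arm, inflation_on) for arm in ("CRT", "RT")}
    curative = (
        props.p_crt * arms["CRT"].costs.total
        + (1.0 - props.p_crt) * arms["RT"].costs.total
    )
    advanced = pathway.advanced_disease_cost(
        costs, props, float(cfgmod.get_path(cfg, "model.palliative_duration_months"))
    )
    total = (1.0 - props.p_advanced) * curative + props.p_advanced * advanced
    rate = float(cfgmod.get_path(cfg, "model.annual_inflation")) if inflation_on else 0.0
    return ModelResult(
        inflation_on=inflation_on,
        inflation_rate=rate,
        p_crt=props.p_crt,
        total_per_case=total,
        curative_total=curative,
        advanced_total=advanced,
        arms=arms,
    )


def total_cost_per_case(cfg: dict, inflation_on: bool) -> float:
    """Convenience scalar used by the sensitivity engine."""
    return run_model(cfg, inflation_on).total_per_case
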