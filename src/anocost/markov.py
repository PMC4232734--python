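"""Discrete-time cohort model of squamous cell anal cancer after curative treatment.

The model follows a cohort of patients left disease free by primary
chemoradiotherapy or radiotherapy through four health states:

* ``DISEASE_FREE`` — on the follow-up programme after primary treatment;
* ``RELAPSE`` — a *tunnel* state occupied for exactly one monthly cycle,
  representing the month in which loco-regional relapse is detected and
  salvage interventions (abdominoperineal resection) take place;
* ``POST_RELAPSE`` — after the relapse month, either on post-salvage
  follow-up or palliative care;
* ``DEAD`` — absorbing.

Cycles are one month long and the default horizon is ten years
(120 cycles), the extent of high-risk follow-up.  Three monthly
probabilities drive the dynamics: relapse from disease free, death from
disease free, and death after relapse (the same for salvage and
palliative patients).  Costs are accrued per cycle from a
:class:`CostSchedule` under an optional constant annual inflation rate;
no discounting is applied, since the model estimates realised
reimbursement rather than an investment decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np


class ValidationError(ValueError):
    """Raised when a model input violates its documented invariants."""


class HealthState(IntEnum):
    DISEASE_FREE = 0
    RELAPSE = 1
    POST_RELAPSE = 2
    DEAD = 3


N_STATES = len(HealthState)

#: Default model horizon: ten years of monthly cycles.
DEFAULT_N_CYCLES = 120

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MonthlyProbabilities:
    """The three calibrated monthly transition probabilities.

    Parameters
    ----------
    p_relapse
        Monthly probability of loco-regional relapse from disease free.
    p_death_df
        Monthly probability of (all-cause) death from disease free.
    p_death_pr
        Monthly probability of death during or after the relapse month,
        assumed equal for salvage and palliative patients.
    """

    p_relapse: float
    p_death_df: float
    p_death_pr: float

    def __post_init__(self) -> None:
        for name in ("p_relapse", "p_death_df", "p_death_pr"):
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.p_relapse + self.p_death_df > 1.0:
            raise ValidationError(
                "p_relapse + p_death_df must not exceed 1, got "
                f"{self.p_relapse} + {self.p_death_df}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.p_relapse, self.p_death_df, self.p_death_pr])


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy of the cohort over the model horizon.

    ``occupancy`` has one row per cycle boundary (``n_cycles + 1`` rows,
    row 0 being the initial distribution) and one column per
    :class:`HealthState`.  ``relapse_inflow[t]`` is the cohort fraction
    newly entering the relapse tunnel during cycle ``t``
    (``relapse_inflow[0] = 0``).
    """

    occupancy: np.ndarray
    relapse_inflow: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        inflow = np.asarray(self.relapse_inflow, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValidationError(f"occupancy must be (cycles+1, {N_STATES})")
        if inflow.shape != (occ.shape[0],):
            raise ValidationError("relapse_inflow length must match occupancy rows")
        if np.any(occ < -_ROW_SUM_TOL) or np.any(occ > 1 + _ROW_SUM_TOL):
            raise ValidationError("occupancy entries must lie in [0, 1]")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > _ROW_SUM_TOL:
            raise ValidationError("each occupancy row must sum to 1")
        dead = occ[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -_ROW_SUM_TOL):
            raise ValidationError("DEAD occupancy must be non-decreasing")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "relapse_inflow", inflow)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass(frozen=True)
class CostSchedule:
    """Cost inputs attached to the cohort trace of one treatment arm.

    ``followup_monthly[m]`` is the disease-free follow-up cost in month
    ``m`` since the start of the model (GBP, year-0 prices);
    ``post_relapse_monthly`` applies per month in POST_RELAPSE;
    ``salvage_oneoff`` is the expected one-off cost applied to each unit
    of relapse inflow; ``upfront_cost`` covers referral, diagnosis,
    staging and primary treatment at cycle 0.  ``inflation_rate`` is a
    constant annual rate compounded in whole-year steps (zero for the
    uninflated pricing scenario).
    """

    upfront_cost: float
    followup_monthly: np.ndarray
    post_relapse_monthly: float
    salvage_oneoff: float
    inflation_rate: float = 0.0

    def __post_init__(self) -> None:
        fu = np.asarray(self.followup_monthly, dtype=float)
        if fu.ndim != 1:
            raise ValidationError("followup_monthly must be a 1-D vector")
        if np.any(fu < 0):
            raise ValidationError("followup_monthly entries must be >= 0")
        for name in ("upfront_cost", "post_relapse_monthly", "salvage_oneoff"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.inflation_rate < 0:
            raise ValidationError("inflation_rate must be >= 0")
        object.__setattr__(self, "followup_monthly", fu)


@dataclass(frozen=True)
class CostResult:
    """Per-cycle, per-year and total costs for one model run (GBP)."""

    per_cycle: np.ndarray
    per_year: np.ndarray
    total: float


def build_transition_matrix(probs: MonthlyProbabilities) -> np.ndarray:
    """Assemble the 4x4 monthly transition matrix.

    Disease-free patients may relapse, die or remain disease free; the
    relapse tunnel always empties after one cycle (survivors move to
    POST_RELAPSE); post-relapse patients face the same monthly death
    probability as relapse-month patients; DEAD is absorbing.
    """
    p_r, p_ddf, p_dpr = probs.p_relapse, probs.p_death_df, probs.p_death_pr
    matrix = np.zeros((N_STATES, N_STATES))
    matrix[HealthState.DISEASE_FREE] = [1.0 - p_r - p_ddf, p_r, 0.0, p_ddf]
    matrix[HealthState.RELAPSE] = [0.0, 0.0, 1.0 - p_dpr, p_dpr]
    matrix[HealthState.POST_RELAPSE] = [0.0, 0.0, 1.0 - p_dpr, p_dpr]
    matrix[HealthState.DEAD] = [0.0, 0.0, 0.0, 1.0]
    return matrix


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (N_STATES, N_STATES):
        raise ValidationError(f"transition matrix must be {N_STATES}x{N_STATES}")
    if np.any(matrix < 0) or np.any(matrix > 1):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    if np.max(np.abs(matrix.sum(axis=1) - 1.0)) > _ROW_SUM_TOL:
        raise ValidationError("transition matrix rows must sum to 1")
    return matrix


def run_cohort(
    matrix: np.ndarray,
    n_cycles: int = DEFAULT_N_CYCLES,
    init: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate the cohort through ``n_cycles`` monthly cycles.

    By default the whole cohort starts disease free, reflecting the
    assumption that curative primary treatment leaves all patients
    free of detectable disease.
    """
    matrix = _validate_matrix(matrix)
    if init is None:
        init = np.zeros(N_STATES)
        init[HealthState.DISEASE_FREE] = 1.0
    init = np.asarray(init, dtype=float)
    if init.shape != (N_STATES,) or np.any(init < 0) or abs(init.sum() - 1.0) > _ROW_SUM_TOL:
        raise ValidationError("init must be a length-4 occupancy vector summing to 1")

    occupancy = np.empty((n_cycles + 1, N_STATES))
    inflow = np.zeros(n_cycles + 1)
    occupancy[0] = init
    p_relapse = matrix[HealthState.DISEASE_FREE, HealthState.RELAPSE]
    for t in range(1, n_cycles + 1):
        occupancy[t] = occupancy[t - 1] @ matrix
        inflow[t] = occupancy[t - 1, HealthState.DISEASE_FREE] * p_relapse
    return CohortTrace(occupancy=occupancy, relapse_inflow=inflow)


def cumulative_outcomes(trace: CohortTrace) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative all-cause mortality and cumulative relapse per cycle.

    These are the two curves the model is calibrated against: DEAD
    occupancy, and the running sum of relapse inflow (counting every
    first entry into the relapse tunnel).
    """
    cum_mortality = trace.occupancy[:, HealthState.DEAD].copy()
    cum_relapse = np.cumsum(trace.relapse_inflow)
    return cum_mortality, cum_relapse


def accumulate_costs(trace: CohortTrace, schedule: CostSchedule) -> CostResult:
    """Accrue costs over the trace under the schedule's pricing scenario.

    Cycle ``t`` (t = 1..n) is costed on its start-of-cycle occupancy
    ``occupancy[t-1]`` — no half-cycle correction — with schedule month
    index ``t-1`` and an annually compounded inflation factor
    ``(1 + rate)^floor((t-1)/12)``.  The salvage one-off follows the
    relapse inflow of the cycle.  The upfront cost sits at cycle 0 in
    year-0 prices.
    """
    n = trace.n_cycles
    if len(schedule.followup_monthly) < n:
        raise ValidationError(
            f"followup_monthly has {len(schedule.followup_monthly)} months; "
            f"trace needs {n}"
        )
    months = np.arange(n)  # month-since-start index of cycles 1..n
    factor = (1.0 + schedule.inflation_rate) ** (months // 12)
    df = trace.occupancy[:-1, HealthState.DISEASE_FREE]
    pr = trace.occupancy[:-1, HealthState.POST_RELAPSE]
    monthly = (
        df * schedule.followup_monthly[:n]
        + pr * schedule.post_relapse_monthly
        + trace.relapse_inflow[1:] * schedule.salvage_oneoff
    ) * factor

    per_cycle = np.concatenate([[schedule.upfront_cost], monthly])
    n_years = -(-n // 12)
    per_year = np.zeros(n_years)
    for y in range(n_years):
        per_year[y] = per_cycle[1 + 12 * y : 1 + 12 * (y + 1)].sum()
    per_year[0] += schedule.upfront_cost
    return CostResult(per_cycle=per_cycle, per_year=per_year, total=float(per_cycle.sum()))
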