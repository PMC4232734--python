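"""Calibration of the monthly transition probabilities.

The three monthly probabilities (relapse, death from disease free,
death post relapse) are not observed directly; they are estimated by an
iterative batch random search against longitudinal target curves of
cumulative all-cause mortality and cumulative loco-regional relapse.
Each round draws a batch of candidate triples uniformly from the
current ranges (1,000 per batch by default), scores each by the least
squares distance between the model's curves and the target at the
target months, then recentres and contracts the ranges around the
round's best triple.  The search stops when the best objective no
longer improves at three significant figures, or after a maximum
number of rounds.

The batch evaluation is vectorised over candidate triples so that a
full calibration costs a few thousand 4-state cycle updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import DEFAULT_N_CYCLES, MonthlyProbabilities, ValidationError

PARAM_NAMES = ("p_relapse", "p_death_df", "p_death_pr")

_MONOTONE_TOL = 1e-9


@dataclass(frozen=True)
class CalibrationTarget:
    """Target curves to fit: cumulative mortality and cumulative relapse
    fractions at ordered follow-up months.

    ``cum_relapse`` may be ``None`` to fit mortality alone — useful for
    demonstrating that the mortality curve by itself cannot separate the
    two death probabilities.
    """

    months: np.ndarray
    cum_mortality: np.ndarray
    cum_relapse: np.ndarray | None

    def __post_init__(self) -> None:
        months = np.asarray(self.months, dtype=int)
        mort = np.asarray(self.cum_mortality, dtype=float)
        if months.ndim != 1 or len(months) == 0:
            raise ValidationError("months must be a non-empty 1-D array")
        if np.any(np.diff(months) <= 0) or months[0] < 0:
            raise ValidationError("months must be strictly increasing and >= 0")
        series = {"cum_mortality": mort}
        rel = self.cum_relapse
        if rel is not None:
            rel = np.asarray(rel, dtype=float)
            series["cum_relapse"] = rel
        for name, values in series.items():
            if values.shape != months.shape:
                raise ValidationError(f"{name} must have one value per month")
            if np.any(values < -_MONOTONE_TOL) or np.any(values > 1 + _MONOTONE_TOL):
                raise ValidationError(f"{name} must lie in [0, 1]")
            if np.any(np.diff(values) < -_MONOTONE_TOL):
                raise ValidationError(f"{name} must be non-decreasing")
        object.__setattr__(self, "months", months)
        object.__setattr__(self, "cum_mortality", mort)
        object.__setattr__(self, "cum_relapse", rel)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTarget":
        df = pd.read_csv(path)
        required = {"month", "cum_mortality"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"target CSV missing columns: {sorted(missing)}")
        rel = df["cum_relapse"].to_numpy() if "cum_relapse" in df.columns else None
        return cls(
            months=df["month"].to_numpy(),
            cum_mortality=df["cum_mortality"].to_numpy(),
            cum_relapse=rel,
        )

    def to_csv(self, path: str | Path) -> None:
        data = {"month": self.months, "cum_mortality": self.cum_mortality}
        if self.cum_relapse is not None:
            data["cum_relapse"] = self.cum_relapse
        pd.DataFrame(data).to_csv(path, index=False)


@dataclass(frozen=True)
class SearchConfig:
    """Settings of the iterative batch random search.

    ``contraction`` is the factor by which each parameter's range width
    shrinks per round (the width never shrinks below the spread of the
    round's best-fitting ``top_frac`` triples, so weakly identified
    parameters keep a wide range until the rest of the space is pinned
    down).  ``local_frac`` of each batch after the first is drawn from a
    Gaussian around the incumbent best to refine it.  The search stops
    once the best objective has been unchanged at ``sig_figs``
    significant figures for ``patience`` consecutive rounds, or at
    ``max_rounds``.
    """

    ranges: dict[str, tuple[float, float]]
    batch_size: int = 1000
    contraction: float = 0.5
    max_rounds: int = 20
    sig_figs: int = 3
    seed: int = 0
    top_frac: float = 0.05
    local_frac: float = 0.3
    patience: int = 3

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.ranges:
                raise ValidationError(f"ranges must include {name}")
            low, high = self.ranges[name]
            if not 0.0 <= low <= high <= 1.0:
                raise ValidationError(
                    f"range for {name} must satisfy 0 <= low <= high <= 1"
                )
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if not 0.0 < self.contraction < 1.0:
            raise ValidationError("contraction must lie in (0, 1)")
        if self.max_rounds < 1 or self.sig_figs < 1:
            raise ValidationError("max_rounds and sig_figs must be >= 1")
        if not 0.0 < self.top_frac <= 1.0 or not 0.0 <= self.local_frac < 1.0:
            raise ValidationError("top_frac must be in (0, 1], local_frac in [0, 1)")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")


@dataclass(frozen=True)
class CalibrationResult:
    best: MonthlyProbabilities
    best_objective: float
    converged: bool
    history: pd.DataFrame = field(repr=False)


def predicted_curves_batch(
    triples: np.ndarray, months: np.ndarray, n_cycles: int = DEFAULT_N_CYCLES
) -> tuple[np.ndarray, np.ndarray]:
    """Model curves for a batch of probability triples.

    Runs the 4-state recursion for all ``B`` triples at once and samples
    cumulative mortality and cumulative relapse at ``months``.  Returns
    two ``(B, len(months))`` arrays.
    """
    triples = np.atleast_2d(np.asarray(triples, dtype=float))
    months = np.asarray(months, dtype=int)
    if np.any(months < 0) or np.any(months > n_cycles):
        raise ValidationError(
            f"target months must lie within the model horizon (0..{n_cycles})"
        )
    p_r, p_ddf, p_dpr = triples[:, 0], triples[:, 1], triples[:, 2]
    n = triples.shape[0]
    df = np.ones(n)
    rl = np.zeros(n)
    pr = np.zeros(n)
    dead = np.zeros(n)
    cum_rel = np.zeros(n)

    month_index = {int(m): j for j, m in enumerate(months)}
    mort_out = np.zeros((n, len(months)))
    rel_out = np.zeros((n, len(months)))
    if 0 in month_index:
        j = month_index[0]
        mort_out[:, j] = dead
        rel_out[:, j] = cum_rel
    for t in range(1, int(months[-1]) + 1):
        inflow = df * p_r
        dead = dead + df * p_ddf + (rl + pr) * p_dpr
        pr = (pr + rl) * (1.0 - p_dpr)
        rl = inflow * 1.0
        df = df * (1.0 - p_r - p_ddf)
        cum_rel = cum_rel + inflow
        if t in month_index:
            j = month_index[t]
            mort_out[:, j] = dead
            rel_out[:, j] = cum_rel
    return mort_out, rel_out


def objective_batch(triples: np.ndarray, target: CalibrationTarget) -> np.ndarray:
    """Least-squares goodness-of-fit of each triple against the target:
    the sum of squared deviations of both curves at the target months
    (mortality alone if the target carries no relapse curve)."""
    mort, rel = predicted_curves_batch(triples, target.months)
    score = ((mort - target.cum_mortality) ** 2).sum(axis=1)
    if target.cum_relapse is not None:
        score = score + ((rel - target.cum_relapse) ** 2).sum(axis=1)
    return score


def objective(probs: MonthlyProbabilities, target: CalibrationTarget) -> float:
    """Goodness-of-fit score for a single probability triple."""
    return float(objective_batch(probs.as_array()[None, :], target)[0])


def sample_batch(
    ranges: dict[str, tuple[float, float]],
    batch_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``batch_size`` triples uniformly within ``ranges``.

    Triples violating the joint feasibility constraint
    ``p_relapse + p_death_df <= 1`` are redrawn.
    """
    lows = np.array([ranges[name][0] for name in PARAM_NAMES])
    highs = np.array([ranges[name][1] for name in PARAM_NAMES])
    if np.any(lows > highs):
        raise ValidationError("infeasible ranges: low > high")
    batch = rng.uniform(lows, highs, size=(batch_size, 3))
    for _ in range(1000):
        bad = batch[:, 0] + batch[:, 1] > 1.0
        if not bad.any():
            break
        batch[bad] = rng.uniform(lows, highs, size=(int(bad.sum()), 3))
    else:  # pragma: no cover - only reachable with pathological ranges
        raise ValidationError("could not draw feasible triples from ranges")
    return batch


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures (0 maps to 0)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig_figs}g}")


def _draw_round(
    ranges: dict[str, tuple[float, float]],
    config: SearchConfig,
    rng: np.random.Generator,
    incumbent: np.ndarray | None,
) -> np.ndarray:
    """One round's candidates: uniform over the current ranges plus a
    local Gaussian refinement cloud around the incumbent best."""
    lows = np.array([ranges[name][0] for name in PARAM_NAMES])
    highs = np.array([ranges[name][1] for name in PARAM_NAMES])
    n_local = int(config.local_frac * config.batch_size) if incumbent is not None else 0
    batch = sample_batch(ranges, config.batch_size - n_local, rng)
    if n_local:
        sd = (highs - lows) / 10.0 + 1e-12
        local = np.clip(rng.normal(incumbent, sd, size=(n_local, 3)), 0.0, 1.0)
        bad = local[:, 0] + local[:, 1] > 1.0
        if bad.any():
            local[bad] = sample_batch(ranges, int(bad.sum()), rng)
        batch = np.vstack([batch, local])
    return batch


def _contract(
    ranges: dict[str, tuple[float, float]],
    centre: np.ndarray,
    top: np.ndarray,
    contraction: float,
) -> dict[str, tuple[float, float]]:
    """Recentre each range on the round-best triple; shrink its width by
    ``contraction`` but never below the spread of the round's
    best-fitting triples, which keeps weakly identified directions open."""
    new = {}
    for j, name in enumerate(PARAM_NAMES):
        low, high = ranges[name]
        width = max((high - low) * contraction, float(np.ptp(top[:, j])))
        new[name] = (max(0.0, centre[j] - width / 2), min(1.0, centre[j] + width / 2))
    return new


def calibrate(target: CalibrationTarget, config: SearchConfig) -> CalibrationResult:
    """Run the iterative batch random search against the target.

    Per-round best objectives are monotone non-increasing (the
    incumbent best triple is carried into every round's scoring).
    Convergence is declared when the best objective has not changed at
    ``sig_figs`` significant figures for ``patience`` consecutive
    rounds.
    """
    rng = np.random.default_rng(config.seed)
    ranges = dict(config.ranges)
    best_triple: np.ndarray | None = None
    best_score = np.inf
    rows = []
    converged = False
    stalled = 0
    for round_no in range(1, config.max_rounds + 1):
        batch = _draw_round(ranges, config, rng, best_triple)
        if best_triple is not None:
            batch = np.vstack([best_triple, batch])
        scores = objective_batch(batch, target)
        if not np.all(np.isfinite(scores)):
            raise ValidationError("non-finite calibration objective encountered")
        order = np.argsort(scores)
        prev_rounded = round_sig(best_score, config.sig_figs)
        best_triple = batch[order[0]]
        best_score = float(scores[order[0]])
        rounded = round_sig(best_score, config.sig_figs)
        rows.append(
            {
                "round": round_no,
                "best_objective": best_score,
                "p_relapse": best_triple[0],
                "p_death_df": best_triple[1],
                "p_death_pr": best_triple[2],
                **{f"{name}_low": ranges[name][0] for name in PARAM_NAMES},
                **{f"{name}_high": ranges[name][1] for name in PARAM_NAMES},
            }
        )
        if round_no > 1:
            stalled = stalled + 1 if rounded == prev_rounded else 0
            if stalled >= config.patience:
                converged = True
                break
        n_top = max(2, int(round(config.top_frac * config.batch_size)))
        ranges = _contract(ranges, best_triple, batch[order[:n_top]], config.contraction)
    best = MonthlyProbabilities(*best_triple)
    return CalibrationResult(
        best=best,
        best_objective=best_score,
        converged=converged,
        history=pd.DataFrame(rows),
    )
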