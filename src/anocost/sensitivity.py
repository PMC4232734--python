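"""One-way sensitivity analysis and tornado diagram.

Each sensitivity variable is a named block of config paths that move
together (a published bound block forms one scenario, hence one tornado
bar).  For every variable the model total is recomputed twice — all
members at their low values, then all at their high values, everything
else at base — and variables are ranked by the absolute spread between
the two totals.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from . import config as cfgmod
from . import pipeline
from .markov import ValidationError


@dataclass(frozen=True)
class SensitivityVariable:
    """A jointly varied block of config parameters."""

    name: str
    members: tuple[str, ...]
    low_values: tuple
    high_values: tuple

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"sensitivity variable {self.name!r} has no members")
        if not len(self.members) == len(self.low_values) == len(self.high_values):
            raise ValidationError(
                f"sensitivity variable {self.name!r}: members, low and high "
                "must have equal length"
            )
        for low, high in zip(self.low_values, self.high_values):
            if isinstance(low, (int, float)) and isinstance(high, (int, float)):
                if low > high:
                    raise ValidationError(
                        f"sensitivity variable {self.name!r}: low > high"
                    )


def parse_variables(cfg: dict) -> list[SensitivityVariable]:
    """Read the ``sensitivity`` config section into variable blocks."""
    blocks = cfg.get("sensitivity", [])
    return [
        SensitivityVariable(
            name=block["name"],
            members=tuple(block["members"]),
            low_values=tuple(block["low"]),
            high_values=tuple(block["high"]),
        )
        for block in blocks
    ]


@dataclass(frozen=True)
class TornadoResult:
    base_total: float
    table: pd.DataFrame  # name, low_total, high_total, spread; sorted by |spread|
    min_total: float
    max_total: float


def _substituted(cfg: dict, variable: SensitivityVariable, values: Sequence) -> dict:
    scenario = copy.deepcopy(cfg)
    for path, value in zip(variable.members, values):
        cfgmod.set_path(scenario, path, value)
    return scenario


def one_way(
    cfg: dict,
    variables: Sequence[SensitivityVariable] | None = None,
    inflation_on: bool = True,
    total_fn: Callable[[dict, bool], float] = pipeline.total_cost_per_case,
) -> TornadoResult:
    """Run the one-way analysis and return the tornado-ordered table.

    ``total_fn`` maps (config, inflation flag) to the model total; the
    default is the full per-case cost pipeline, but any scalar summary
    of a config can be analysed.
    """
    if variables is None:
        variables = parse_variables(cfg)
    base_total = total_fn(cfg, inflation_on)
    rows = []
    totals = [base_total]
    for variable in variables:
        low_total = total_fn(_substituted(cfg, variable, variable.low_values), inflation_on)
        high_total = total_fn(_substituted(cfg, variable, variable.high_values), inflation_on)
        totals.extend([low_total, high_total])
        rows.append(
            {
                "name": variable.name,
                "low_total": low_total,
                "high_total": high_total,
                "spread": high_total - low_total,
            }
        )
    table = pd.DataFrame(rows, columns=["name", "low_total", "high_total", "spread"])
    if len(table):
        table = (
            table.reindex(table["spread"].abs().sort_values(ascending=False).index)
            .reset_index(drop=True)
        )
    return TornadoResult(
        base_total=base_total,
        table=table,
        min_total=min(totals),
        max_total=max(totals),
    )


def plot_tornado(result: TornadoResult, path: str | Path) -> None:
    """Write a tornado diagram (horizontal bars around the base case)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table.iloc[::-1]  # widest bar on top
    fig, ax = plt.subplots(figsize=(8, 0.5 * max(len(table), 2) + 1.5))
    for i, row in enumerate(table.itertuples()):
        left = min(row.low_total, row.high_total)
        width = abs(row.high_total - row.low_total)
        ax.barh(i, width, left=left, color="steelblue", edgecolor="black")
    ax.axvline(result.base_total, color="black", linestyle="--", linewidth=1)
    ax.set_yticks(range(len(table)))
    ax.set_yticklabels(table["name"])
    ax.set_xlabel("Total cost per case (GBP)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
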