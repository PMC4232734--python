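"""Declarative configuration: loading, path access and typed builders.

All model inputs — unit costs, admission-dependent primary-treatment
costs, pathway proportions, follow-up intensities, monthly transition
probabilities and the one-way sensitivity variable blocks — live in a
single YAML file.  Dotted paths (``unit_costs.mri``) address individual
values so the sensitivity engine can substitute bounds generically.

A default configuration ships with the package.  Its Table-style
sensitivity bounds come from the published one-way analysis ranges; its
base unit costs are illustrative 2010/11-tariff-scale values (midpoints
of the published bounds where bounds exist), since the full base-case
parameter file is an external input.
"""

from __future__ import annotations

import copy
import importlib.resources
from pathlib import Path
from typing import Any

import yaml

from .markov import MonthlyProbabilities, ValidationError
from .pathway import AdmissionCosts, FollowUpIntensity, PathwayProportions, UnitCosts

DEFAULT_CONFIG_RESOURCE = "base_config.yaml"


def default_config_path() -> Path:
    """Path of the packaged default configuration file."""
    return Path(importlib.resources.files("anocost") / "data" / DEFAULT_CONFIG_RESOURCE)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML configuration (the packaged default when no path given)."""
    cfg_path = default_config_path() if path is None else Path(path)
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {cfg_path} did not parse to a mapping")
    return cfg


def get_path(cfg: dict, dotted: str) -> Any:
    """Fetch a value at a dotted path, erroring with the offending path."""
    node: Any = cfg
    for key in dotted.split("."):
        if not isinstance(node, dict) or key not in node:
            raise ValidationError(f"config path not found: {dotted!r}")
        node = node[key]
    return node


def set_path(cfg: dict, dotted: str, value: Any) -> None:
    """Replace the value at a dotted path in place; the path must exist."""
    keys = dotted.split(".")
    node: Any = cfg
    for key in keys[:-1]:
        if not isinstance(node, dict) or key not in node:
            raise ValidationError(f"config path not found: {dotted!r}")
        node = node[key]
    if not isinstance(node, dict) or keys[-1] not in node:
        raise ValidationError(f"config path not found: {dotted!r}")
    node[keys[-1]] = copy.deepcopy(value)


def _require(cfg: dict, dotted: str) -> Any:
    try:
        return get_path(cfg, dotted)
    except ValidationError as exc:
        raise ValidationError(f"missing required config parameter: {dotted!r}") from exc


def unit_costs_from_config(cfg: dict) -> UnitCosts:
    section = _require(cfg, "unit_costs")
    try:
        return UnitCosts(**section)
    except TypeError as exc:
        raise ValidationError(f"unit_costs section malformed: {exc}") from exc


def proportions_from_config(cfg: dict) -> PathwayProportions:
    section = _require(cfg, "proportions")
    try:
        return PathwayProportions(**section)
    except TypeError as exc:
        raise ValidationError(f"proportions section malformed: {exc}") from exc


def admission_costs_from_config(cfg: dict) -> dict[str, AdmissionCosts]:
    table = _require(cfg, "primary_treatment.admission_costs")
    return {name: AdmissionCosts(**row) for name, row in table.items()}


def followup_intensity_from_config(cfg: dict, risk_level: str) -> FollowUpIntensity:
    key = risk_level.lower()
    section = _require(cfg, f"followup.{key}")
    return FollowUpIntensity(risk_level=risk_level.upper(), **section)


def probabilities_from_config(cfg: dict) -> MonthlyProbabilities:
    section = _require(cfg, "probabilities")
    try:
        return MonthlyProbabilities(**section)
    except TypeError as exc:
        raise ValidationError(f"probabilities section malformed: {exc}") from exc
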