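"""Run-configuration parsing, validation, and scenario overrides.

A run configuration binds everything one model evaluation needs: cycle
settings, epidemiology and test accuracy, per-regimen cost schedules and
adverse-event disutilities, health-state utilities, the curve manifest
mapping model branches to digitized-curve CSV files, and the strategy
definitions (decision-tree arms and their treatment-line pathways).

Scenario overrides address configuration entries by dotted path
(``strategies.testing.arms.0.lines.1.os``); unknown keys raise an error
listing the valid keys at that level.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .decision_tree import TestPerformance
from .markov_engine import CycleConfig

__all__ = [
    "RunConfig",
    "RegimenSpec",
    "LineBinding",
    "ArmSpec",
    "StrategySpec",
    "ConfigError",
    "load_and_validate",
    "apply_overrides",
    "config_hash",
]

EXTRAPOLATION_METHODS = ("mean", "regression", "least_squares")

# symbolic arm weights resolved against the decision-tree proportions
ARM_WEIGHT_KEYS = ("p_test_positive", "p_test_negative", "p_chemo_pathway",
                   "p_unknown", "all")


class ConfigError(ValueError):
    """Validation failure; ``errors`` collects every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass(frozen=True)
class RegimenSpec:
    name: str
    cost_admin: float
    cost_nonadmin: float
    admin_cycles: int | str  # int or "all"
    oral: bool = False
    ae_disutility: float = 0.0

    def admin_cycle_count(self, horizon: int) -> int:
        return horizon if self.admin_cycles == "all" else int(self.admin_cycles)


@dataclass(frozen=True)
class LineBinding:
    """One treatment line of a pathway: regimen + curve branches + utility key."""

    regimen: str
    os: str
    pfs: str | None = None
    utility: str = "pre_progression"


@dataclass(frozen=True)
class ArmSpec:
    name: str
    weight: str | float
    lines: tuple[LineBinding, ...]


@dataclass(frozen=True)
class StrategySpec:
    name: str
    arms: tuple[ArmSpec, ...]
    test_cost_applies: bool = False


@dataclass
class RunConfig:
    """Validated model configuration.

    ``raw`` keeps the normalized dictionary form for serialization and
    dotted-path scenario overrides; the typed fields are derived from it.
    """

    raw: dict[str, Any]
    cycle: CycleConfig = field(init=False)
    prevalence: float = field(init=False)
    test: TestPerformance = field(init=False)
    test_cost: float = field(init=False)
    extrapolation: str = field(init=False)
    ae_whole_admin_period: bool = field(init=False)
    iv_disutility_scenario: bool = field(init=False)
    utilities: dict[str, float] = field(init=False)
    regimens: dict[str, RegimenSpec] = field(init=False)
    cost_scale: dict[str, float] = field(init=False)
    curve_dir: str = field(init=False)
    curve_branches: dict[str, list[str]] = field(init=False)
    strategies: dict[str, StrategySpec] = field(init=False)

    def __post_init__(self) -> None:
        errors: list[str] = []
        raw = self.raw

        def prob(section: Mapping, key: str, path: str) -> float:
            v = float(section.get(key, -1))
            if not (0.0 <= v <= 1.0):
                errors.append(f"{path}.{key}: probability {v} outside [0, 1]")
            return v

        cyc = raw.get("cycle", {})
        try:
            self.cycle = CycleConfig(
                horizon=int(cyc.get("horizon", 60)),
                annual_discount_rate=float(cyc.get("annual_discount_rate", 0.03)),
                half_cycle_correction=bool(cyc.get("half_cycle_correction", False)),
            )
        except ValueError as e:
            errors.append(f"cycle: {e}")
            self.cycle = CycleConfig()

        epi = raw.get("epidemiology", {})
        self.prevalence = prob(epi, "prevalence", "epidemiology")
        sens = prob(epi, "sensitivity", "epidemiology")
        spec = prob(epi, "specificity", "epidemiology")
        punk = prob(epi, "p_unknown", "epidemiology")
        try:
            self.test = TestPerformance(sens, spec, punk)
        except ValueError:
            self.test = TestPerformance(0.5, 0.5, 0.0)

        self.test_cost = float(raw.get("test_cost", 0.0))
        if self.test_cost < 0:
            errors.append("test_cost: negative cost")

        self.extrapolation = raw.get("extrapolation", "mean")
        if self.extrapolation not in EXTRAPOLATION_METHODS:
            errors.append(
                f"extrapolation: {self.extrapolation!r} not one of {EXTRAPOLATION_METHODS}")
        self.ae_whole_admin_period = bool(raw.get("ae_whole_admin_period", False))
        self.iv_disutility_scenario = bool(raw.get("iv_disutility_scenario", False))

        self.utilities = {k: float(v) for k, v in raw.get("utilities", {}).items()}
        for key in ("pre_progression", "progression", "bsc"):
            if key not in self.utilities:
                errors.append(f"utilities.{key}: missing")
            elif not (0.0 <= self.utilities[key] <= 1.0):
                errors.append(f"utilities.{key}: outside [0, 1]")
        self.utilities.setdefault("oral_adjustment", 0.02)
        self.utilities.setdefault("iv_disutility", 0.043)

        self.regimens = {}
        for name, r in raw.get("regimens", {}).items():
            spec_ = RegimenSpec(
                name=name,
                cost_admin=float(r.get("cost_admin", -1)),
                cost_nonadmin=float(r.get("cost_nonadmin", -1)),
                admin_cycles=r.get("admin_cycles", 0),
                oral=bool(r.get("oral", False)),
                ae_disutility=float(r.get("ae_disutility", 0.0)),
            )
            if spec_.cost_admin < 0 or spec_.cost_nonadmin < 0:
                errors.append(f"regimens.{name}: negative or missing cost")
            if spec_.admin_cycles != "all" and int(spec_.admin_cycles) < 0:
                errors.append(f"regimens.{name}.admin_cycles: negative")
            self.regimens[name] = spec_

        self.cost_scale = {k: float(v) for k, v in raw.get("cost_scale", {}).items()}
        for name in self.cost_scale:
            if name not in self.regimens and name != "test":
                errors.append(f"cost_scale.{name}: unknown regimen")

        curves = raw.get("curves", {})
        self.curve_dir = curves.get("dir", "curves")
        self.curve_branches = {k: list(v) for k, v in curves.get("branches", {}).items()}

        self.strategies = {}
        for sname, s in raw.get("strategies", {}).items():
            arms = []
            for i, a in enumerate(s.get("arms", [])):
                lines = []
                for j, ln in enumerate(a.get("lines", [])):
                    lb = LineBinding(
                        regimen=ln.get("regimen", ""),
                        os=ln.get("os", ""),
                        pfs=ln.get("pfs"),
                        utility=ln.get("utility", "pre_progression"),
                    )
                    where = f"strategies.{sname}.arms.{i}.lines.{j}"
                    if lb.regimen not in self.regimens:
                        errors.append(f"{where}.regimen: unknown regimen {lb.regimen!r}")
                    if lb.os not in self.curve_branches:
                        errors.append(f"{where}.os: unbound curve branch {lb.os!r}")
                    if lb.pfs is not None and lb.pfs not in self.curve_branches:
                        errors.append(f"{where}.pfs: unbound curve branch {lb.pfs!r}")
                    if lb.utility not in ("pre_progression", "progression", "bsc"):
                        errors.append(f"{where}.utility: unknown key {lb.utility!r}")
                    lines.append(lb)
                weight = a.get("weight", "all")
                if isinstance(weight, str) and weight not in ARM_WEIGHT_KEYS:
                    errors.append(
                        f"strategies.{sname}.arms.{i}.weight: {weight!r} "
                        f"not numeric or one of {ARM_WEIGHT_KEYS}")
                if lines and lines[-1].pfs is not None:
                    errors.append(
                        f"strategies.{sname}.arms.{i}: pathway must end in a "
                        "terminal line without a PFS branch")
                arms.append(ArmSpec(a.get("name", f"arm{i}"), weight, tuple(lines)))
            self.strategies[sname] = StrategySpec(
                sname, tuple(arms), bool(s.get("test_cost_applies", False)))
        if errors:
            raise ConfigError(errors)

    def to_dict(self) -> dict[str, Any]:
        return copy.deepcopy(self.raw)

    def with_overrides(self, overrides: Mapping[str, Any]) -> "RunConfig":
        return RunConfig(apply_overrides(self.raw, overrides))

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(raw: Mapping[str, Any]) -> str:
    """Short stable digest of the resolved configuration, for reports."""
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_and_validate(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) configuration file and validate it fully."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return RunConfig(raw)


def _set_dotted(raw: dict, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node: Any = raw
    for i, part in enumerate(parts[:-1]):
        if isinstance(node, list):
            try:
                node = node[int(part)]
            except (ValueError, IndexError):
                raise KeyError(
                    f"override {dotted!r}: index {part!r} invalid; "
                    f"valid indices: 0..{len(node) - 1}")
        elif isinstance(node, dict):
            if part not in node:
                raise KeyError(
                    f"override {dotted!r}: unknown key {part!r}; "
                    f"valid keys: {sorted(node)}")
            node = node[part]
        else:
            raise KeyError(f"override {dotted!r}: {'.'.join(parts[:i])} is a leaf")
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    elif isinstance(node, dict):
        # creating new leaves is allowed only in explicitly open sections
        if last not in node and parts[0] not in ("cost_scale",):
            raise KeyError(
                f"override {dotted!r}: unknown key {last!r}; valid keys: {sorted(node)}")
        node[last] = value
    else:
        raise KeyError(f"override {dotted!r}: target is a leaf")


def apply_overrides(raw: Mapping[str, Any], overrides: Mapping[str, Any]) -> dict:
    """Return a deep copy of ``raw`` with dotted-path overrides applied."""
    out = copy.deepcopy(dict(raw))
    out.setdefault("cost_scale", {})
    for dotted, value in overrides.items():
        _set_dotted(out, dotted, value)
    return out
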