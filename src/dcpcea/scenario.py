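"""Scenario configuration: loading, validation and the shipped base cases.

A scenario bundles everything one subgroup model needs: the four fitted
survival models (PFS/OS per arm), unit costs, utilities, adverse-event
profiles, the horizon, the discount rate and the willingness-to-pay
threshold.  Two configuration files ship with the package, one per
mismatch-repair subgroup (``dmmr``, ``pmmr``); validation is strict and
rejects unknown keys so that typos fail loudly rather than silently falling
back to defaults.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .cohort import Horizon
from .costs import AEProfile, CostInputs, UtilityInputs
from .survival import SurvivalModel

__all__ = ["Scenario", "ScenarioError", "load_scenario", "load_builtin", "save_scenario"]

ARMS = ("DCP", "CP")


class ScenarioError(ValueError):
    """Configuration is missing fields, has unknown keys, or fails checks."""


@dataclass(frozen=True)
class Scenario:
    subgroup: str
    models: dict  # {arm: {"pfs": SurvivalModel, "os": SurvivalModel}}
    costs: CostInputs
    utilities: UtilityInputs
    ae_profiles: dict  # {arm: AEProfile}
    horizon: Horizon
    discount_rate: float
    wtp: float

    def __post_init__(self):
        if self.subgroup not in ("dMMR", "pMMR"):
            raise ScenarioError(f"subgroup must be dMMR or pMMR, got {self.subgroup!r}")
        for arm in ARMS:
            if arm not in self.models:
                raise ScenarioError(f"survival_models.{arm}: missing")
            for curve in ("pfs", "os"):
                if curve not in self.models[arm]:
                    raise ScenarioError(f"survival_models.{arm}.{curve}: missing")
            if arm not in self.ae_profiles:
                raise ScenarioError(f"adverse_events.{arm}: missing")
        if not -1 < self.discount_rate < 1:
            raise ScenarioError("discount_rate out of range")
        if self.wtp <= 0:
            raise ScenarioError("wtp must be positive")

    def to_dict(self) -> dict:
        return {
            "subgroup": self.subgroup,
            "discount_rate": self.discount_rate,
            "wtp": self.wtp,
            "horizon": {
                "start_age": self.horizon.start_age,
                "end_age": self.horizon.end_age,
                "cycle_days": self.horizon.cycle_days,
            },
            "survival_models": {
                arm: {curve: m.to_dict() for curve, m in curves.items()}
                for arm, curves in self.models.items()
            },
            "costs": dataclasses.asdict(self.costs),
            "utilities": dataclasses.asdict(self.utilities),
            "adverse_events": {
                arm: [
                    {
                        "name": p.names[i],
                        "incidence": float(p.incidence[i]),
                        "cost": float(p.cost[i]),
                        "disutility": float(p.disutility[i]),
                    }
                    for i in range(len(p.names))
                ]
                for arm, p in self.ae_profiles.items()
            },
        }


_TOP_KEYS = {
    "subgroup",
    "discount_rate",
    "wtp",
    "horizon",
    "survival_models",
    "costs",
    "utilities",
    "adverse_events",
}


def _require(d: dict, key: str, path: str):
    if key not in d:
        raise ScenarioError(f"{path}.{key}: missing required field")
    return d[key]


def _check_unknown(d: dict, allowed, path: str):
    unknown = set(d) - set(allowed)
    if unknown:
        raise ScenarioError(f"{path}: unknown keys {sorted(unknown)}")


def _parse_ae(entries, path: str) -> AEProfile:
    if not isinstance(entries, list) or not entries:
        raise ScenarioError(f"{path}: must be a non-empty list")
    names, inc, cost, dis = [], [], [], []
    for i, e in enumerate(entries):
        _check_unknown(e, {"name", "incidence", "cost", "disutility"}, f"{path}[{i}]")
        names.append(_require(e, "name", f"{path}[{i}]"))
        inc.append(float(_require(e, "incidence", f"{path}[{i}]")))
        cost.append(float(_require(e, "cost", f"{path}[{i}]")))
        dis.append(float(_require(e, "disutility", f"{path}[{i}]")))
    return AEProfile(tuple(names), np.array(inc), np.array(cost), np.array(dis))


def scenario_from_dict(cfg: dict) -> Scenario:
    if not isinstance(cfg, dict):
        raise ScenarioError("scenario file must contain a mapping")
    _check_unknown(cfg, _TOP_KEYS, "scenario")
    missing = _TOP_KEYS - set(cfg)
    if missing:
        raise ScenarioError(f"scenario: missing required fields {sorted(missing)}")

    hz_cfg = cfg["horizon"]
    _check_unknown(hz_cfg, {"start_age", "end_age", "cycle_days"}, "horizon")
    horizon = Horizon(**hz_cfg)

    models = {}
    for arm in ARMS:
        arm_cfg = _require(cfg["survival_models"], arm, "survival_models")
        _check_unknown(arm_cfg, {"pfs", "os"}, f"survival_models.{arm}")
        models[arm] = {}
        for curve in ("pfs", "os"):
            m_cfg = _require(arm_cfg, curve, f"survival_models.{arm}")
            _check_unknown(m_cfg, {"family", "params", "time_unit"}, f"survival_models.{arm}.{curve}")
            try:
                models[arm][curve] = SurvivalModel.from_dict(m_cfg)
            except ValueError as exc:
                raise ScenarioError(f"survival_models.{arm}.{curve}: {exc}") from exc

    cost_fields = {f.name for f in dataclasses.fields(CostInputs)}
    _check_unknown(cfg["costs"], cost_fields, "costs")
    missing_costs = cost_fields - set(cfg["costs"])
    if missing_costs:
        raise ScenarioError(f"costs: missing required fields {sorted(missing_costs)}")
    try:
        costs = CostInputs(**cfg["costs"])
    except ValueError as exc:
        raise ScenarioError(f"costs: {exc}") from exc

    util_fields = {f.name for f in dataclasses.fields(UtilityInputs)}
    _check_unknown(cfg["utilities"], util_fields, "utilities")
    utilities = UtilityInputs(**cfg["utilities"])

    ae = {}
    for arm in ARMS:
        ae[arm] = _parse_ae(
            _require(cfg["adverse_events"], arm, "adverse_events"), f"adverse_events.{arm}"
        )

    return Scenario(
        subgroup=cfg["subgroup"],
        models=models,
        costs=costs,
        utilities=utilities,
        ae_profiles=ae,
        horizon=horizon,
        discount_rate=float(cfg["discount_rate"]),
        wtp=float(cfg["wtp"]),
    )


def load_scenario(path) -> Scenario:
    """Load and fully validate a YAML scenario file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return scenario_from_dict(cfg)


def save_scenario(scenario: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))


def load_builtin(name: str) -> Scenario:
    """Load a shipped scenario: ``dmmr`` or ``pmmr``."""
    name = name.lower()
    if name not in ("dmmr", "pmmr"):
        raise ValueError("builtin scenarios: 'dmmr' or 'pmmr'")
    ref = importlib.resources.files("dcpcea") / "configs" / f"{name}.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return scenario_from_dict(cfg)
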