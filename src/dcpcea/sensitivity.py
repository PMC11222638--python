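"""Deterministic and probabilistic sensitivity analyses.

One-way (tornado) analysis re-evaluates the ICER with each parameter at its
lower and upper bound (base +/- 20% unless stated otherwise) while holding
everything else fixed.  The probabilistic analysis draws all uncertain
parameters jointly - costs from gamma distributions, proportions and
utilities from beta distributions, body surface area from a normal, with
the checkpoint-inhibitor unit prices held fixed - using method-of-moments
hyper-parameters (mean = base value, SD = range width / (2 * 1.96), so the
+/-20% bounds approximate a 95% interval).  Survival-curve parameters carry
no published uncertainty distribution and are not varied.

Adverse-event unit costs and disutilities are common parameters: one draw
applies to both arms, while incidences are arm-specific.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costs import AEProfile, CostInputs, StrategyEvaluator, UtilityInputs, icer
from .scenario import Scenario

__all__ = [
    "ParameterSpec",
    "build_parameter_specs",
    "one_way_dsa",
    "sample_psa_draw",
    "run_psa",
    "PSAResult",
    "ceac",
    "threshold_price",
]

RANGE_FRACTION = 0.20  # plausible deviation from baseline
_Z95 = 1.959963984540054

# CostInputs fields varied in sensitivity analyses, with PSA distribution.
_COST_FIELD_DISTS = {
    "dostarlimab_per_10mg": "fixed",
    "pembrolizumab_per_mg": "fixed",
    "doxorubicin_per_10mg": "gamma",
    "paclitaxel_per_mg": "gamma",
    "carboplatin_per_50mg": "gamma",
    "imaging_per_scan": "gamma",
    "labs_per_cycle": "gamma",
    "administration_per_cycle": "gamma",
    "physician_visit_per_cycle": "gamma",
    "end_of_life": "gamma",
    "bsc_per_cycle": "gamma",
    "bsa": "normal",
    # the subsequent-therapy proportions carry no published uncertainty
    # distribution: varied in the one-way analysis only
    "subsequent_fraction_dcp": "fixed",
    "subsequent_fraction_cp": "fixed",
}


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input: bounds for DSA, distribution for PSA."""

    name: str
    base: float
    low: float
    high: float
    dist: str  # gamma | beta | normal | fixed

    def __post_init__(self):
        if self.dist not in ("gamma", "beta", "normal", "fixed"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: bounds must bracket the base value")
        if self.dist == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires values in [0, 1]")
        if self.dist == "gamma" and self.low < 0:
            raise ValueError(f"{self.name}: gamma requires non-negative values")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / (2.0 * _Z95)

    def sample(self, rng: np.random.Generator) -> float:
        m, sd = self.base, self.sd
        if self.dist == "fixed" or sd == 0:
            return m
        if self.dist == "normal":
            return float(rng.normal(m, sd))
        if self.dist == "gamma":
            shape = (m / sd) ** 2
            return float(rng.gamma(shape, m / shape))
        # beta, method of moments
        v = sd ** 2
        nu = m * (1 - m) / v - 1.0
        if nu <= 0:  # degenerate: variance too wide for a beta mean
            return float(np.clip(rng.normal(m, sd), 0.0, 1.0))
        return float(rng.beta(m * nu, (1 - m) * nu))


def _spec(name, base, dist, frac=RANGE_FRACTION):
    low, high = base * (1 - frac), base * (1 + frac)
    if dist == "beta":
        high = min(high, 1.0)
    return ParameterSpec(name, base, low, high, dist)


def build_parameter_specs(scenario: Scenario) -> list[ParameterSpec]:
    """All uncertain parameters of a scenario, in a stable order."""
    specs: list[ParameterSpec] = []
    for field, dist in _COST_FIELD_DISTS.items():
        specs.append(_spec(f"cost.{field}", getattr(scenario.costs, field), dist))
    specs.append(_spec("utility.u_pfs", scenario.utilities.u_pfs, "beta"))
    specs.append(_spec("utility.u_pd", scenario.utilities.u_pd, "beta"))
    ref = scenario.ae_profiles["DCP"]
    for i, name in enumerate(ref.names):
        specs.append(_spec(f"ae_cost.{name}", float(ref.cost[i]), "gamma"))
        specs.append(_spec(f"ae_disutility.{name}", float(ref.disutility[i]), "beta"))
    for arm in ("DCP", "CP"):
        prof = scenario.ae_profiles[arm]
        for i, name in enumerate(prof.names):
            specs.append(
                _spec(f"ae_incidence.{arm}.{name}", float(prof.incidence[i]), "beta")
            )
    return specs


def _apply_assignment(
    scenario: Scenario, assignment: dict
) -> tuple[CostInputs, UtilityInputs, AEProfile, AEProfile]:
    """Materialise modified inputs from a {spec name: value} mapping."""
    cost_kw = {}
    util_kw = {}
    ae = {arm: {
        "incidence": scenario.ae_profiles[arm].incidence.copy(),
        "cost": scenario.ae_profiles[arm].cost.copy(),
        "disutility": scenario.ae_profiles[arm].disutility.copy(),
    } for arm in ("DCP", "CP")}
    index = {n: i for i, n in enumerate(scenario.ae_profiles["DCP"].names)}

    for name, value in assignment.items():
        head, _, rest = name.partition(".")
        if head == "cost":
            cost_kw[rest] = value
        elif head == "utility":
            util_kw[rest] = float(np.clip(value, 0.0, 1.0))
        elif head == "ae_cost":
            for arm in ("DCP", "CP"):
                ae[arm]["cost"][index[rest]] = value
        elif head == "ae_disutility":
            for arm in ("DCP", "CP"):
                ae[arm]["disutility"][index[rest]] = value
        elif head == "ae_incidence":
            arm, _, ae_name = rest.partition(".")
            ae[arm]["incidence"][index[ae_name]] = float(np.clip(value, 0.0, 1.0))
        else:
            raise KeyError(f"unknown parameter {name!r}")

    prices = dataclasses.replace(scenario.costs, **cost_kw)
    utilities = dataclasses.replace(scenario.utilities, **util_kw)
    profiles = {
        arm: AEProfile(scenario.ae_profiles[arm].names, d["incidence"], d["cost"], d["disutility"])
        for arm, d in ae.items()
    }
    return prices, utilities, profiles["DCP"], profiles["CP"]


def _evaluate_assignment(evaluator: StrategyEvaluator, assignment: dict):
    prices, utilities, ae_dcp, ae_cp = _apply_assignment(evaluator.scenario, assignment)
    return evaluator.compare(prices, utilities, ae_dcp, ae_cp)


def one_way_dsa(
    scenario: Scenario,
    parameters: list[ParameterSpec] | None = None,
    evaluator: StrategyEvaluator | None = None,
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's bounds, sorted by spread."""
    evaluator = evaluator or StrategyEvaluator(scenario)
    parameters = parameters if parameters is not None else build_parameter_specs(scenario)
    rows = []
    base = evaluator.compare()
    for spec in parameters:
        lo = _evaluate_assignment(evaluator, {spec.name: spec.low}).icer
        hi = _evaluate_assignment(evaluator, {spec.name: spec.high}).icer
        rows.append(
            {
                "parameter": spec.name,
                "low_bound": spec.low,
                "high_bound": spec.high,
                "icer_low": lo,
                "icer_high": hi,
                "spread": abs(hi - lo),
            }
        )
    df = pd.DataFrame(rows).sort_values("spread", ascending=False, kind="stable")
    df.attrs["base_icer"] = base.icer
    return df.reset_index(drop=True)


def sample_psa_draw(parameters: list[ParameterSpec], rng: np.random.Generator) -> dict:
    """One joint draw of all uncertain parameters."""
    return {spec.name: spec.sample(rng) for spec in parameters}


@dataclass
class PSAResult:
    draws: pd.DataFrame  # delta_cost, delta_qaly per draw
    seed: int
    wtp_grid: np.ndarray

    def prob_cost_effective(self, wtp: float) -> float:
        nmb = self.draws["delta_qaly"] * wtp - self.draws["delta_cost"]
        return float((nmb >= 0).mean())

    @property
    def ceac(self) -> pd.DataFrame:
        return ceac(self.draws, self.wtp_grid)


def ceac(draws: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA draws."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dq = draws["delta_qaly"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    prob = [(dq * w - dc >= 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})


def run_psa(
    scenario: Scenario,
    n_draws: int = 1000,
    seed: int = 0,
    wtp_grid=None,
    evaluator: StrategyEvaluator | None = None,
) -> PSAResult:
    """Monte Carlo PSA: joint parameter draws, full model per draw."""
    evaluator = evaluator or StrategyEvaluator(scenario)
    specs = build_parameter_specs(scenario)
    rng = np.random.default_rng(seed)
    if wtp_grid is None:
        wtp_grid = np.arange(0, 300001, 10000, dtype=float)
    rows = []
    for _ in range(n_draws):
        res = _evaluate_assignment(evaluator, sample_psa_draw(specs, rng))
        rows.append((res.delta_cost, res.delta_qaly))
    draws = pd.DataFrame(rows, columns=["delta_cost", "delta_qaly"])
    return PSAResult(draws=draws, seed=seed, wtp_grid=np.asarray(wtp_grid, dtype=float))


def threshold_price(
    scenario: Scenario,
    target_icer: float | None = None,
    tol: float = 10.0,
    evaluator: StrategyEvaluator | None = None,
) -> float:
    """Dostarlimab price discount at which the ICER hits the target.

    Bisection on the multiplicative discount fraction in [0, 1]; the ICER is
    monotone decreasing in the discount, so the search converges.  Returns 0
    when the base-case ICER is already at or below the target.
    """
    evaluator = evaluator or StrategyEvaluator(scenario)
    target = scenario.wtp if target_icer is None else target_icer

    def icer_at(discount: float) -> float:
        prices = dataclasses.replace(
            scenario.costs,
            dostarlimab_per_10mg=scenario.costs.dostarlimab_per_10mg * (1.0 - discount),
        )
        return evaluator.compare(prices=prices).icer

    if icer_at(0.0) <= target:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        value = icer_at(mid)
        if abs(value - target) <= tol:
            return mid
        if value > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
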