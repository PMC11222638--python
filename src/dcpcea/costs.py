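"""Cost and utility accumulation over a cohort trace.

Implements the payer-perspective costing of the two strategies:

* DCP - dostarlimab 500 mg + carboplatin (AUC 5) + paclitaxel 175 mg/m2
  every 3 weeks for six cycles, then dostarlimab 1,000 mg every 6 weeks
  (every second cycle) for up to 3 years, given only while progression-free;
* CP - the same chemotherapy backbone without dostarlimab.

Doses scale with body surface area (paclitaxel, doxorubicin) or the Calvert
formula (carboplatin); imaging follows the trial calendar (6-weekly to week
25, 9-weekly to week 52, 12-weekly thereafter) and stops at progression.
After progression a fraction of each arm receives subsequent active therapy
(doxorubicin for six cycles then best supportive care, or pembrolizumab
until death), the rest best supportive care; everyone alive sees a
physician each cycle, and each death incurs a one-time end-of-life cost.
Grade >=3 adverse events enter as one-time first-cycle costs and QALY
losses.  All flows are discounted at mid-cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import (
    CohortTrace,
    Horizon,
    discount_factor,
    half_cycle_correct,
    pd_entrants,
    run_trace,
)
from .survival import SurvivalModel

__all__ = [
    "CostInputs",
    "UtilityInputs",
    "AEProfile",
    "StrategyOutcome",
    "CEResult",
    "drug_cost_per_administration",
    "imaging_scan_cycles",
    "imaging_cost_schedule",
    "ae_burden",
    "progression_state_cost_per_cycle",
    "end_of_life_cost",
    "StrategyEvaluator",
    "evaluate_strategy",
    "icer",
]

INDUCTION_CYCLES = 6
MAINTENANCE_INTERVAL = 2  # dostarlimab 1,000 mg every 6 weeks = every 2nd cycle
MAINTENANCE_MAX_MONTHS = 36.0
DOXORUBICIN_CYCLES = 6

# (unit size in mg, CostInputs price attribute)
_DRUGS = {
    "dostarlimab": (10.0, "dostarlimab_per_10mg"),
    "pembrolizumab": (1.0, "pembrolizumab_per_mg"),
    "doxorubicin": (10.0, "doxorubicin_per_10mg"),
    "paclitaxel": (1.0, "paclitaxel_per_mg"),
    "carboplatin": (50.0, "carboplatin_per_50mg"),
}


@dataclass(frozen=True)
class CostInputs:
    """Unit prices (2024 USD) and per-cycle resource costs."""

    dostarlimab_per_10mg: float = 233.258
    pembrolizumab_per_mg: float = 55.730
    doxorubicin_per_10mg: float = 3.279
    paclitaxel_per_mg: float = 0.108
    carboplatin_per_50mg: float = 3.599
    imaging_per_scan: float = 651.81
    labs_per_cycle: float = 359.16
    administration_per_cycle: float = 149.69
    physician_visit_per_cycle: float = 164.04
    end_of_life: float = 37590.23
    bsc_per_cycle: float = 1300.61
    bsa: float = 1.84  # m2
    gfr: float = 70.0  # mL/min, for the Calvert carboplatin dose
    carboplatin_auc: float = 5.0
    subsequent_fraction_dcp: float = 0.283
    subsequent_fraction_cp: float = 0.585
    doxorubicin_split: float = 0.5  # share of subsequent therapy on doxorubicin
    # pembrolizumab continues until death unless a cap (months) is set
    pembrolizumab_cap_months: float | None = None
    whole_vial: bool = False

    def __post_init__(self):
        for name in ("subsequent_fraction_dcp", "subsequent_fraction_cp", "doxorubicin_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def subsequent_fraction(self, arm: str) -> float:
        return {"DCP": self.subsequent_fraction_dcp, "CP": self.subsequent_fraction_cp}[arm]


@dataclass(frozen=True)
class UtilityInputs:
    u_pfs: float = 0.817
    u_pd: float = 0.779
    u_death: float = 0.0

    def __post_init__(self):
        for name in ("u_pfs", "u_pd", "u_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class AEProfile:
    """Grade >=3 adverse events: per-arm incidence with one-time cost and
    disutility, all applied in the first model cycle."""

    names: tuple
    incidence: np.ndarray
    cost: np.ndarray
    disutility: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "incidence", np.asarray(self.incidence, dtype=float))
        object.__setattr__(self, "cost", np.asarray(self.cost, dtype=float))
        object.__setattr__(self, "disutility", np.asarray(self.disutility, dtype=float))
        n = len(self.names)
        if not (len(self.incidence) == len(self.cost) == len(self.disutility) == n):
            raise ValueError("AE arrays must have equal length")
        if np.any((self.incidence < 0) | (self.incidence > 1)):
            raise ValueError("AE incidences must be in [0, 1]")


def ae_burden(profile: AEProfile) -> tuple[float, float]:
    """Expected one-time (cost, QALY loss) of the adverse-event profile."""
    return (
        float(np.dot(profile.incidence, profile.cost)),
        float(np.dot(profile.incidence, profile.disutility)),
    )


def drug_cost_per_administration(
    drug: str, prices: CostInputs, dose_mg: float | None = None
) -> float:
    """Cost of one administration.

    Flat doses default to the regimen (dostarlimab 500 mg induction,
    pembrolizumab 200 mg); BSA-scaled and Calvert doses are computed from
    ``prices.bsa``/``prices.gfr``.  Fractional units are billed pro-rata
    unless ``prices.whole_vial`` is set.
    """
    if drug not in _DRUGS:
        raise ValueError(f"unknown drug {drug!r}")
    if dose_mg is None:
        dose_mg = {
            "dostarlimab": 500.0,
            "pembrolizumab": 200.0,
            "paclitaxel": 175.0 * prices.bsa,
            "doxorubicin": 60.0 * prices.bsa,
            "carboplatin": prices.carboplatin_auc * (prices.gfr + 25.0),
        }[drug]
    unit_mg, attr = _DRUGS[drug]
    units = dose_mg / unit_mg
    if prices.whole_vial:
        units = math.ceil(units - 1e-9)
    return units * getattr(prices, attr)


def imaging_scan_cycles(horizon: Horizon | None = None) -> np.ndarray:
    """Model cycles (1-based) containing a surveillance scan.

    Scans fall at weeks 6, 12, 18, 24 (6-weekly until week 25), 33, 42, 51
    (9-weekly until week 52) and every 12 weeks thereafter; with 3-week
    cycles the scan at week w lands in cycle w/3.
    """
    horizon = horizon or Horizon()
    max_week = horizon.n_cycles * 3
    weeks = list(range(6, 25, 6)) + list(range(33, 52, 9)) + list(range(63, max_week + 1, 12))
    cycles = np.array([math.ceil(w / 3) for w in weeks])
    return cycles[cycles <= horizon.n_cycles]


def imaging_cost_schedule(cycle: int, prices: CostInputs | None = None,
                          horizon: Horizon | None = None) -> float:
    """Imaging cost charged in a given cycle (0 off-schedule)."""
    if cycle < 1:
        raise ValueError("cycles are 1-based")
    prices = prices or CostInputs()
    return prices.imaging_per_scan if cycle in set(imaging_scan_cycles(horizon)) else 0.0


def maintenance_cycles(horizon: Horizon | None = None) -> np.ndarray:
    """DCP maintenance dosing cycles: every 2nd cycle after induction,
    through cycle floor(36 months / cycle length)."""
    horizon = horizon or Horizon()
    last = int(MAINTENANCE_MAX_MONTHS // horizon.cycle_months)
    return np.arange(INDUCTION_CYCLES + 1, last + 1, MAINTENANCE_INTERVAL)


def progression_state_cost_per_cycle(arm: str, cycles_since: int, prices: CostInputs) -> float:
    """Expected cost per person-cycle in PD, by time since progression.

    The subsequent-therapy fraction splits between doxorubicin (six cycles,
    then best supportive care) and pembrolizumab (every 3 weeks until death,
    or until the optional cap); the remainder receives best supportive care
    throughout.  Active-drug cycles add administration and laboratory fees
    (these are charged in every treatment cycle); every PD cycle includes a
    physician visit.
    """
    if arm not in ("DCP", "CP"):
        raise ValueError(f"unknown arm {arm!r}")
    if cycles_since < 0:
        raise ValueError("cycles_since must be >= 0")
    p = prices.subsequent_fraction(arm)
    f_dox = prices.doxorubicin_split
    on_treatment = prices.administration_per_cycle + prices.labs_per_cycle
    if prices.pembrolizumab_cap_months is None:
        pem_cap_cycles = math.inf
    else:
        pem_cap_cycles = int(prices.pembrolizumab_cap_months // Horizon().cycle_months)
    if cycles_since < DOXORUBICIN_CYCLES:
        dox = drug_cost_per_administration("doxorubicin", prices) + on_treatment
    else:
        dox = prices.bsc_per_cycle
    if cycles_since < pem_cap_cycles:
        pem = drug_cost_per_administration("pembrolizumab", prices) + on_treatment
    else:
        pem = prices.bsc_per_cycle
    return (
        p * (f_dox * dox + (1.0 - f_dox) * pem)
        + (1.0 - p) * prices.bsc_per_cycle
        + prices.physician_visit_per_cycle
    )


def end_of_life_cost(trace: CohortTrace, prices: CostInputs, discount_rate: float) -> float:
    """Discounted one-time terminal-care cost over all new deaths."""
    disc = discount_factor(trace.mid_cycle_years(), discount_rate)
    return float(np.dot(trace.new_deaths(), disc)) * prices.end_of_life


@dataclass(frozen=True)
class StrategyOutcome:
    cost: float
    qaly: float


@dataclass(frozen=True)
class CEResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str | None = None


def icer(intervention: StrategyOutcome, comparator: StrategyOutcome) -> CEResult:
    """Incremental cost-effectiveness of intervention versus comparator."""
    dc = intervention.cost - comparator.cost
    dq = intervention.qaly - comparator.qaly
    if dq == 0:
        label = None if dc == 0 else "undefined"
        return CEResult(dc, dq, None, label)
    ratio = dc / dq
    label = None
    if dc < 0 and dq > 0:
        label = "dominant"
    elif dc > 0 and dq < 0:
        label = "dominated"
    return CEResult(dc, dq, ratio, label)


def _pd_age_weights(trace: CohortTrace, disc: np.ndarray) -> np.ndarray:
    """Discounted person-cycles in PD by cycles-since-progression.

    PD occupancy is decomposed into entry-cycle vintages (deaths assumed to
    hit all vintages proportionally); returns A with A[s] = discounted
    person-cycles spent in PD at age s, so any per-cycle PD cost profile
    c(s) prices out as A . c.
    """
    n = trace.n_cycles
    e = pd_entrants(trace)
    pd_occ = trace.pd
    vint = np.zeros(n)
    A = np.zeros(n)
    for k in range(1, n + 1):
        prev = vint[: k - 1].sum()
        target_old = max(pd_occ[k] - e[k - 1], 0.0)
        if prev > 0:
            vint[: k - 1] *= target_old / prev
        vint[k - 1] = e[k - 1]
        total = vint[:k].sum()
        if total > 0:
            vint[:k] *= pd_occ[k] / total
        # ages s = k-1-j for entry cycle j+1 -> reversed slice
        A[:k] += disc[k - 1] * vint[:k][::-1]
    return A


class StrategyEvaluator:
    """Per-arm evaluator with precomputed discounted occupancy weights.

    The cohort trace depends only on the survival models and horizon, so it
    is computed once; every cost and utility component then reduces to a dot
    product with cached weights, which makes the probabilistic sensitivity
    analysis (thousands of re-evaluations) cheap.
    """

    def __init__(self, scenario, method: str = "partitioned_survival"):
        self.scenario = scenario
        self.horizon = scenario.horizon
        self.rate = scenario.discount_rate
        self._arm: dict[str, dict] = {}
        for arm in ("DCP", "CP"):
            models = scenario.models[arm]
            trace = run_trace(models["pfs"], models["os"], self.horizon, method=method)
            self._arm[arm] = self._precompute(trace)

    def _precompute(self, trace: CohortTrace) -> dict:
        hz = self.horizon
        n = hz.n_cycles
        disc = discount_factor(trace.mid_cycle_years(), self.rate)
        mean_occ_pfs = half_cycle_correct(trace.pfs)
        mean_occ_pd = half_cycle_correct(trace.pd)
        pfs_start = trace.pfs[:-1]  # dosing happens at the start of a cycle
        cycles = np.arange(1, n + 1)
        ind = cycles <= INDUCTION_CYCLES
        maint = np.isin(cycles, maintenance_cycles(hz))
        scans = np.isin(cycles, imaging_scan_cycles(hz))
        return {
            "trace": trace,
            "disc": disc,
            "w_induction": float(np.dot(pfs_start[ind], disc[ind])),
            "w_maintenance": float(np.dot(pfs_start[maint], disc[maint])),
            "w_imaging": float(np.dot(pfs_start[scans], disc[scans])),
            "w_visit_pfs": float(np.dot(mean_occ_pfs, disc)),
            "w_eol": float(np.dot(trace.new_deaths(), disc)),
            "pd_age": _pd_age_weights(trace, disc),
            "q_pfs": float(np.dot(mean_occ_pfs, disc)) * hz.cycle_years,
            "q_pd": float(np.dot(mean_occ_pd, disc)) * hz.cycle_years,
            "disc0": float(disc[0]),
        }

    def trace(self, arm: str) -> CohortTrace:
        return self._arm[arm]["trace"]

    def _pd_cost_vector(self, arm: str, prices: CostInputs, n: int) -> np.ndarray:
        s = np.arange(n)
        p = prices.subsequent_fraction(arm)
        f_dox = prices.doxorubicin_split
        on_treatment = prices.administration_per_cycle + prices.labs_per_cycle
        if prices.pembrolizumab_cap_months is None:
            pem_cap = n
        else:
            pem_cap = int(prices.pembrolizumab_cap_months // self.horizon.cycle_months)
        dox_cost = drug_cost_per_administration("doxorubicin", prices) + on_treatment
        pem_cost = drug_cost_per_administration("pembrolizumab", prices) + on_treatment
        dox = np.where(s < DOXORUBICIN_CYCLES, dox_cost, prices.bsc_per_cycle)
        pem = np.where(s < pem_cap, pem_cost, prices.bsc_per_cycle)
        return (
            p * (f_dox * dox + (1.0 - f_dox) * pem)
            + (1.0 - p) * prices.bsc_per_cycle
            + prices.physician_visit_per_cycle
        )

    def evaluate(
        self,
        arm: str,
        prices: CostInputs | None = None,
        utilities: UtilityInputs | None = None,
        ae: AEProfile | None = None,
    ) -> StrategyOutcome:
        sc = self.scenario
        prices = prices if prices is not None else sc.costs
        utilities = utilities if utilities is not None else sc.utilities
        ae = ae if ae is not None else sc.ae_profiles[arm]
        w = self._arm[arm]

        chemo = drug_cost_per_administration("paclitaxel", prices) + drug_cost_per_administration(
            "carboplatin", prices
        )
        per_treatment_cycle = prices.administration_per_cycle + prices.labs_per_cycle
        induction_dose = chemo + per_treatment_cycle
        if arm == "DCP":
            induction_dose += drug_cost_per_administration("dostarlimab", prices, dose_mg=500.0)
            maintenance_dose = (
                drug_cost_per_administration("dostarlimab", prices, dose_mg=1000.0)
                + per_treatment_cycle
            )
        else:
            maintenance_dose = 0.0

        ae_cost, ae_dis = ae_burden(ae)
        n = self.horizon.n_cycles
        cost = (
            w["w_induction"] * induction_dose
            + w["w_maintenance"] * maintenance_dose
            + w["w_imaging"] * prices.imaging_per_scan
            + w["w_visit_pfs"] * prices.physician_visit_per_cycle
            + float(np.dot(w["pd_age"], self._pd_cost_vector(arm, prices, n)))
            + w["w_eol"] * prices.end_of_life
            + ae_cost * w["disc0"]
        )
        qaly = (
            utilities.u_pfs * w["q_pfs"]
            + utilities.u_pd * w["q_pd"]
            - ae_dis * w["disc0"]
        )
        return StrategyOutcome(cost=cost, qaly=qaly)

    def compare(
        self,
        prices: CostInputs | None = None,
        utilities: UtilityInputs | None = None,
        ae_dcp: AEProfile | None = None,
        ae_cp: AEProfile | None = None,
    ) -> CEResult:
        dcp = self.evaluate("DCP", prices, utilities, ae_dcp)
        cp = self.evaluate("CP", prices, utilities, ae_cp)
        return icer(dcp, cp)


def evaluate_strategy(scenario, arm: str, method: str = "partitioned_survival") -> StrategyOutcome:
    """One-shot evaluation of a single arm under a scenario's base case."""
    return StrategyEvaluator(scenario, method=method).evaluate(arm)
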