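"""Three-state cohort engine: PFS, progressed disease (PD), death.

The cohort enters at age 64 in PFS and is followed in 3-week cycles until
age 82 (313 cycles of 21 days; one month is taken as 30.4375 days).  State
occupancy is derived from the fitted PFS and OS curves, by default with the
partitioned-survival construction (PFS occupancy is the area under the PFS
curve, death the area above the OS curve, PD the band in between); a
state-transition mode driven by per-cycle conditional-exit probabilities is
retained behind a flag and yields the same occupancy when the curves do not
cross.  Crossing curves (S_PFS > S_OS) are capped at S_OS with a warning,
not treated as an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import SurvivalModel

__all__ = [
    "DAYS_PER_MONTH",
    "Horizon",
    "CohortTrace",
    "discount_factor",
    "transition_probability",
    "run_trace",
    "half_cycle_correct",
]

DAYS_PER_MONTH = 30.4375  # calendar average; 12 months = 365.25 days


@dataclass(frozen=True)
class Horizon:
    """Model time frame, defaulting to ages 64-82 in 21-day cycles."""

    start_age: float = 64.0
    end_age: float = 82.0
    cycle_days: float = 21.0

    def __post_init__(self):
        if self.end_age <= self.start_age or self.cycle_days <= 0:
            raise ValueError("invalid horizon")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    @property
    def n_cycles(self) -> int:
        # final partial cycle dropped: 18 years of 21-day cycles -> 313
        return int((self.end_age - self.start_age) * 365.25 // self.cycle_days)

    def boundary_times(self) -> np.ndarray:
        """Cycle-boundary times in months, length n_cycles + 1."""
        return np.arange(self.n_cycles + 1) * self.cycle_months


def discount_factor(t_years, rate: float):
    """Present-value factor (1 + rate)^(-t)."""
    if rate <= -1:
        raise ValueError("rate must exceed -1")
    return (1.0 + rate) ** (-np.asarray(t_years, dtype=float))


def transition_probability(model: SurvivalModel, t: float, u: float) -> float:
    """Per-cycle exit probability 1 - S(t)/S(t-u) for the cycle ending at t.

    For a Weibull S(t) = exp(-lambda t^gamma) this reduces to the familiar
    1 - exp[lambda (t-u)^gamma - lambda t^gamma]; the conditional-survival
    ratio is the family-agnostic generalisation.  An exhausted cohort
    (S(t-u) = 0) transitions with probability 1.
    """
    if not 0 <= u <= t:
        raise ValueError("need 0 <= u <= t")
    if u == 0:
        return 0.0
    s_prev = float(model.sf(t - u))
    if s_prev <= 0.0:
        return 1.0
    return float(np.clip(1.0 - float(model.sf(t)) / s_prev, 0.0, 1.0))


@dataclass
class CohortTrace:
    """Occupancy at cycle boundaries plus per-cycle accrual accumulators.

    ``pfs``, ``pd``, ``dead`` have length n_cycles + 1 (boundary 0 is model
    entry).  Cost and QALY increments are filled in by the cost-utility
    layer; the engine itself only guarantees the occupancy invariants.
    """

    horizon: Horizon
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    curves_crossed: bool = False

    def __post_init__(self):
        total = self.pfs + self.pd + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise AssertionError("state occupancy must sum to 1")
        if np.any(np.diff(self.dead) < -1e-12):
            raise AssertionError("death occupancy must be non-decreasing")
        if np.any(np.diff(self.pfs) > 1e-12):
            raise AssertionError("PFS occupancy must be non-increasing")

    @property
    def n_cycles(self) -> int:
        return self.horizon.n_cycles

    def times_months(self) -> np.ndarray:
        return self.horizon.boundary_times()

    def mid_cycle_years(self) -> np.ndarray:
        """Discounting times: the midpoint of each cycle, in years."""
        return (np.arange(self.n_cycles) + 0.5) * self.horizon.cycle_years

    def new_deaths(self) -> np.ndarray:
        return np.diff(self.dead)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles + 1),
                "time_months": self.times_months(),
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
            }
        )


def half_cycle_correct(occupancy: np.ndarray, half_cycle: bool = True) -> np.ndarray:
    """Per-cycle state time (in cycles) from boundary occupancy.

    With the life-table correction each cycle accrues the mean of its start
    and end occupancy; without it, the start-of-cycle occupancy.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape[0] < 2:
        raise ValueError("need at least 2 boundaries")
    if half_cycle:
        return 0.5 * (occupancy[:-1] + occupancy[1:])
    return occupancy[:-1]


def run_trace(
    pfs_model: SurvivalModel,
    os_model: SurvivalModel,
    horizon: Horizon | None = None,
    method: str = "partitioned_survival",
) -> CohortTrace:
    """Propagate the cohort over the horizon and return its trace."""
    horizon = horizon or Horizon()
    t = horizon.boundary_times()
    s_pfs = pfs_model.sf(t)
    s_os = os_model.sf(t)
    crossed = bool(np.any(s_pfs > s_os + 1e-12))
    if crossed:
        warnings.warn(
            "PFS curve exceeds OS curve; capping PFS occupancy at OS",
            RuntimeWarning,
            stacklevel=2,
        )

    if method == "partitioned_survival":
        pfs = np.minimum(s_pfs, s_os)
        dead = 1.0 - s_os
        pd_ = 1.0 - pfs - dead
    elif method == "state_transition":
        n = horizon.n_cycles
        pfs = np.empty(n + 1)
        pd_ = np.empty(n + 1)
        dead = np.empty(n + 1)
        pfs[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
        s_pfs_cap = np.minimum(s_pfs, s_os)
        for k in range(1, n + 1):
            # conditional exit probabilities over this cycle
            p_exit_pfs = 1.0 - (s_pfs_cap[k] / s_pfs_cap[k - 1] if s_pfs_cap[k - 1] > 0 else 0.0)
            exits = pfs[k - 1] * np.clip(p_exit_pfs, 0.0, 1.0)
            new_dead = s_os[k - 1] - s_os[k]
            alive = pfs[k - 1] + pd_[k - 1]
            d_pfs = new_dead * (pfs[k - 1] / alive) if alive > 0 else 0.0
            # deaths from PFS cannot exceed total PFS exits
            d_pfs = min(d_pfs, exits)
            to_pd = exits - d_pfs
            if to_pd < 0:  # pragma: no cover - clamped above
                warnings.warn("negative PFS->PD flow clamped to 0", RuntimeWarning)
                to_pd = 0.0
            d_pd = new_dead - d_pfs
            if d_pd < 0:
                warnings.warn("negative PD->death flow clamped to 0", RuntimeWarning)
                d_pfs = new_dead
                d_pd = 0.0
                to_pd = max(exits - d_pfs, 0.0)
            pfs[k] = pfs[k - 1] - exits
            pd_[k] = pd_[k - 1] + to_pd - d_pd
            dead[k] = dead[k - 1] + new_dead
        # numerical guard
        pd_ = np.clip(pd_, 0.0, 1.0)
        total = pfs + pd_ + dead
        pd_ -= total - 1.0
        pd_ = np.clip(pd_, 0.0, None)
        dead = 1.0 - pfs - pd_
    else:
        raise ValueError(f"unknown method {method!r}")

    return CohortTrace(
        horizon=horizon,
        pfs=pfs,
        pd=np.clip(pd_, 0.0, 1.0),
        dead=dead,
        curves_crossed=crossed,
    )


def pd_entrants(trace: CohortTrace) -> np.ndarray:
    """New entrants into PD during each cycle (length n_cycles).

    Partitioned occupancy does not identify which state deaths come from;
    deaths within a cycle are split between PFS and PD in proportion to
    start-of-cycle occupancy, and the PFS decrement not explained by its
    death share enters PD.
    """
    pfs, pd_, dead = trace.pfs, trace.pd, trace.dead
    new_dead = np.diff(dead)
    alive = pfs[:-1] + pd_[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(alive > 0, pfs[:-1] / np.maximum(alive, 1e-300), 0.0)
    d_pfs = np.minimum(new_dead * share, pfs[:-1] - pfs[1:])
    return np.clip((pfs[:-1] - pfs[1:]) - d_pfs, 0.0, None)
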