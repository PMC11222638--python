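"""Synthetic Kaplan-Meier curves and pseudo-IPD reconstruction.

Published trial figures only expose the product-limit curve and a
numbers-at-risk table.  This module (a) generates exactly that artifact from
a known parametric model, so the digitize-and-reconstruct pipeline can be
exercised without any image processing, and (b) reconstructs
pseudo-individual-patient-data from such curve coordinates by interval
allocation: within each interval between at-risk times, the number of events
follows from the survival drop scaled by the at-risk counts and the
remainder of the at-risk decrement is treated as censoring spread evenly
across the interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import SurvivalModel

__all__ = ["KMDataset", "PseudoIPD", "generate_synthetic_km", "reconstruct_ipd"]


class KMValidationError(ValueError):
    """KM inputs violate product-limit invariants."""


@dataclass(frozen=True)
class PseudoIPD:
    """Patient-level (time, event) records; time in months."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        if len(self.time) != len(self.event):
            raise ValueError("time/event length mismatch")
        if np.any(self.time <= 0):
            raise ValueError("times must be > 0")

    def __len__(self):
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy())


@dataclass(frozen=True)
class KMDataset:
    """Digitized-curve stand-in: coordinates plus a numbers-at-risk table."""

    coord_time: np.ndarray
    coord_surv: np.ndarray
    at_risk_time: np.ndarray
    at_risk_n: np.ndarray
    n_total: int
    arm_label: str = ""

    def __post_init__(self):
        for name in ("coord_time", "coord_surv", "at_risk_time"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "at_risk_n", np.asarray(self.at_risk_n, dtype=int))
        self.validate()

    def validate(self):
        t, s = self.coord_time, self.coord_surv
        if len(t) < 2 or t[0] != 0 or s[0] != 1.0:
            raise KMValidationError("coordinates must start at (0, 1.0)")
        if np.any(np.diff(t) < 0):
            raise KMValidationError("coordinate times must be sorted")
        if np.any(np.diff(s) > 1e-12):
            raise KMValidationError("survival must be non-increasing")
        if np.any((s < 0) | (s > 1)):
            raise KMValidationError("survival outside [0, 1]")
        if len(self.at_risk_time) < 2:
            raise KMValidationError("need at least 2 at-risk times")
        if np.any(np.diff(self.at_risk_time) <= 0):
            raise KMValidationError("at-risk times must be increasing")
        if np.any(np.diff(self.at_risk_n) > 0):
            raise KMValidationError("numbers at risk must be non-increasing")
        if self.at_risk_n[0] != self.n_total:
            raise KMValidationError("at_risk[0] must equal n_total")

    def surv_at(self, times) -> np.ndarray:
        """Survival linearly interpolated at arbitrary times (digitized
        coordinates rarely land exactly on at-risk boundaries)."""
        return np.interp(times, self.coord_time, self.coord_surv)

    # -- text round trip (coords CSV + at-risk CSV + JSON sidecar) ---------

    def write(self, stem):
        stem = Path(stem)
        pd.DataFrame({"time": self.coord_time, "survival": self.coord_surv}).to_csv(
            stem.with_suffix(".coords.csv"), index=False
        )
        pd.DataFrame({"time": self.at_risk_time, "n_at_risk": self.at_risk_n}).to_csv(
            stem.with_suffix(".atrisk.csv"), index=False
        )
        stem.with_suffix(".json").write_text(
            json.dumps({"n_total": int(self.n_total), "arm_label": self.arm_label})
        )

    @classmethod
    def read(cls, stem) -> "KMDataset":
        stem = Path(stem)
        coords = pd.read_csv(stem.with_suffix(".coords.csv"))
        atrisk = pd.read_csv(stem.with_suffix(".atrisk.csv"))
        meta = json.loads(stem.with_suffix(".json").read_text())
        return cls(
            coords["time"].to_numpy(),
            coords["survival"].to_numpy(),
            atrisk["time"].to_numpy(),
            atrisk["n_at_risk"].to_numpy(),
            n_total=meta["n_total"],
            arm_label=meta.get("arm_label", ""),
        )


def generate_synthetic_km(
    model: SurvivalModel,
    n: int,
    censor_rate: float,
    admin_cutoff: float,
    grid_step: float = 1.0,
    seed: int = 0,
    arm_label: str = "",
) -> tuple[KMDataset, PseudoIPD]:
    """Simulate a trial arm and return its published-figure artifacts.

    Event times are drawn from ``model``; censoring is the minimum of an
    exponential(``censor_rate``) dropout time and the administrative cutoff.
    The product-limit curve is sampled on a regular grid with numbers at
    risk at the same grid times.  Identical seeds give identical output.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if admin_cutoff <= 0:
        raise ValueError("admin_cutoff must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    t_event = model.rvs(n, rng)
    if censor_rate > 0:
        t_drop = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, admin_cutoff)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # guard against zero observed times from pathological models
    time = np.maximum(time, 1e-9)
    ipd = PseudoIPD(time, event)

    grid = np.arange(0.0, admin_cutoff + grid_step / 2, grid_step)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = np.array([(time >= g).sum() for g in grid])
    km = KMDataset(
        coord_time=grid,
        coord_surv=surv,
        at_risk_time=grid,
        at_risk_n=at_risk,
        n_total=n,
        arm_label=arm_label,
    )
    return km, ipd


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of ``total`` into integer shares."""
    if total <= 0 or weights.sum() <= 0:
        out = np.zeros(len(weights), dtype=int)
        if total > 0 and len(weights):
            out[len(weights) // 2] = total
        return out
    shares = total * weights / weights.sum()
    base = np.floor(shares).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:rem]] += 1
    return base


def reconstruct_ipd(km: KMDataset) -> PseudoIPD:
    """Rebuild pseudo-IPD from digitized coordinates and at-risk counts.

    Within each at-risk interval [t_j, t_{j+1}) with boundary survival
    S_j, S_{j+1} and counts n_j, n_{j+1}, the event count solves the
    product-limit drop with censoring assumed mid-interval on average:
    d_j = (1 - r) (n_j + n_{j+1}) / (1 + r), r = S_{j+1}/S_j, and the
    censor count is the at-risk decrement not explained by events.  Events
    are timed at the digitized drops (shares by largest remainder),
    censorings evenly spaced.  Deterministic; no randomisation.
    """
    km.validate()
    tb = km.at_risk_time
    nb = km.at_risk_n
    sb = km.surv_at(tb)

    times: list[float] = []
    events: list[int] = []

    ct, cs = km.coord_time, km.coord_surv
    drops = np.maximum(np.concatenate([[0.0], -np.diff(cs)]), 0.0)
    # a drop observed at a coordinate happened somewhere since the previous
    # one; date events at the gap midpoint to avoid a systematic late shift
    prev_ct = np.concatenate([[ct[0]], ct[:-1]])
    event_time = 0.5 * (prev_ct + ct)

    for j in range(len(tb) - 1):
        t0, t1 = tb[j], tb[j + 1]
        n0, n1 = int(nb[j]), int(nb[j + 1])
        removed = n0 - n1
        if removed <= 0:
            continue
        s0, s1 = sb[j], sb[j + 1]
        if s0 <= 0:
            d = 0
        else:
            r = max(min(s1 / s0, 1.0), 0.0)
            d = int(round((1.0 - r) * (n0 + n1) / (1.0 + r)))
        d = min(max(d, 0), removed)
        c = removed - d
        in_int = (ct > t0) & (ct <= t1)
        ev_counts = _allocate(d, drops[in_int])
        for tt, k in zip(event_time[in_int], ev_counts):
            times.extend([float(tt)] * int(k))
            events.extend([1] * int(k))
        if d > 0 and not in_int.any():
            times.extend([float(0.5 * (t0 + t1))] * d)
            events.extend([1] * d)
        for i in range(c):
            times.append(float(t0 + (i + 0.5) / c * (t1 - t0)))
            events.append(0)

    # tail: everyone still at risk at the last at-risk time
    n_last = int(nb[-1])
    if n_last > 0:
        t_last = tb[-1]
        s_last = sb[-1]
        in_tail = ct > t_last
        if in_tail.any() and s_last > 0:
            s_end = cs[-1]
            d_tail = int(round(n_last * (1.0 - s_end / s_last)))
            d_tail = min(max(d_tail, 0), n_last)
            ev_counts = _allocate(d_tail, drops[in_tail])
            for tt, k in zip(event_time[in_tail], ev_counts):
                times.extend([float(tt)] * int(k))
                events.extend([1] * int(k))
            n_last -= d_tail
            t_last = max(t_last, ct[-1])
        times.extend([float(max(t_last, 1e-9))] * n_last)
        events.extend([0] * n_last)

    time = np.asarray(times, dtype=float)
    order = np.argsort(time, kind="stable")
    return PseudoIPD(np.maximum(time[order], 1e-9), np.asarray(events)[order])


def km_curve(ipd: PseudoIPD, times) -> np.ndarray:
    """Product-limit survival of an IPD sample evaluated at given times."""
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    return kmf.survival_function_at_times(np.asarray(times, dtype=float)).to_numpy()
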