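"""Parametric survival families for extrapolating trial PFS/OS curves.

Seven families are supported: exponential, Weibull, Gompertz, gamma,
generalized gamma (Prentice mu/sigma/Q form), log-logistic and log-normal.
Times are in months throughout.

The generalized gamma is evaluated in log-space so that extreme shape
parameters (|Q| > 30, as occur in fitted overall-survival models) neither
overflow nor produce NaN anywhere on [0, 600] months: the incomplete-gamma
argument ``x = Q^-2 * exp(Q*w)`` is kept as ``log x`` and the regularized
incomplete gamma is replaced by its leading small-x series once ``log x``
leaves the representable range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "SurvivalModel",
    "FitResult",
    "ParameterError",
    "DegenerateDataError",
    "FitError",
    "survival_function",
    "fit_parametric",
    "select_best",
]

# Enum order doubles as the deterministic tie-break order in select_best.
FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "gamma",
    "generalized_gamma",
    "log_logistic",
    "log_normal",
)

_PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("lambda", "gamma"),
    "gompertz": ("shape", "rate"),
    "gamma": ("shape", "rate"),
    "generalized_gamma": ("mu", "sigma", "Q"),
    "log_logistic": ("shape", "scale"),
    "log_normal": ("meanlog", "sdlog"),
}

# Parameters that must be strictly positive; the rest are unconstrained reals.
_POSITIVE = {
    "exponential": ("rate",),
    "weibull": ("lambda", "gamma"),
    "gompertz": ("rate",),
    "gamma": ("shape", "rate"),
    "generalized_gamma": ("sigma",),
    "log_logistic": ("shape", "scale"),
    "log_normal": ("sdlog",),
}


class ParameterError(ValueError):
    """Parameters violate the family's domain constraints."""


class DegenerateDataError(ValueError):
    """Input data cannot identify the model (e.g. zero events)."""


class FitError(RuntimeError):
    """Maximum-likelihood optimisation failed to converge."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class SurvivalModel:
    """A parametric survival curve S(t), t in months.

    Weibull uses the (lambda, gamma) rate/shape form S(t) = exp(-lambda *
    t**gamma), matching the per-cycle transition-probability formula used by
    the cohort engine.  The generalized gamma uses the Prentice (mu, sigma,
    Q) form: with w = (ln t - mu)/sigma and a = Q^-2, S(t) is the upper
    (Q > 0) or lower (Q < 0) regularized incomplete-gamma tail at
    (a, a*exp(Q*w)); Q = 0 is the log-normal limit.
    """

    family: str
    params: dict = field(default_factory=dict)
    time_unit: str = "months"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        names = _PARAM_NAMES[self.family]
        missing = set(names) - set(self.params)
        extra = set(self.params) - set(names)
        if missing or extra:
            raise ParameterError(
                f"{self.family} expects parameters {names}; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name in _POSITIVE[self.family]:
            if not self.params[name] > 0:
                raise ParameterError(
                    f"{self.family} parameter {name!r} must be > 0, "
                    f"got {self.params[name]}"
                )
        for name, value in self.params.items():
            if not math.isfinite(value):
                raise ParameterError(f"non-finite parameter {name}={value}")

    @property
    def n_params(self) -> int:
        return len(_PARAM_NAMES[self.family])

    # -- evaluation ---------------------------------------------------------

    def sf(self, t) -> np.ndarray:
        """Survival function S(t); accepts scalars or arrays, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time passed to survival function")
        s = _SF[self.family](t, self.params)
        return np.clip(s, 0.0, 1.0)

    def logpdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("log-density requires t > 0")
        return _LOGPDF[self.family](t, self.params)

    def isf(self, q) -> np.ndarray:
        """Inverse survival function: t such that S(t) = q (for sampling)."""
        q = np.asarray(q, dtype=float)
        return _ISF[self.family](q, self.params)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.isf(rng.uniform(size=n))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalModel":
        return cls(family=d["family"], params=dict(d["params"]))


def survival_function(model: SurvivalModel, t) -> np.ndarray:
    """Functional alias for ``model.sf(t)``."""
    return model.sf(t)


# -- family implementations -------------------------------------------------


def _with_zero(t, s_pos):
    """Splice S(0) = 1 into an array computed for t > 0."""
    out = np.where(t == 0, 1.0, s_pos)
    return out


def _sf_exponential(t, p):
    return np.exp(-p["rate"] * t)


def _sf_weibull(t, p):
    return np.exp(-p["lambda"] * np.power(t, p["gamma"]))


def _sf_gompertz(t, p):
    a, b = p["shape"], p["rate"]
    if abs(a) < 1e-12:
        return np.exp(-b * t)
    return np.exp(-b / a * np.expm1(a * t))


def _sf_gamma(t, p):
    return special.gammaincc(p["shape"], p["rate"] * t)


def _loggamma_tail(logx, a, lower):
    """Regularized incomplete gamma of exp(logx), robust to extreme logx.

    ``lower`` selects P(a, x) (True) or Q(a, x) (False).  For logx below the
    representable range the leading series term P ~ x^a / Gamma(a+1) is used;
    above it the tail saturates to {0, 1}.
    """
    logx = np.asarray(logx, dtype=float)
    out = np.empty_like(logx)
    tiny = logx < -700.0
    huge = logx > 700.0
    mid = ~(tiny | huge)
    if np.any(mid):
        x = np.exp(logx[mid])
        out[mid] = special.gammainc(a, x) if lower else special.gammaincc(a, x)
    if np.any(tiny):
        logp = a * logx[tiny] - special.gammaln(a + 1.0)
        p = np.exp(np.clip(logp, -745.0, 0.0))
        out[tiny] = p if lower else 1.0 - p
    if np.any(huge):
        out[huge] = 1.0 if lower else 0.0
    return out


def _sf_gengamma(t, p):
    mu, sigma, q = p["mu"], p["sigma"], p["Q"]
    if abs(q) < 1e-8:
        return _sf_lognormal(t, {"meanlog": mu, "sdlog": sigma})
    with np.errstate(divide="ignore"):
        w = (np.log(t) - mu) / sigma
    a = q ** -2
    logx = math.log(a) + q * w  # log of the incomplete-gamma argument
    s = _loggamma_tail(logx, a, lower=(q < 0))
    return _with_zero(t, s)


def _sf_loglogistic(t, p):
    shape, scale = p["shape"], p["scale"]
    with np.errstate(divide="ignore", over="ignore"):
        return 1.0 / (1.0 + np.power(t / scale, shape))


def _sf_lognormal(t, p):
    with np.errstate(divide="ignore"):
        z = (np.log(t) - p["meanlog"]) / p["sdlog"]
    return _with_zero(t, special.ndtr(-z))


_SF = {
    "exponential": _sf_exponential,
    "weibull": _sf_weibull,
    "gompertz": _sf_gompertz,
    "gamma": lambda t, p: _sf_gamma(t, p),
    "generalized_gamma": _sf_gengamma,
    "log_logistic": _sf_loglogistic,
    "log_normal": _sf_lognormal,
}


def _logpdf_exponential(t, p):
    return math.log(p["rate"]) - p["rate"] * t


def _logpdf_weibull(t, p):
    lam, gam = p["lambda"], p["gamma"]
    return math.log(lam * gam) + (gam - 1.0) * np.log(t) - lam * np.power(t, gam)


def _logpdf_gompertz(t, p):
    a, b = p["shape"], p["rate"]
    if abs(a) < 1e-12:
        return math.log(b) - b * t
    return math.log(b) + a * t - b / a * np.expm1(a * t)


def _logpdf_gamma(t, p):
    k, r = p["shape"], p["rate"]
    return k * math.log(r) + (k - 1.0) * np.log(t) - r * t - special.gammaln(k)


def _logpdf_gengamma(t, p):
    mu, sigma, q = p["mu"], p["sigma"], p["Q"]
    if abs(q) < 1e-8:
        return _logpdf_lognormal(t, {"meanlog": mu, "sdlog": sigma})
    w = (np.log(t) - mu) / sigma
    a = q ** -2
    qw = np.clip(q * w, -700.0, 700.0)
    return (
        math.log(abs(q))
        + a * math.log(a)
        - math.log(sigma)
        - np.log(t)
        - special.gammaln(a)
        + a * (qw - np.exp(qw))
    )


def _logpdf_loglogistic(t, p):
    shape, scale = p["shape"], p["scale"]
    z = np.log(t / scale) * shape
    return (
        math.log(shape)
        - np.log(t)
        + z
        - 2.0 * np.logaddexp(0.0, z)
    )


def _logpdf_lognormal(t, p):
    m, s = p["meanlog"], p["sdlog"]
    z = (np.log(t) - m) / s
    return -np.log(t) - math.log(s) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z


_LOGPDF = {
    "exponential": _logpdf_exponential,
    "weibull": _logpdf_weibull,
    "gompertz": _logpdf_gompertz,
    "gamma": _logpdf_gamma,
    "generalized_gamma": _logpdf_gengamma,
    "log_logistic": _logpdf_loglogistic,
    "log_normal": _logpdf_lognormal,
}


def _isf_exponential(q, p):
    return -np.log(q) / p["rate"]


def _isf_weibull(q, p):
    return np.power(-np.log(q) / p["lambda"], 1.0 / p["gamma"])


def _isf_gompertz(q, p):
    a, b = p["shape"], p["rate"]
    if abs(a) < 1e-12:
        return -np.log(q) / b
    arg = 1.0 - a * np.log(q) / b
    # For shape < 0 a fraction of the cohort never dies; map those to +inf.
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.log(arg) / a
    return np.where(arg > 0, t, np.inf)


def _isf_gamma(q, p):
    return special.gammainccinv(p["shape"], q) / p["rate"]


def _isf_gengamma(q, p):
    mu, sigma, qq = p["mu"], p["sigma"], p["Q"]
    if abs(qq) < 1e-8:
        return _isf_lognormal(q, {"meanlog": mu, "sdlog": sigma})
    a = qq ** -2
    if qq < 0:
        x = special.gammaincinv(a, q)
    else:
        x = special.gammainccinv(a, q)
    with np.errstate(divide="ignore"):
        w = (np.log(x) - math.log(a)) / qq
    return np.exp(mu + sigma * w)


def _isf_loglogistic(q, p):
    return p["scale"] * np.power((1.0 - q) / q, 1.0 / p["shape"])


def _isf_lognormal(q, p):
    return np.exp(p["meanlog"] + p["sdlog"] * special.ndtri(1.0 - q))


_ISF = {
    "exponential": _isf_exponential,
    "weibull": _isf_weibull,
    "gompertz": _isf_gompertz,
    "gamma": _isf_gamma,
    "generalized_gamma": _isf_gengamma,
    "log_logistic": _isf_loglogistic,
    "log_normal": _isf_lognormal,
}


# -- maximum-likelihood fitting ---------------------------------------------


@dataclass(frozen=True)
class FitResult:
    model: SurvivalModel
    log_likelihood: float
    aic: float
    bic: float
    n_obs: int


def _pack(family: str, params: dict) -> np.ndarray:
    pos = _POSITIVE[family]
    return np.array(
        [
            math.log(params[n]) if n in pos else params[n]
            for n in _PARAM_NAMES[family]
        ]
    )


def _unpack(family: str, theta: np.ndarray) -> dict:
    pos = _POSITIVE[family]
    return {
        n: (math.exp(v) if n in pos else float(v))
        for n, v in zip(_PARAM_NAMES[family], theta)
    }


def _moment_starts(family: str, time, event) -> list[dict]:
    """Moment-based multi-start heuristics (>= 3 starts per family)."""
    t_ev = time[event.astype(bool)]
    if len(t_ev) == 0:
        t_ev = time
    rate = max(event.sum(), 1) / time.sum()
    m = float(np.mean(np.log(t_ev)))
    s = float(np.std(np.log(t_ev))) or 0.5
    med = float(np.median(t_ev))
    starts = {
        "exponential": [
            {"rate": rate},
            {"rate": rate * 2},
            {"rate": rate / 2},
        ],
        "weibull": [
            {"lambda": rate, "gamma": g} for g in (1.0, 0.7, 1.5)
        ],
        "gompertz": [
            {"shape": a, "rate": rate} for a in (1e-3, 0.05, -0.05)
        ],
        "gamma": [
            {"shape": k, "rate": k * rate} for k in (1.0, 0.5, 2.0)
        ],
        "generalized_gamma": [
            {"mu": m, "sigma": s, "Q": q} for q in (1e-3, 1.0, -1.0)
        ],
        "log_logistic": [
            {"shape": sh, "scale": med} for sh in (1.0, 2.0, 0.5)
        ],
        "log_normal": [
            {"meanlog": m, "sdlog": s},
            {"meanlog": m, "sdlog": 2 * s},
            {"meanlog": math.log(med), "sdlog": 1.0},
        ],
    }
    return starts[family]


def _neg_log_likelihood(family: str, theta, time, event):
    try:
        params = _unpack(family, theta)
        model = SurvivalModel(family, params)
    except (ParameterError, OverflowError):
        return np.inf
    with np.errstate(all="ignore"):
        ev = event.astype(bool)
        ll = 0.0
        if ev.any():
            ll += np.sum(model.logpdf(time[ev]))
        if (~ev).any():
            s = model.sf(time[~ev])
            ll += np.sum(np.log(np.clip(s, 1e-300, 1.0)))
    if not np.isfinite(ll):
        return np.inf
    return -ll


def fit_parametric(ipd, family: str) -> FitResult:
    """Fit one parametric family to pseudo-IPD by right-censored ML.

    ``ipd`` is anything with ``time`` and ``event`` array attributes or a
    pandas DataFrame with those columns.  Uses Nelder-Mead from several
    moment-based starting points on log/identity-transformed parameters and
    keeps the best local optimum.
    """
    time = np.asarray(getattr(ipd, "time", ipd["time"] if hasattr(ipd, "__getitem__") else None), dtype=float)
    event = np.asarray(getattr(ipd, "event", ipd["event"] if hasattr(ipd, "__getitem__") else None), dtype=float)
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}")
    if len(time) < 10:
        raise DegenerateDataError("need at least 10 observations")
    if event.sum() < 1:
        raise DegenerateDataError(
            "all observations censored: likelihood unbounded"
        )
    if np.any(time <= 0):
        raise ValueError("times must be positive")

    best = None
    diagnostics = []
    for start in _moment_starts(family, time, event):
        theta0 = _pack(family, start)
        res = optimize.minimize(
            lambda th: _neg_log_likelihood(family, th, time, event),
            theta0,
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        diagnostics.append(res)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"{family} fit failed to converge", diagnostics)

    params = _unpack(family, best.x)
    model = SurvivalModel(family, params)
    ll = -float(best.fun)
    k = model.n_params
    n = len(time)
    return FitResult(
        model=model,
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        bic=k * math.log(n) - 2 * ll,
        n_obs=n,
    )


def select_best(fits: Sequence[FitResult], criterion: str = "aic") -> FitResult:
    """Pick the minimum-AIC (or -BIC) fit.

    Ties break deterministically: fewer free parameters first, then family
    order in ``FAMILIES``.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    return min(
        fits,
        key=lambda f: (
            getattr(f, criterion),
            f.model.n_params,
            FAMILIES.index(f.model.family),
        ),
    )
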