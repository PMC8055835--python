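"""Parametric survival families used for curve extrapolation.

Five families cover the standard health-economic toolkit: exponential,
Weibull, Gompertz, log-logistic and log-normal.  Each family fixes an
explicit parameterization:

===========  =====================  ======================================
family       parameters             survival function S(t)
===========  =====================  ======================================
exponential  rate λ > 0             exp(−λt)
weibull      shape k > 0,           exp(−(t/σ)^k)
             scale σ > 0
gompertz     shape a ∈ ℝ,           exp(−(b/a)(e^{at} − 1))
             rate b > 0             (hazard h(t) = b·e^{at})
loglogistic  shape β > 0,           1 / (1 + (t/α)^β)
             scale α > 0
lognormal    mu μ ∈ ℝ,              1 − Φ((ln t − μ)/σ)
             sigma σ > 0
===========  =====================  ======================================

The Gompertz shape may be negative, in which case the distribution is
improper (a fraction exp(b/a) of the population never experiences the
event); this is deliberate, as a decelerating hazard is one way a long
survival plateau manifests.  A "restricted" Gompertz (a ≥ 0) is available
through the fitting layer.

Times are in months throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Sequence

import numpy as np
from scipy import stats

_EPS_SHAPE = 1e-10  # below this |a|, Gompertz is evaluated as its exponential limit

FAMILY_NAMES = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")


@dataclass(frozen=True)
class Family:
    """A parametric survival family with a fixed, documented parameterization."""

    name: str
    param_names: tuple
    # "positive" params are log-transformed for unconstrained optimization,
    # "real" params are passed through.
    param_kinds: tuple
    logsf: Callable
    logpdf: Callable
    rvs: Callable

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def sf(self, t, params):
        return np.exp(self.logsf(t, params))

    def pdf(self, t, params):
        return np.exp(self.logpdf(t, params))

    def hazard(self, t, params):
        return np.exp(self.logpdf(t, params) - self.logsf(t, params))

    def to_unconstrained(self, params: Dict[str, float]) -> np.ndarray:
        out = []
        for nm, kind in zip(self.param_names, self.param_kinds):
            v = float(params[nm])
            out.append(math.log(v) if kind == "positive" else v)
        return np.asarray(out)

    def from_unconstrained(self, x: Sequence[float]) -> Dict[str, float]:
        out = {}
        for nm, kind, v in zip(self.param_names, self.param_kinds, x):
            out[nm] = float(np.exp(v)) if kind == "positive" else float(v)
        return out


# ---------------------------------------------------------------------------
# exponential

def _exp_logsf(t, p):
    return -p["rate"] * np.asarray(t, dtype=float)


def _exp_logpdf(t, p):
    return np.log(p["rate"]) - p["rate"] * np.asarray(t, dtype=float)


def _exp_rvs(p, size, rng):
    return rng.exponential(1.0 / p["rate"], size=size)


# ---------------------------------------------------------------------------
# weibull

def _wei_logsf(t, p):
    t = np.asarray(t, dtype=float)
    return -((t / p["scale"]) ** p["shape"])


def _wei_logpdf(t, p):
    t = np.asarray(t, dtype=float)
    k, s = p["shape"], p["scale"]
    z = t / s
    with np.errstate(divide="ignore"):
        return np.log(k) - np.log(s) + (k - 1.0) * np.log(z) - z**k


def _wei_rvs(p, size, rng):
    return p["scale"] * rng.weibull(p["shape"], size=size)


# ---------------------------------------------------------------------------
# gompertz — h(t) = b·exp(a·t)

def _gom_cumhaz(t, a, b):
    t = np.asarray(t, dtype=float)
    if abs(a) < _EPS_SHAPE:
        return b * t
    return (b / a) * np.expm1(a * t)


def _gom_logsf(t, p):
    return -_gom_cumhaz(t, p["shape"], p["rate"])


def _gom_logpdf(t, p):
    t = np.asarray(t, dtype=float)
    a, b = p["shape"], p["rate"]
    return np.log(b) + a * t - _gom_cumhaz(t, a, b)


def _gom_rvs(p, size, rng):
    """Inverse-CDF sampling; improper mass (a<0) maps to +inf."""
    a, b = p["shape"], p["rate"]
    u = rng.uniform(size=size)  # u plays the role of S(t)
    if abs(a) < _EPS_SHAPE:
        return -np.log(u) / b
    arg = 1.0 - a * np.log(u) / b
    out = np.full(np.shape(u), np.inf)
    ok = arg > 0
    out[ok] = np.log(arg[ok]) / a
    return out


# ---------------------------------------------------------------------------
# log-logistic

def _llog_logsf(t, p):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        return -np.log1p((t / p["scale"]) ** p["shape"])


def _llog_logpdf(t, p):
    t = np.asarray(t, dtype=float)
    b, a = p["shape"], p["scale"]
    z = t / a
    with np.errstate(divide="ignore"):
        return np.log(b) - np.log(a) + (b - 1.0) * np.log(z) - 2.0 * np.log1p(z**b)


def _llog_rvs(p, size, rng):
    u = rng.uniform(size=size)
    return p["scale"] * (1.0 / u - 1.0) ** (1.0 / p["shape"])


# ---------------------------------------------------------------------------
# log-normal

def _lnorm_logsf(t, p):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        return stats.norm.logsf((np.log(t) - p["mu"]) / p["sigma"])


def _lnorm_logpdf(t, p):
    t = np.asarray(t, dtype=float)
    mu, sg = p["mu"], p["sigma"]
    with np.errstate(divide="ignore"):
        z = (np.log(t) - mu) / sg
        return stats.norm.logpdf(z) - np.log(sg) - np.log(t)


def _lnorm_rvs(p, size, rng):
    return np.exp(p["mu"] + p["sigma"] * rng.standard_normal(size))


FAMILIES: Dict[str, Family] = {
    "exponential": Family(
        "exponential", ("rate",), ("positive",), _exp_logsf, _exp_logpdf, _exp_rvs
    ),
    "weibull": Family(
        "weibull", ("shape", "scale"), ("positive", "positive"),
        _wei_logsf, _wei_logpdf, _wei_rvs,
    ),
    "gompertz": Family(
        "gompertz", ("shape", "rate"), ("real", "positive"),
        _gom_logsf, _gom_logpdf, _gom_rvs,
    ),
    "loglogistic": Family(
        "loglogistic", ("shape", "scale"), ("positive", "positive"),
        _llog_logsf, _llog_logpdf, _llog_rvs,
    ),
    "lognormal": Family(
        "lognormal", ("mu", "sigma"), ("real", "positive"),
        _lnorm_logsf, _lnorm_logpdf, _lnorm_rvs,
    ),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; expected one of {sorted(FAMILIES)}"
        ) from None
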