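"""Comparison models for interevent-time distributions.

Four standard families compete with the multiscale model: exponential
(homogeneous Poisson process), Pareto above a lower cutoff ``x_m``, Weibull,
and log-normal.  Each gets a closed-form density/CDF and a maximum-likelihood
fit.  The module also exposes the hazard special cases that connect the
families to the survival-process picture: a constant hazard gives the
exponential law, ``lambda(tau) = gamma / tau`` gives a Pareto tail with
exponent ``1 + gamma``, and ``lambda(tau) = gamma / tau**a`` with ``a < 1``
recovers the Weibull distribution.

Pareto fitting follows the standard tail-fitting convention: the cutoff
``x_m`` is tuned by scanning candidates over the order statistics and
minimizing the Kolmogorov-Smirnov distance between the tail data and the
fitted tail (``tune_xm``); data below ``x_m`` is cropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .hazard import as_durations

logger = logging.getLogger("burstfit")

FAMILIES = ("exponential", "pareto", "weibull", "lognormal")

__all__ = [
    "FAMILIES",
    "BaselineParams",
    "PowerLawHazardParams",
    "DegenerateDataError",
    "baseline_density",
    "baseline_cdf",
    "fit_baseline",
    "tune_xm",
    "TunedPareto",
    "special_case_density",
]


class DegenerateDataError(ValueError):
    """Raised when a family's MLE does not exist (e.g. zero spread)."""


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of one comparison family.

    family = "exponential": rate (events/second).
    family = "pareto":      x_m (lower cutoff, seconds) and exponent > 1,
                            density (e-1) x_m^(e-1) tau^(-e) on [x_m, inf).
    family = "weibull":     shape and scale (seconds).
    family = "lognormal":   mu and sigma of log-durations.
    """

    family: str
    rate: float | None = None
    x_m: float | None = None
    exponent: float | None = None
    shape: float | None = None
    scale: float | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        f = self.family
        if f == "exponential":
            if not (self.rate and self.rate > 0):
                raise ValueError("exponential requires rate > 0")
        elif f == "pareto":
            if not (self.x_m and self.x_m > 0 and self.exponent and self.exponent > 1):
                raise ValueError("pareto requires x_m > 0 and exponent > 1")
        elif f == "weibull":
            if not (self.shape and self.shape > 0 and self.scale and self.scale > 0):
                raise ValueError("weibull requires shape > 0 and scale > 0")
        elif f == "lognormal":
            if self.mu is None or not (self.sigma and self.sigma > 0):
                raise ValueError("lognormal requires mu and sigma > 0")
        else:
            raise ValueError(f"unknown family {f!r}")

    @property
    def n_free_parameters(self) -> int:
        return {"exponential": 1, "pareto": 2, "weibull": 2, "lognormal": 2}[
            self.family
        ]

    def dist(self):
        """The scipy.stats frozen distribution for this parameter set."""
        if self.family == "exponential":
            return stats.expon(scale=1.0 / self.rate)
        if self.family == "pareto":
            return stats.pareto(b=self.exponent - 1.0, scale=self.x_m)
        if self.family == "weibull":
            return stats.weibull_min(self.shape, scale=self.scale)
        return stats.lognorm(self.sigma, scale=np.exp(self.mu))


@dataclass(frozen=True)
class PowerLawHazardParams:
    """Hazard special case lambda(tau) = gamma / tau**alpha_h.

    alpha_h = 1 yields a Pareto waiting-time law with exponent 1 + gamma;
    alpha_h < 1 yields the Weibull distribution.
    """

    gamma: float
    alpha_h: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if not (0 < self.alpha_h <= 1):
            raise ValueError("alpha_h must lie in (0, 1]")


def baseline_density(tau, params: BaselineParams):
    """Closed-form density of the named family; zero (with a logged flag)
    below the Pareto support rather than an error."""
    arr = np.asarray(tau, dtype=float)
    if np.any(arr < 0):
        raise ValueError("tau must be nonnegative")
    if params.family == "pareto" and np.any(arr < params.x_m):
        logger.debug(
            "%d evaluation points below the Pareto cutoff x_m=%.3g -> zero density",
            int(np.sum(arr < params.x_m)),
            params.x_m,
        )
    out = params.dist().pdf(arr)
    return float(out) if np.ndim(tau) == 0 else out


def baseline_cdf(tau, params: BaselineParams):
    arr = np.asarray(tau, dtype=float)
    if np.any(arr < 0):
        raise ValueError("tau must be nonnegative")
    out = params.dist().cdf(arr)
    return float(out) if np.ndim(tau) == 0 else out


# ---------------------------------------------------------------------------
# Maximum-likelihood fits
# ---------------------------------------------------------------------------


def _positive(durations: np.ndarray, family: str) -> np.ndarray:
    pos = durations[durations > 0]
    n_zero = durations.size - pos.size
    if n_zero:
        logger.info("%s fit: dropped %d zero durations", family, n_zero)
    return pos


def _fit_weibull(tau: np.ndarray) -> BaselineParams:
    """Weibull MLE via the standard 1-D profile equation for the shape.

    With scale profiled out, the shape k solves
        sum(t^k log t)/sum(t^k) - 1/k - mean(log t) = 0,
    which is monotone in k; solved by bracketing + brentq.  Zeros are kept
    (they contribute to the scale through the mean) but excluded from the
    log terms by clipping at the smallest positive value.
    """
    t = np.clip(tau, np.min(tau[tau > 0]) if np.any(tau > 0) else 1.0, None)
    logt = np.log(t)
    mean_logt = logt.mean()

    def profile(k: float) -> float:
        w = t**k
        return float((w * logt).sum() / w.sum() - 1.0 / k - mean_logt)

    lo, hi = 1e-2, 1.0
    while profile(hi) < 0 and hi < 1e3:
        hi *= 2.0
    while profile(lo) > 0 and lo > 1e-6:
        lo /= 2.0
    k = optimize.brentq(profile, lo, hi, xtol=1e-12, rtol=1e-12)
    scale = float((t**k).mean() ** (1.0 / k))
    return BaselineParams(family="weibull", shape=k, scale=scale)


def fit_baseline(
    series, family: str, x_m: float | None = None
) -> BaselineParams:
    """Maximum-likelihood parameters of one comparison family.

    Exponential and log-normal are closed form; Weibull solves the 1-D
    profile equation; Pareto uses the conditional (Hill) MLE
    ``exponent = 1 + n_tail / sum(log(tau_i / x_m))`` given ``x_m``
    (default: the smallest positive duration).  Zero durations are excluded
    (with a logged count) for the log-normal and Pareto families, whose
    support excludes zero.
    """
    tau = as_durations(series)
    if tau.size < 3:
        raise ValueError("need at least 3 durations to fit a baseline")
    if family == "exponential":
        return BaselineParams(family="exponential", rate=1.0 / tau.mean())
    if family == "lognormal":
        pos = _positive(tau, family)
        if pos.size < 3:
            raise ValueError("too few positive durations for a lognormal fit")
        if np.ptp(pos) == 0.0:
            raise DegenerateDataError("all durations identical: lognormal MLE degenerate")
        logt = np.log(pos)
        sigma = float(logt.std())
        return BaselineParams(family="lognormal", mu=float(logt.mean()), sigma=sigma)
    if family == "weibull":
        if np.ptp(tau) == 0.0:
            raise DegenerateDataError("all durations identical: weibull MLE degenerate")
        return _fit_weibull(tau)
    if family == "pareto":
        pos = _positive(tau, family)
        if pos.size < 3:
            raise ValueError("too few positive durations for a pareto fit")
        if x_m is None:
            x_m = float(pos.min())
        tail = pos[pos >= x_m]
        s = float(np.log(tail / x_m).sum())
        if s <= 0.0:
            raise DegenerateDataError("zero log-spread above x_m: pareto MLE degenerate")
        exponent = 1.0 + tail.size / s
        return BaselineParams(family="pareto", x_m=x_m, exponent=exponent)
    raise ValueError(f"unknown family {family!r}")


class TunedPareto(NamedTuple):
    x_m: float
    params: BaselineParams
    cropped_fraction: float
    ks_statistic: float


def tune_xm(series, max_candidates: int = 200) -> TunedPareto:
    """Tune the Pareto lower cutoff x_m by scanning the order statistics.

    Candidate cutoffs are every k-th order statistic (k chosen to cap the
    number of candidates); for each, the tail above it is fitted by the
    conditional MLE and scored by the KS distance between the tail data and
    the fitted Pareto.  Returns the cutoff minimizing the KS statistic
    together with the fraction of data strictly below it.  Candidates whose
    tail holds fewer than 5 points are skipped.
    """
    from .gof import ks_statistic  # local import to avoid a cycle

    tau = np.sort(as_durations(series))
    tau = tau[tau > 0]
    n = tau.size
    if n < 10:
        raise ValueError("need at least 10 positive durations to tune x_m")
    step = max(1, n // max_candidates)
    candidates = np.unique(tau[::step])
    best: TunedPareto | None = None
    for xm in candidates:
        tail = tau[tau >= xm]
        if tail.size < 5:
            continue
        try:
            params = fit_baseline(tail, "pareto", x_m=float(xm))
        except DegenerateDataError:
            continue
        d = ks_statistic(tail, params.dist().cdf)
        if best is None or d < best.ks_statistic:
            frac = float(np.mean(tau < xm))
            best = TunedPareto(float(xm), params, frac, float(d))
    if best is None:
        raise ValueError("no admissible x_m candidate (tails all too short)")
    return best


def special_case_density(tau, params: PowerLawHazardParams, tau_min: float):
    """Density induced by the power-law hazard gamma/tau**alpha_h with
    survival measured from tau_min (> 0, required because the cumulative
    hazard of 1/tau diverges at the origin).

    For alpha_h = 1 this is exactly the Pareto density with exponent
    1 + gamma on [tau_min, inf); for alpha_h < 1 it is exactly Weibull.
    """
    if not tau_min > 0:
        raise ValueError("tau_min must be > 0")
    arr = np.asarray(tau, dtype=float)
    if np.any(arr < tau_min):
        raise ValueError("tau must be >= tau_min")
    g, a = params.gamma, params.alpha_h
    haz = g * arr ** (-a)
    if a == 1.0:
        cum = g * np.log(arr / tau_min)
    else:
        cum = g * (arr ** (1.0 - a) - tau_min ** (1.0 - a)) / (1.0 - a)
    out = haz * np.exp(-cum)
    return float(out) if np.ndim(tau) == 0 else out
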