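"""Mathematical core of the multiscale survival process.

An individual's waiting time between consecutive events is modelled through
its hazard (intensity) rate

    lambda(tau) = lambda0 / ((tau / t0)**alpha + 1) + lambda_inf

which interpolates between three regimes: a quick-response plateau at rate
``lambda0 + lambda_inf`` below the critical timescale ``t0``, a bursty
power-law decay with exponent ``alpha`` above it, and a floor ``lambda_inf``
that produces an exponential tail and controls the mean interevent time.

This module provides the induced survival quantities: intensity, cumulative
hazard, survival function, CDF, density, quantiles and the mean interevent
time.  Everything is vectorized over ``tau``.

The cumulative hazard is

    Lambda(tau) = lambda_inf * tau + lambda0 * t0 * phi(tau / t0; alpha)

with the dimensionless integral ``phi(u; a) = int_0^u ds / (1 + s**a)``,
evaluated in closed form through the Gauss hypergeometric function
``phi(u; a) = u * 2F1(1, 1/a; 1 + 1/a; -u**a)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

logger = logging.getLogger("burstfit")

#: Smallest admissible value for any rate/scale parameter.  Exact zeros are
#: disallowed so that log-likelihoods stay finite and the optimizer works in
#: an open (log-space) domain; "lambda0 = 0" limits are realized as this floor.
PARAM_FLOOR = 1e-12

__all__ = [
    "PARAM_FLOOR",
    "ModelParams",
    "InterEventSeries",
    "intensity",
    "cumulative_hazard",
    "survival",
    "cdf",
    "density",
    "log_density",
    "quantile",
    "invert_cumulative_hazard",
    "mean_interevent",
]


@dataclass(frozen=True)
class ModelParams:
    """Four-parameter hazard specification theta = {lambda0, t0, alpha, lambda_inf}.

    Parameters
    ----------
    lambda0
        Quick-response activity rate (events/second) governing tau << t0.
    t0
        Critical timescale (seconds) where bursty behaviour emerges.
    alpha
        Dimensionless exponent controlling the heterogeneity of the burst
        regime (log-log density slope ~ -alpha at intermediate tau).
    lambda_inf
        Long-time activity rate (events/second); sets the exponential tail
        and dominates the mean interevent time.

    All four must be strictly positive (>= ``PARAM_FLOOR``).  The model's
    interpretation assumes ``lambda_inf << lambda0``; violating that is not an
    error but raises a diagnostic warning and sets ``tail_dominant``.
    """

    lambda0: float
    t0: float
    alpha: float
    lambda_inf: float
    tail_dominant: bool = field(init=False, repr=False, compare=False, default=False)

    def __post_init__(self) -> None:
        for name in ("lambda0", "t0", "alpha", "lambda_inf"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < PARAM_FLOOR:
                raise ValueError(
                    f"{name} must be finite and >= {PARAM_FLOOR:g}, got {v!r}"
                )
        if self.lambda_inf >= self.lambda0:
            object.__setattr__(self, "tail_dominant", True)
            warnings.warn(
                "lambda_inf >= lambda0: the multiscale interpretation assumes "
                "lambda_inf << lambda0; fit may be effectively exponential",
                UserWarning,
                stacklevel=2,
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda0, self.t0, self.alpha, self.lambda_inf])


@dataclass(frozen=True)
class InterEventSeries:
    """One individual's ordered waiting times (seconds).

    Order is retained for provenance only; every operation on a series is
    exchangeable in it.  Zero durations are admitted (the model density is
    finite at tau = 0).
    """

    durations: np.ndarray
    individual_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.durations, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("durations must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("durations must be finite and nonnegative")
        object.__setattr__(self, "durations", arr)

    @property
    def n(self) -> int:
        return int(self.durations.size)


def as_durations(series) -> np.ndarray:
    """Accept an InterEventSeries or a bare array-like of durations."""
    if isinstance(series, InterEventSeries):
        return series.durations
    arr = np.asarray(series, dtype=float)
    return np.atleast_1d(arr)


# ---------------------------------------------------------------------------
# The dimensionless integral phi(u; a) = int_0^u ds / (1 + s^a)
# ---------------------------------------------------------------------------

# Beyond u**a > _ASYMPTOTIC_CUT the hypergeometric argument is extreme and the
# two-term tail expansion is already accurate to machine precision (a > 1).
_ASYMPTOTIC_CUT_LOG = 30.0 * np.log(10.0)


def phi_total(alpha: float) -> float:
    """phi(inf; alpha) = (pi/alpha) / sin(pi/alpha), finite for alpha > 1."""
    if alpha <= 1.0:
        return np.inf
    x = np.pi / alpha
    return x / np.sin(x)


def _phi(u: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized phi(u; alpha) for u >= 0."""
    shape = np.shape(u)
    u = np.ravel(np.asarray(u, dtype=float))
    if alpha == 1.0:  # exact elementary antiderivatives
        return np.log1p(u).reshape(shape)
    if alpha == 2.0:
        return np.arctan(u).reshape(shape)
    out = np.zeros_like(u)
    pos = u > 0
    if not np.any(pos):
        return out.reshape(shape)
    up = u[pos]
    with np.errstate(divide="ignore"):
        loga = alpha * np.log(up)
    far = loga > _ASYMPTOTIC_CUT_LOG
    if alpha > 1.0 and np.any(far):
        uf = up[far]
        # tail expansion: phi(inf) - u^(1-a)/(a-1) + u^(1-2a)/(2a-1) - ...
        tail = phi_total(alpha) - uf ** (1.0 - alpha) / (alpha - 1.0)
        if alpha > 0.5:  # second term representable
            with np.errstate(under="ignore"):
                tail += uf ** (1.0 - 2.0 * alpha) / (2.0 * alpha - 1.0)
        vals = np.empty_like(up)
        vals[far] = tail
        near = ~far
        un = up[near]
        vals[near] = un * special.hyp2f1(
            1.0, 1.0 / alpha, 1.0 + 1.0 / alpha, -(un**alpha)
        )
    else:
        with np.errstate(over="ignore"):
            z = -(up**alpha)
        z = np.maximum(z, -1e300)
        vals = up * special.hyp2f1(1.0, 1.0 / alpha, 1.0 + 1.0 / alpha, z)
    out[pos] = vals
    return out.reshape(shape)


def phi_quadrature(u: float, alpha: float) -> float:
    """Adaptive-quadrature evaluation of phi(u; alpha) (independent slow path;
    used as a cross-check of the closed form)."""
    if u <= 0:
        return 0.0
    pts = [p for p in (1.0,) if 0 < p < u]
    val, _ = integrate.quad(
        lambda s: 1.0 / (1.0 + s**alpha), 0.0, u, points=pts or None,
        limit=400, epsabs=0.0, epsrel=1e-11,
    )
    return val


def _validate_tau(tau, allow_zero: bool = True) -> np.ndarray:
    arr = np.asarray(tau, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("tau must be finite")
    if np.any(arr < 0):
        raise ValueError("tau must be nonnegative")
    return arr


def _maybe_scalar(x: np.ndarray, tau) -> np.ndarray | float:
    if np.isscalar(tau) or np.ndim(tau) == 0:
        return float(x)
    return x


# ---------------------------------------------------------------------------
# Survival quantities
# ---------------------------------------------------------------------------


def intensity(tau, theta: ModelParams):
    """Hazard rate lambda(tau | theta); strictly positive, nonincreasing."""
    t = _validate_tau(tau)
    u = t / theta.t0
    with np.errstate(over="ignore"):
        ua = u**theta.alpha
    lam = theta.lambda0 / (1.0 + ua) + theta.lambda_inf
    return _maybe_scalar(lam, tau)


def cumulative_hazard(tau, theta: ModelParams):
    """Lambda(tau) = lambda_inf*tau + lambda0*t0*phi(tau/t0; alpha).

    Strictly increasing, Lambda(0) = 0; evaluated through the closed-form
    hypergeometric representation of phi (relative accuracy ~1e-10).
    """
    t = _validate_tau(tau)
    val = theta.lambda_inf * t + theta.lambda0 * theta.t0 * _phi(
        t / theta.t0, theta.alpha
    )
    return _maybe_scalar(val, tau)


def survival(tau, theta: ModelParams):
    """S(tau) = exp(-Lambda(tau)): probability the waiting time exceeds tau."""
    t = _validate_tau(tau)
    val = np.exp(-np.asarray(cumulative_hazard(t, theta)))
    return _maybe_scalar(val, tau)


def cdf(tau, theta: ModelParams):
    """F(tau) = 1 - S(tau)."""
    t = _validate_tau(tau)
    lam = np.asarray(cumulative_hazard(t, theta))
    val = -np.expm1(-lam)
    return _maybe_scalar(val, tau)


def density(tau, theta: ModelParams):
    """Waiting-time density P(tau) = lambda(tau) * S(tau).

    Finite at tau = 0, where it equals lambda0 + lambda_inf.
    """
    t = _validate_tau(tau)
    val = np.asarray(intensity(t, theta)) * np.asarray(survival(t, theta))
    return _maybe_scalar(val, tau)


def log_density(tau, theta: ModelParams):
    """log P(tau) = log lambda(tau) - Lambda(tau); finite for all tau >= 0."""
    t = _validate_tau(tau)
    val = np.log(np.asarray(intensity(t, theta))) - np.asarray(
        cumulative_hazard(t, theta)
    )
    return _maybe_scalar(val, tau)


def invert_cumulative_hazard(y, theta: ModelParams, rtol: float = 1e-12):
    """Solve Lambda(tau) = y for tau (y >= 0), vectorized.

    Uses a log-spaced bracketing grid for the initial guess followed by
    safeguarded Newton iteration.  Because Lambda is increasing and concave
    apart from its asymptotically linear tail, Newton converges monotonically
    once left of the root; a multiplicative floor guards the jump from the
    right.  Cannot fail to bracket for valid theta since Lambda is unbounded
    (Lambda(tau) >= lambda_inf * tau).
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0) or not np.all(np.isfinite(y_arr)):
        raise ValueError("cumulative-hazard values must be finite and >= 0")
    out = np.zeros_like(y_arr, dtype=float)
    pos = y_arr > 0
    if not np.any(pos):
        return _maybe_scalar(out, y)
    yp = y_arr[pos]
    # Root bounds: lambda_inf*tau <= Lambda(tau) <= (lambda0+lambda_inf)*tau
    lo = yp.min() / (theta.lambda0 + theta.lambda_inf)
    hi = yp.max() / theta.lambda_inf
    grid = np.geomspace(max(lo / 10.0, 1e-300), hi * 10.0, 600)
    lam_grid = np.asarray(cumulative_hazard(grid, theta))
    tau = np.interp(yp, lam_grid, grid)
    tau = np.clip(tau, lo / 10.0, hi * 10.0)
    for _ in range(100):
        lam = np.asarray(cumulative_hazard(tau, theta))
        rate = np.asarray(intensity(tau, theta))
        step = (yp - lam) / rate
        new = np.maximum(tau + step, 0.2 * tau)
        rel = np.max(np.abs(new - tau) / np.maximum(new, 1e-300))
        tau = new
        if rel < rtol:
            break
    else:  # pragma: no cover - concave Newton converges in practice
        raise RuntimeError("cumulative-hazard inversion did not converge")
    out[pos] = tau
    return _maybe_scalar(out, y)


def quantile(q, theta: ModelParams):
    """Waiting-time quantile function F^{-1}(q), q in [0, 1)."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0) or np.any(q_arr >= 1):
        raise ValueError("quantile levels must lie in [0, 1)")
    return invert_cumulative_hazard(-np.log1p(-q_arr), theta)


def mean_interevent(theta: ModelParams) -> float:
    """Mean waiting time E[tau] = int_0^inf S(tau) dtau.

    The body is integrated by adaptive quadrature under the substitution
    x = log(1 + tau) (which tames the many-decade support); beyond the switch
    point A where lambda_inf * A = 35 the hazard's power-law part is treated
    as frozen and the exponential tail integrates in closed form to
    S(A)/lambda_inf (the truncation error is O(e-35)).
    """
    a_switch = 35.0 / theta.lambda_inf

    def body(x):
        tau = np.expm1(x)
        return float(survival(tau, theta)) * (tau + 1.0)

    x_hi = np.log1p(a_switch)
    pts = [np.log1p(p) for p in (theta.t0, 1.0 / theta.lambda_inf) if p < a_switch]
    val, _ = integrate.quad(body, 0.0, x_hi, points=sorted(set(pts)) or None,
                            limit=400)
    tail = float(survival(a_switch, theta)) / theta.lambda_inf
    return val + tail
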