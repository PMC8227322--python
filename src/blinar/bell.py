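"""The Bell distribution and the Bell numbers.

The Bell distribution is a one-parameter discrete distribution on the
non-negative integers with probability mass function

    P(Z = z) = theta^z * exp(1 - e^theta) * B_z / z!,    theta > 0,

where ``B_z`` is the z-th Bell number (the number of set partitions of a
z-element set, equivalently the z-th moment of a Poisson(1) variable).  It
belongs to the one-parameter exponential family, is infinitely divisible,
and is always overdispersed: Var(Z)/E(Z) = 1 + theta > 1.  As theta -> 0
it approaches a Poisson distribution with the same mean.  These properties
make it a convenient innovation law for overdispersed count time series.

This module provides exact big-integer Bell numbers, numerically stable
log-scale pmf/cdf/pgf evaluation, moments, two independent samplers, and
the inverse mean map theta e^theta = m solved by the Lambert W function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special


@dataclass(frozen=True)
class BellParam:
    """Parameter of a Bell distribution.

    Attributes
    ----------
    theta : float
        Strictly positive distribution parameter.  The mean is
        ``theta * exp(theta)`` and the variance ``theta * (1 + theta) *
        exp(theta)``.
    """

    theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be a finite positive real, got {self.theta!r}")


# ---------------------------------------------------------------------------
# Bell numbers
# ---------------------------------------------------------------------------

# Growing cache of exact Bell numbers; _triangle_row is the last row of the
# Bell triangle, from which the next Bell number is produced in O(n) big-int
# additions.  B_n overflows double precision near n ~ 180, so the exact
# values are Python ints and the log values are computed from the ints
# directly (math.log accepts arbitrary-precision ints).
_bell_values: list[int] = [1, 1]
_triangle_row: list[int] = [1, 2]
_log_bell: list[float] = [0.0, 0.0]


def _extend_bell_cache(n: int) -> None:
    global _triangle_row
    while len(_bell_values) <= n:
        row = _triangle_row
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        _bell_values.append(new[0])
        _log_bell.append(math.log(new[0]))
        _triangle_row = new


def bell_number(n: int) -> int:
    """Exact n-th Bell number as a Python integer.

    Computed by the Bell-triangle form of the binomial recurrence
    ``B_{n+1} = sum_k C(n, k) B_k`` with big-integer arithmetic, so there
    is no floating round-off at any n.
    """
    n = _check_index(n)
    _extend_bell_cache(n)
    return _bell_values[n]


def log_bell_number(n: int) -> float:
    """Natural log of the n-th Bell number.

    Exact up to one floating rounding: the log is taken of the exact
    big-integer value, never of a floating approximation.
    """
    n = _check_index(n)
    _extend_bell_cache(n)
    return _log_bell[n]


def log_bell_numbers(n_max: int) -> np.ndarray:
    """Vector ``[log B_0, ..., log B_{n_max}]``."""
    n_max = _check_index(n_max)
    _extend_bell_cache(n_max)
    return np.asarray(_log_bell[: n_max + 1])


def _check_index(n) -> int:
    if n != int(n) or n < 0:
        raise ValueError(f"n must be a non-negative integer, got {n!r}")
    return int(n)


@dataclass(frozen=True)
class BellNumberTable:
    """Precomputed exact and log-scale Bell numbers B_0..B_{n_max}."""

    n_max: int
    values: tuple
    log_values: np.ndarray

    @classmethod
    def build(cls, n_max: int) -> "BellNumberTable":
        n_max = _check_index(n_max)
        _extend_bell_cache(n_max)
        return cls(
            n_max=n_max,
            values=tuple(_bell_values[: n_max + 1]),
            log_values=np.asarray(_log_bell[: n_max + 1]),
        )


def bell_number_dobinski(n: int, terms: int = 400) -> float:
    """Dobinski-series evaluation ``B_n = (1/e) sum_k k^n / k!``.

    Slowly convergent and numerically delicate; kept only as an
    independent cross-check oracle for the exact recurrence.
    """
    n = _check_index(n)
    k = np.arange(terms)
    with np.errstate(divide="ignore"):
        logterms = n * np.log(np.maximum(k, 1)) - special.gammaln(k + 1)
    if n == 0:
        logterms[0] = -special.gammaln(1)
    else:
        logterms[0] = -np.inf
    return float(np.exp(special.logsumexp(logterms) - 1.0))


# ---------------------------------------------------------------------------
# pmf / cdf / pgf / moments
# ---------------------------------------------------------------------------


def bell_logpmf(z, p: BellParam):
    """Log pmf ``z ln(theta) - (e^theta - 1) + ln B_z - ln z!``.

    Accepts a scalar or array of non-negative integers; returns the same
    shape.  Evaluation is entirely in log space, so it is stable far past
    the z ~ 180 point where B_z / z! overflows double precision.
    """
    z_arr = np.atleast_1d(np.asarray(z))
    if np.any(z_arr < 0) or not np.issubdtype(z_arr.dtype, np.integer):
        z_arr = _as_counts(z_arr)
    logb = log_bell_numbers(int(z_arr.max()) if z_arr.size else 0)
    out = (
        z_arr * math.log(p.theta)
        - math.expm1(p.theta)
        + logb[z_arr]
        - special.gammaln(z_arr + 1.0)
    )
    return out if np.ndim(z) else float(out[0])


def bell_pmf(z, p: BellParam):
    return np.exp(bell_logpmf(z, p))


def _as_counts(a) -> np.ndarray:
    arr = np.asarray(a)
    ints = np.asarray(np.round(arr), dtype=np.int64)
    if np.any(ints != arr) or np.any(ints < 0):
        raise ValueError("support values must be non-negative integers")
    return ints


def support_upper(p: BellParam, tail: float = 1e-14) -> int:
    """Adaptive support cutoff: smallest z with tail mass below ``tail``.

    Starts at mean + 10 sd and extends while the geometric tail majorant
    pmf(z) * r / (1 - r), r = theta * B_{z+1} / ((z+1) B_z), exceeds the
    target.  The ratio r < 1 eventually since B_{z+1}/B_z ~ z / ln z.
    """
    mean, var = bell_moments(p)
    z = max(10, int(mean + 10.0 * math.sqrt(var)))
    while True:
        lb = log_bell_numbers(z + 1)
        r = p.theta * math.exp(lb[z + 1] - lb[z]) / (z + 1)
        if r < 1.0:
            majorant = math.exp(bell_logpmf(z, p)) * r / (1.0 - r)
            if majorant < tail:
                return z
        z = int(z * 1.5) + 5


def bell_cdf(z, p: BellParam):
    """Cumulative distribution function P(Z <= z)."""
    z_arr = _as_counts(np.atleast_1d(z))
    zmax = int(z_arr.max()) if z_arr.size else 0
    cum = np.cumsum(np.exp(bell_logpmf(np.arange(zmax + 1), p)))
    out = cum[z_arr]
    return out if np.ndim(z) else float(out[0])


def bell_moments(p: BellParam) -> tuple[float, float]:
    """(mean, variance) = (theta e^theta, theta (1 + theta) e^theta)."""
    et = math.exp(p.theta)
    return p.theta * et, p.theta * (1.0 + p.theta) * et


def bell_third_cumulant(p: BellParam) -> float:
    """Third cumulant theta (1 + 3 theta + theta^2) e^theta.

    From the cumulant generating function K(t) = e^{theta e^t} - e^theta.
    """
    return p.theta * (1.0 + 3.0 * p.theta + p.theta**2) * math.exp(p.theta)


def bell_pgf(s, p: BellParam):
    """Probability generating function ``E[s^Z] = exp(e^{s theta} - e^theta)``."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(np.abs(s_arr) > 1.0 + 1e-12):
        raise ValueError("pgf argument must satisfy |s| <= 1")
    out = np.exp(np.exp(s_arr * p.theta) - math.exp(p.theta))
    return out if np.ndim(s) else float(out[0])


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def bell_sample(p: BellParam, n: int, seed=None, method: str = "compound") -> np.ndarray:
    """Draw n i.i.d. Bell(theta) variates.

    ``method='compound'`` (default) uses the compound-Poisson
    representation: Z = Y_1 + ... + Y_N with N ~ Poisson(e^theta - 1) and
    Y_i i.i.d. zero-truncated Poisson(theta).  ``method='inversion'``
    inverts the cdf on uniforms; the two samplers are distributionally
    identical and serve as mutual cross-checks.
    """
    if n != int(n) or n <= 0:
        raise ValueError(f"sample size must be a positive integer, got {n!r}")
    n = int(n)
    rng = _as_rng(seed)
    if method == "compound":
        counts = rng.poisson(math.expm1(p.theta), size=n)
        total = int(counts.sum())
        if total == 0:
            return np.zeros(n, dtype=np.int64)
        y = _ztp_sample(p.theta, total, rng)
        out = np.zeros(n, dtype=np.int64)
        np.add.at(out, np.repeat(np.arange(n), counts), y)
        return out
    if method == "inversion":
        zmax = support_upper(p)
        cdf = np.cumsum(np.exp(bell_logpmf(np.arange(zmax + 1), p)))
        u = rng.random(n)
        return np.searchsorted(cdf, u, side="right").astype(np.int64)
    raise ValueError(f"unknown sampling method {method!r}")


def _ztp_sample(theta: float, n: int, rng: np.random.Generator) -> np.ndarray:
    # Zero-truncated Poisson by inversion: map U onto (P(0), 1] and invert
    # the untruncated Poisson cdf.
    from scipy import stats

    p0 = math.exp(-theta)
    u = p0 + (1.0 - p0) * rng.random(n)
    return stats.poisson.ppf(u, theta).astype(np.int64)


# ---------------------------------------------------------------------------
# mean inversion
# ---------------------------------------------------------------------------


def theta_from_mean(m: float) -> BellParam:
    """The unique theta > 0 with ``theta * exp(theta) = m``.

    Principal-branch Lambert W followed by one Newton polish step, giving
    round-trip error |theta e^theta - m| <= 1e-10 * max(1, m).
    """
    if not (np.isfinite(m) and m > 0):
        raise ValueError(f"mean must be a finite positive real, got {m!r}")
    theta = float(special.lambertw(m).real)
    # Newton polish on f(t) = t e^t - m; f'(t) = (1 + t) e^t.
    et = math.exp(theta)
    theta -= (theta * et - m) / ((1.0 + theta) * et)
    return BellParam(max(theta, np.finfo(float).tiny))
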