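"""The BL-INAR(1) process: binomial thinning with Bell innovations.

The model is the first-order integer-valued autoregression

    X_t = alpha o X_{t-1} + eps_t,        eps_t ~ Bell(theta) i.i.d.,

where ``alpha o X = sum_{i=1}^X xi_i`` is binomial thinning (the xi_i are
i.i.d. Bernoulli(alpha), so alpha o X | X ~ Binomial(X, alpha)).  With
0 < alpha < 1 and theta > 0 the chain is an ergodic stationary Markov
chain with

    mean        mu      = theta e^theta / (1 - alpha)
    variance    sigma^2 = theta e^theta (1 + alpha + theta) / (1 - alpha^2)
    autocorr.   rho_k   = alpha^k
    dispersion  I_x     = sigma^2 / mu = 1 + theta / (1 + alpha) > 1,

so the process is overdispersed for every admissible parameter pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special

from .bell import (
    BellParam,
    _as_rng,
    bell_logpmf,
    bell_moments,
    bell_sample,
)

# Floor for log-probabilities: log of the smallest normal double plus a
# margin, so exp() underflows gracefully instead of producing -inf chains.
LOG_FLOOR = math.log(np.finfo(float).tiny) + 50.0


@dataclass(frozen=True)
class ModelParams:
    """BL-INAR(1) parameters: thinning probability and innovation parameter.

    ``alpha`` is the survival probability of each unit from one month to
    the next; ``theta`` governs the Bell innovation law.
    """

    alpha: float
    theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and 0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie strictly in (0, 1), got {self.alpha!r}")
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be a finite positive real, got {self.theta!r}")

    @property
    def innovation(self) -> BellParam:
        return BellParam(self.theta)


class CountSeries:
    """An ordered series of non-negative integer counts.

    Thin wrapper over a 1-d int64 numpy array with validation and
    plain-text round-trip (one observation per line; an optional
    non-numeric header line is ignored on read).
    """

    def __init__(self, values) -> None:
        arr = np.asarray(values)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("a count series must be a non-empty 1-d sequence")
        ints = np.asarray(np.round(arr.astype(float)), dtype=np.int64)
        if np.any(ints != arr.astype(float)) or np.any(ints < 0):
            raise ValueError("count series values must be non-negative integers")
        self.values = ints

    def __len__(self) -> int:
        return int(self.values.size)

    def __iter__(self):
        return iter(self.values)

    def __repr__(self) -> str:
        return f"CountSeries(T={len(self)}, head={self.values[:8].tolist()})"

    @classmethod
    def read_text(cls, path) -> "CountSeries":
        lines = Path(path).read_text().strip().splitlines()
        if lines and not _is_numeric(lines[0].split(",")[0]):
            lines = lines[1:]
        vals = [float(line.strip().split(",")[0]) for line in lines if line.strip()]
        return cls(vals)

    def write_text(self, path) -> None:
        Path(path).write_text("\n".join(str(int(v)) for v in self.values) + "\n")


def _is_numeric(tok: str) -> bool:
    try:
        float(tok.strip())
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class MomentSummary:
    """Stationary moments of a BL-INAR(1) process."""

    mean: float
    variance: float
    autocovariance: np.ndarray  # gamma_1..gamma_max_lag
    autocorrelation: np.ndarray  # rho_1..rho_max_lag
    dispersion_index: float
    lags: np.ndarray = field(default_factory=lambda: np.arange(1, 2))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def binomial_thin(x: int, alpha: float, rng=None) -> int:
    """One binomial thinning draw ``alpha o x ~ Binomial(x, alpha)``.

    alpha = 0 and alpha = 1 are accepted as degenerate boundaries here
    (all-fail / all-survive), though the process itself requires the open
    interval.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"thinning probability must lie in [0, 1], got {alpha!r}")
    if x != int(x) or x < 0:
        raise ValueError(f"thinned count must be a non-negative integer, got {x!r}")
    return int(_as_rng(rng).binomial(int(x), alpha))


def simulate(
    params: ModelParams,
    T: int,
    burnin: int = 500,
    seed=None,
    x0: int | None = None,
) -> CountSeries:
    """Simulate a BL-INAR(1) path of length T.

    If ``x0`` is None the chain starts from a Bell(theta) draw and the
    first ``burnin`` steps are discarded to reach approximate
    stationarity (the chain is ergodic, so any start works).  Passing
    ``x0`` with ``burnin=0`` gives the exact conditional law given
    X_0 = x0, used by the Chapman-Kolmogorov checks.  Seeded runs are
    bit-reproducible.
    """
    if T < 1 or burnin < 0:
        raise ValueError("need T >= 1 and burnin >= 0")
    rng = _as_rng(seed)
    total = T + burnin
    innov = bell_sample(params.innovation, total, rng)
    path = np.empty(total, dtype=np.int64)
    x = int(bell_sample(params.innovation, 1, rng)[0]) if x0 is None else int(x0)
    for t in range(total):
        x = int(rng.binomial(x, params.alpha)) + int(innov[t])
        path[t] = x
    return CountSeries(path[burnin:])


# ---------------------------------------------------------------------------
# transition and joint probabilities
# ---------------------------------------------------------------------------


def _innov_logpmf_vector(kmax: int, params: ModelParams) -> np.ndarray:
    return np.atleast_1d(bell_logpmf(np.arange(kmax + 1), params.innovation))


def transition_logprob_pairs(
    x_next: np.ndarray, x_prev: np.ndarray, alpha: float, innov_logpmf: np.ndarray
) -> np.ndarray:
    """Vectorized log P(X_t = i | X_{t-1} = j) for paired (i, j) arrays.

    Each entry is log sum_{m=0}^{min(i,j)} C(j,m) a^m (1-a)^{j-m}
    pmf_eps(i-m), accumulated by log-sum-exp.  ``innov_logpmf`` must cover
    0..max(x_next).  Shared by the Bell likelihood and the generic
    innovation-family likelihood in `diagnostics`.
    """
    i = np.asarray(x_next, dtype=np.int64)
    j = np.asarray(x_prev, dtype=np.int64)
    mmax = np.minimum(i, j)
    M = int(mmax.max(initial=0))
    m = np.arange(M + 1)[None, :]
    jj = j[:, None].astype(float)
    ii = i[:, None]
    valid = m <= mmax[:, None]
    m_safe = np.where(valid, m, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_binom = (
            special.gammaln(jj + 1.0)
            - special.gammaln(m_safe + 1.0)
            - special.gammaln(jj - m_safe + 1.0)
            + m_safe * math.log(alpha)
            + (jj - m_safe) * math.log1p(-alpha)
        )
    terms = log_binom + innov_logpmf[ii - m_safe]
    terms = np.where(valid, terms, -np.inf)
    out = special.logsumexp(terms, axis=1)
    return np.maximum(out, LOG_FLOOR)


def transition_logprob(i: int, j: int, params: ModelParams) -> float:
    """Log transition probability log P(X_t = i | X_{t-1} = j)."""
    if i < 0 or j < 0:
        raise ValueError("states must be non-negative integers")
    lp = _innov_logpmf_vector(int(i), params)
    return float(
        transition_logprob_pairs(
            np.array([i]), np.array([j]), params.alpha, lp
        )[0]
    )


def transition_prob(i: int, j: int, params: ModelParams) -> float:
    """Transition probability P(X_t = i | X_{t-1} = j)."""
    return math.exp(transition_logprob(i, j, params))


def transition_matrix(params: ModelParams, size: int) -> np.ndarray:
    """Dense transition matrix P[i, j] = P(X_t = i | X_{t-1} = j), states 0..size-1."""
    ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    lp = _innov_logpmf_vector(size - 1, params)
    logP = transition_logprob_pairs(
        ii.ravel(), jj.ravel(), params.alpha, lp
    ).reshape(size, size)
    return np.exp(logP)


def stationary_distribution(params: ModelParams, tol: float = 1e-12) -> np.ndarray:
    """Stationary pmf by power iteration on an adaptively truncated transition matrix."""
    mom = stationary_moments(params)
    size = int(mom.mean + 12.0 * math.sqrt(mom.variance)) + 10
    P = transition_matrix(params, size)
    pi = np.exp(np.atleast_1d(bell_logpmf(np.arange(size), params.innovation)))
    pi /= pi.sum()
    for _ in range(100000):
        new = P @ pi
        new /= new.sum()
        if np.abs(new - pi).max() < tol:
            return new
        pi = new
    return pi


def joint_log_prob(
    series: CountSeries, params: ModelParams, initial: str = "conditioning"
) -> float:
    """Log joint probability of an observed path.

    With ``initial='conditioning'`` (default) returns
    sum_{t=1}^{T-1} log P(X_{t+1} | X_t) — the conditional log-likelihood
    used by CML.  With ``initial='stationary'`` the marginal log P(X_1)
    under the stationary law (computed by fixed-point iteration of the
    transition operator; no closed form exists) is added.
    """
    x = series.values
    if len(series) < 2:
        raise ValueError("need at least two observations")
    lp = _innov_logpmf_vector(int(x.max()), params)
    terms = transition_logprob_pairs(x[1:], x[:-1], params.alpha, lp)
    total = float(terms.sum())
    if initial == "conditioning":
        return total
    if initial == "stationary":
        pi = stationary_distribution(params)
        first = pi[x[0]] if x[0] < pi.size else 0.0
        return total + max(math.log(first) if first > 0 else -math.inf, LOG_FLOOR)
    raise ValueError(f"unknown initial option {initial!r}")


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


def stationary_moments(params: ModelParams, max_lag: int = 1) -> MomentSummary:
    """Stationary mean, variance, autocovariances and dispersion index."""
    a, th = params.alpha, params.theta
    mu_eps = th * math.exp(th)
    mu = mu_eps / (1.0 - a)
    var = mu_eps * (1.0 + a + th) / (1.0 - a**2)
    lags = np.arange(1, max_lag + 1)
    rho = a**lags
    return MomentSummary(
        mean=mu,
        variance=var,
        autocovariance=rho * var,
        autocorrelation=rho,
        dispersion_index=1.0 + th / (1.0 + a),
        lags=lags,
    )


def conditional_moments(x_prev: int, params: ModelParams) -> tuple[float, float]:
    """One-step conditional mean and variance given X_{t-1} = x_prev.

    mean = alpha x + theta e^theta;
    var  = alpha (1 - alpha) x + theta (1 + theta) e^theta.
    """
    if x_prev < 0:
        raise ValueError("conditioning value must be non-negative")
    a = params.alpha
    mu_eps, var_eps = bell_moments(params.innovation)
    return a * x_prev + mu_eps, a * (1.0 - a) * x_prev + var_eps


def k_step_moments(x_t: int, k: int, params: ModelParams) -> tuple[float, float]:
    """k-step-ahead conditional mean and variance given X_t = x_t.

    mean_k = a^k x + mu_eps (1 - a^k)/(1 - a)
    var_k  = a^k (1 - a^k) x + mu_eps (a - a^k)(1 - a^k)/(1 - a^2)
             + sig_eps^2 (1 - a^{2k})/(1 - a^2)

    As k -> infinity both converge to the stationary mean and variance.
    """
    if k < 1:
        raise ValueError("horizon k must be >= 1")
    if x_t < 0:
        raise ValueError("conditioning value must be non-negative")
    a = params.alpha
    mu_eps, var_eps = bell_moments(params.innovation)
    ak = a**k
    mean = ak * x_t + mu_eps * (1.0 - ak) / (1.0 - a)
    var = (
        ak * (1.0 - ak) * x_t
        + mu_eps * (a - ak) * (1.0 - ak) / (1.0 - a**2)
        + var_eps * (1.0 - a ** (2 * k)) / (1.0 - a**2)
    )
    return mean, var
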