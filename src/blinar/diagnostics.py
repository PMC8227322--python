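"""Model adequacy and comparison tools for INAR(1) count models.

The INAR(1) skeleton ``X_t = alpha o X_{t-1} + eps_t`` is agnostic to the
innovation law: this module makes the innovation family pluggable
(`InnovationFamily`) and provides conditional maximum likelihood for any
family, the four usual information criteria, Pearson residuals, the
Ljung-Box portmanteau test, dispersion-index screening with a parametric
bootstrap overdispersion test against the equidispersed Poisson-INAR(1)
null, multi-step forecasting, and holdout forecast RMSE — everything
needed to ask "which innovation law fits this count series best?".

Bell, Poisson and geometric families ship ready-made; supplying another
family is a matter of filling in the dataclass fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.diagnostic import acorr_ljungbox

from . import bell as _bell
from .bell import _as_rng, theta_from_mean
from .estimation import (
    ALPHA_CLIP,
    FitResult,
    _pair_summary,
    _pairs_loglik,
    fit_yw,
)
from .process import CountSeries, ModelParams, k_step_moments


# ---------------------------------------------------------------------------
# innovation families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InnovationFamily:
    """A parametric innovation law for the INAR(1) recursion.

    ``logpmf(k, params)`` must accept an integer array and return log
    probabilities; ``to_unconstrained``/``from_unconstrained`` map the
    natural parameter tuple to an unconstrained optimization scale and
    back; ``init_from_moments`` proposes starting values from an
    innovation-scale mean/variance pair.
    """

    name: str
    n_params: int
    param_names: tuple
    logpmf: Callable
    mean: Callable
    variance: Callable
    sample: Callable  # (params, n, rng) -> int array
    init_from_moments: Callable
    to_unconstrained: Callable
    from_unconstrained: Callable


def _bell_logpmf(k, params):
    return _bell.bell_logpmf(np.asarray(k), _bell.BellParam(params[0]))


BELL = InnovationFamily(
    name="bell",
    n_params=1,
    param_names=("theta",),
    logpmf=_bell_logpmf,
    mean=lambda p: p[0] * math.exp(p[0]),
    variance=lambda p: p[0] * (1 + p[0]) * math.exp(p[0]),
    sample=lambda p, n, rng: _bell.bell_sample(_bell.BellParam(p[0]), n, rng),
    init_from_moments=lambda m, v: (theta_from_mean(max(m, 1e-3)).theta,),
    to_unconstrained=lambda p: (math.log(p[0]),),
    from_unconstrained=lambda u: (math.exp(u[0]),),
)

POISSON = InnovationFamily(
    name="poisson",
    n_params=1,
    param_names=("lambda",),
    logpmf=lambda k, p: stats.poisson.logpmf(np.asarray(k), p[0]),
    mean=lambda p: p[0],
    variance=lambda p: p[0],
    sample=lambda p, n, rng: rng.poisson(p[0], size=n).astype(np.int64),
    init_from_moments=lambda m, v: (max(m, 1e-3),),
    to_unconstrained=lambda p: (math.log(p[0]),),
    from_unconstrained=lambda u: (math.exp(u[0]),),
)

# Geometric on {0, 1, 2, ...} with success probability pi:
# P(k) = pi (1 - pi)^k, mean (1 - pi)/pi, variance (1 - pi)/pi^2.
GEOMETRIC = InnovationFamily(
    name="geometric",
    n_params=1,
    param_names=("pi",),
    logpmf=lambda k, p: math.log(p[0]) + np.asarray(k) * math.log1p(-p[0]),
    mean=lambda p: (1 - p[0]) / p[0],
    variance=lambda p: (1 - p[0]) / p[0] ** 2,
    sample=lambda p, n, rng: (rng.geometric(p[0], size=n) - 1).astype(np.int64),
    init_from_moments=lambda m, v: (1.0 / (1.0 + max(m, 1e-3)),),
    to_unconstrained=lambda p: (float(special.logit(p[0])),),
    from_unconstrained=lambda u: (float(special.expit(u[0])),),
)

FAMILIES = {f.name: f for f in (BELL, POISSON, GEOMETRIC)}


def simulate_inar(
    alpha: float,
    family: InnovationFamily,
    params: tuple,
    T: int,
    burnin: int = 500,
    seed=None,
) -> CountSeries:
    """Simulate an INAR(1) path with an arbitrary innovation family."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = _as_rng(seed)
    total = T + burnin
    innov = family.sample(params, total, rng)
    x = int(innov[0])
    path = np.empty(total, dtype=np.int64)
    for t in range(total):
        x = int(rng.binomial(x, alpha)) + int(innov[t])
        path[t] = x
    return CountSeries(path[burnin:])


# ---------------------------------------------------------------------------
# generalized CML
# ---------------------------------------------------------------------------


def fit_inar_cml(
    series: CountSeries,
    family: InnovationFamily = BELL,
    init: tuple | None = None,
) -> FitResult:
    """Conditional maximum likelihood for an INAR(1) with any innovation law.

    Maximizes ``sum_t log sum_m C(x_t, m) a^m (1-a)^{x_t - m}
    pmf_eps(x_{t+1} - m)`` over (alpha, family parameters), BFGS on the
    unconstrained scale.  ``init``, when given, is (alpha, *family
    params).  For the Bell family this is the same optimum as
    `estimation.fit_cml`.
    """
    x = series.values
    if x.size < 3:
        raise ValueError("need at least three observations")
    j, i, counts = _pair_summary(x)
    kmax = int(x.max())
    kvals = np.arange(kmax + 1)

    if init is None:
        yw = fit_yw(series)
        alpha0 = float(np.clip(yw.alpha_hat, *ALPHA_CLIP))
        mean_eps = max(yw.mu_hat * (1 - alpha0), 1e-3)
        fam0 = family.init_from_moments(mean_eps, mean_eps)
    else:
        alpha0, fam0 = float(init[0]), tuple(init[1:])

    def negll(u):
        alpha = float(special.expit(u[0]))
        if not 1e-12 < alpha < 1 - 1e-12:
            return 1e12
        try:
            fam = family.from_unconstrained(u[1:])
        except (OverflowError, ValueError):
            return 1e12
        with np.errstate(divide="ignore"):
            lp = np.asarray(family.logpmf(kvals, fam), dtype=float)
        if np.any(np.isnan(lp)):
            return 1e12
        return -_pairs_loglik(j, i, counts, alpha, lp)

    u0 = np.concatenate([[special.logit(alpha0)], family.to_unconstrained(fam0)])
    res = optimize.minimize(negll, u0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 200})
    alpha_hat = float(special.expit(res.x[0]))
    fam_hat = family.from_unconstrained(res.x[1:])
    mu_hat = family.mean(fam_hat) / (1.0 - alpha_hat)
    out = FitResult(
        method=f"CML[{family.name}]",
        alpha_hat=alpha_hat,
        theta_hat=float(fam_hat[0]) if family.name == "bell" else math.nan,
        mu_hat=mu_hat,
        loglik=-float(res.fun),
        converged=bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3,
        n_used=x.size - 1,
    )
    out.family_params = tuple(float(v) for v in fam_hat)  # type: ignore[attr-defined]
    if not out.converged:
        out.flags.append("optimizer-not-converged")
    return out


# ---------------------------------------------------------------------------
# criteria, residuals, tests
# ---------------------------------------------------------------------------


def information_criteria(loglik: float, n_params: int, n_obs: int):
    """(AIC, BIC, CAIC, HQIC) from a log-likelihood.

    AIC = -2L + 2k; BIC = -2L + k ln n; CAIC = -2L + k (ln n + 1);
    HQIC = -2L + 2k ln ln n.  For conditional likelihoods n is the number
    of transition terms, i.e. T - 1.
    """
    if n_obs <= 1 or n_params < 1:
        raise ValueError("need n_obs >= 2 and n_params >= 1")
    k, L, n = n_params, loglik, n_obs
    return (
        -2 * L + 2 * k,
        -2 * L + k * math.log(n),
        -2 * L + k * (math.log(n) + 1),
        -2 * L + 2 * k * math.log(math.log(n)),
    )


def pearson_residuals(series: CountSeries, params: ModelParams) -> np.ndarray:
    """Standardized one-step prediction errors, length T - 1.

    r_t = (X_t - E[X_t|X_{t-1}]) / sd(X_t|X_{t-1}); approximately white
    with unit variance when the model is correct.
    """
    x = series.values.astype(float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    a = params.alpha
    mu_eps, var_eps = _bell.bell_moments(params.innovation)
    cmean = a * x[:-1] + mu_eps
    cvar = a * (1 - a) * x[:-1] + var_eps
    return (x[1:] - cmean) / np.sqrt(cvar)


def ljung_box(x, lags: int = 10, model_df: int = 0) -> tuple[float, float]:
    """Ljung-Box portmanteau statistic and p-value at the given lag.

    Q = n(n+2) sum_{k<=lags} rho_k^2/(n-k), referred to chi-square with
    ``lags - model_df`` degrees of freedom (``model_df`` discounts fitted
    parameters when testing residuals).
    """
    arr = np.asarray(x, dtype=float)
    if lags < 1 or arr.size <= lags:
        raise ValueError("need lags >= 1 and more observations than lags")
    if np.std(arr) == 0:
        raise ValueError("degenerate (constant) input")
    res = acorr_ljungbox(arr, lags=[lags], model_df=model_df)
    return float(res["lb_stat"].iloc[0]), float(res["lb_pvalue"].iloc[0])


def dispersion_index(series: CountSeries) -> float:
    """Sample variance (denominator T - 1) over sample mean."""
    x = series.values.astype(float)
    if x.mean() == 0:
        raise ValueError("zero-mean series: dispersion index undefined")
    return float(x.var(ddof=1) / x.mean())


def overdispersion_test(
    series: CountSeries, B: int = 499, level: float = 0.05, seed=None
) -> tuple[float, float, bool]:
    """Parametric-bootstrap overdispersion test against Poisson-INAR(1).

    Fits the equidispersed Poisson-innovation INAR(1) null by CML,
    simulates B null paths of the observed length, and compares the
    observed dispersion index with the empirical (1 - level) quantile of
    the null indices.  Returns (index, critical value, reject flag).
    """
    if len(series) < 30:
        raise ValueError("need at least 30 observations")
    if B < 199:
        raise ValueError("need at least 199 bootstrap replicates")
    null_fit = fit_inar_cml(series, POISSON)
    if not null_fit.converged:
        raise RuntimeError("null Poisson-INAR(1) fit failed to converge")
    lam = null_fit.family_params  # type: ignore[attr-defined]
    rng = _as_rng(seed)
    idx = np.empty(B)
    for b in range(B):
        sim = simulate_inar(null_fit.alpha_hat, POISSON, lam, len(series),
                            burnin=100, seed=rng)
        idx[b] = dispersion_index(sim)
    crit = float(np.quantile(idx, 1.0 - level))
    obs = dispersion_index(series)
    return obs, crit, obs > crit


# ---------------------------------------------------------------------------
# forecasting and comparison
# ---------------------------------------------------------------------------


def forecast(series: CountSeries, params: ModelParams, h: int) -> list[tuple[float, float]]:
    """k-step-ahead conditional (mean, variance), k = 1..h, from the last observation."""
    if h < 1:
        raise ValueError("horizon must be >= 1")
    last = int(series.values[-1])
    return [k_step_moments(last, k, params) for k in range(1, h + 1)]


def _inar_forecast_means(alpha: float, mu_eps: float, x_anchor: int, h: int) -> np.ndarray:
    k = np.arange(1, h + 1)
    return alpha**k * x_anchor + mu_eps * (1 - alpha**k) / (1 - alpha)


def rmse_holdout(series: CountSeries, family: InnovationFamily = BELL, h: int = 6) -> float:
    """Holdout forecast RMSE: fit on the first T-h points, predict the last h.

    Forecasts are the conditional means anchored at observation T-h
    (real-valued point forecasts); RMSE = sqrt(mean((X - Xhat)^2)).
    """
    x = series.values
    if not 1 <= h < x.size:
        raise ValueError("need T > h >= 1")
    fit = fit_inar_cml(CountSeries(x[: x.size - h]), family)
    mu_eps = family.mean(fit.family_params)  # type: ignore[attr-defined]
    preds = _inar_forecast_means(fit.alpha_hat, mu_eps, int(x[x.size - h - 1]), h)
    return float(np.sqrt(np.mean((x[x.size - h:] - preds) ** 2)))


@dataclass
class ComparisonRow:
    """One line of an innovation-family comparison table."""

    model: str
    estimates: dict
    aic: float
    bic: float
    caic: float
    hqic: float
    fitted_mean: float
    fitted_variance: float
    rmse: float | None = None
    converged: bool = True
    error: str | None = None


def compare_models(
    series: CountSeries,
    families: Sequence[InnovationFamily] = (BELL, POISSON, GEOMETRIC),
    h: int | None = 6,
) -> list[ComparisonRow]:
    """Fit several innovation families and rank them by AIC.

    Each row carries the CML estimates, AIC/BIC/CAIC/HQIC, the fitted
    stationary mean and variance implied by that family
    (mu = mu_eps/(1-a), sigma^2 = (sigma_eps^2 + a mu_eps)/(1-a^2)), and
    the holdout RMSE when ``h`` is given.  Per-family failures are
    recorded in the row and do not interrupt the comparison.
    """
    if not families:
        raise ValueError("need at least one innovation family")
    rows: list[ComparisonRow] = []
    n = len(series) - 1
    for fam in families:
        try:
            fit = fit_inar_cml(series, fam)
            fp = fit.family_params  # type: ignore[attr-defined]
            k = 1 + fam.n_params
            aic, bic, caic, hqic = information_criteria(fit.loglik, k, n)
            a = fit.alpha_hat
            mu_eps, var_eps = fam.mean(fp), fam.variance(fp)
            est = {"alpha": a, **dict(zip(fam.param_names, fp))}
            rmse = rmse_holdout(series, fam, h) if h else None
            rows.append(ComparisonRow(
                model=f"{fam.name}-INAR(1)", estimates=est,
                aic=aic, bic=bic, caic=caic, hqic=hqic,
                fitted_mean=mu_eps / (1 - a),
                fitted_variance=(var_eps + a * mu_eps) / (1 - a**2),
                rmse=rmse, converged=fit.converged,
            ))
        except Exception as exc:  # noqa: BLE001 — per-row fault isolation
            rows.append(ComparisonRow(
                model=f"{fam.name}-INAR(1)", estimates={}, aic=math.inf,
                bic=math.inf, caic=math.inf, hqic=math.inf,
                fitted_mean=math.nan, fitted_variance=math.nan,
                converged=False, error=str(exc),
            ))
    rows.sort(key=lambda r: r.aic)
    return rows
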