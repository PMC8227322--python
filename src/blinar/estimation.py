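"""Parameter estimation for the BL-INAR(1) model.

Three estimators of (alpha, theta) are provided:

* **CLS** — conditional least squares: minimize
  ``sum_{t=2}^T (X_t - E[X_t | X_{t-1}])^2``.  Because the conditional
  mean is affine, alpha-hat and mu-hat have closed forms; theta-hat then
  solves ``theta e^theta = mu_hat (1 - alpha_hat)`` by Lambert W.
* **YW** — Yule-Walker: alpha-hat is the lag-1 sample autocorrelation
  (rho_k = alpha^k for this process) and mu-hat the sample mean; CLS and
  YW are asymptotically equivalent (their difference is o_p(T^{-1/2})).
* **CML** — conditional maximum likelihood: maximize the log-likelihood
  conditional on X_1, a sum of log one-step transition probabilities,
  by BFGS on the unconstrained scale (logit alpha, log theta) with
  Yule-Walker starting values.

`cls_asymptotic_cov` evaluates the asymptotic covariance of
sqrt(T) (alpha_hat_CLS - alpha, mu_hat_CLS - mu) from the standard
conditional-least-squares sandwich V^{-1} W V^{-1} (V the second-moment
matrix of the regressor (X_{t-1}, 1), W its conditional-variance-weighted
version), transformed from the (alpha, mu_eps) scale to (alpha, mu); the
third raw moment of the stationary law enters through W and is computed
from the stationarity recursion with the Bell third cumulant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .bell import (
    bell_moments,
    bell_third_cumulant,
    theta_from_mean,
)
from .process import (
    CountSeries,
    ModelParams,
    _innov_logpmf_vector,
    transition_logprob_pairs,
)

ALPHA_CLIP = (0.001, 0.999)


@dataclass
class FitResult:
    """Result of one estimation run."""

    method: str
    alpha_hat: float
    theta_hat: float  # nan when mu_hat (1 - alpha_hat) <= 0
    mu_hat: float
    loglik: float | None = None
    cov: np.ndarray | None = None
    converged: bool = True
    n_used: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def params(self) -> ModelParams:
        if not np.isfinite(self.theta_hat) or not (0 < self.alpha_hat < 1):
            raise ValueError(f"fit does not define valid model parameters: {self}")
        return ModelParams(self.alpha_hat, self.theta_hat)


@dataclass(frozen=True)
class AsymptoticCov:
    """Asymptotic covariance Sigma of sqrt(T)(alpha_hat, mu_hat) and E[X^3]."""

    sigma_matrix: np.ndarray
    mu3: float


def _check_series(series: CountSeries, min_T: int = 3) -> np.ndarray:
    x = series.values.astype(float)
    if x.size < min_T:
        raise ValueError(f"need at least {min_T} observations, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("constant series: estimators are degenerate (zero denominator)")
    return x


def _attach_theta(res: FitResult) -> FitResult:
    m = res.mu_hat * (1.0 - res.alpha_hat)
    if m > 0:
        res.theta_hat = theta_from_mean(m).theta
    else:
        res.theta_hat = math.nan
        res.flags.append("theta-undefined")
    if not 0.0 < res.alpha_hat < 1.0:
        res.flags.append("alpha-outside-(0,1)")
    return res


def fit_cls(series: CountSeries) -> FitResult:
    """Closed-form conditional least squares estimate of (alpha, mu, theta).

    Sums run over t = 2..T exactly; the reported mu-hat is the process
    mean (innovation mean divided by 1 - alpha-hat).
    """
    x = _check_series(series)
    T = x.size
    xc, xp = x[1:], x[:-1]  # current t=2..T, previous t=1..T-1
    n = T - 1
    denom = n * np.sum(xp**2) - np.sum(xp) ** 2
    if denom == 0:
        raise ValueError("degenerate series: CLS denominator is zero")
    alpha = (n * np.sum(xc * xp) - np.sum(xc) * np.sum(xp)) / denom
    if alpha == 1.0:
        raise ValueError("degenerate series: alpha-hat = 1 leaves mu undefined")
    mu = (np.sum(xc) - alpha * np.sum(xp)) / (n * (1.0 - alpha))
    return _attach_theta(
        FitResult(method="CLS", alpha_hat=float(alpha), theta_hat=math.nan,
                  mu_hat=float(mu), n_used=n)
    )


def fit_yw(series: CountSeries) -> FitResult:
    """Yule-Walker estimate: lag-1 sample autocorrelation and sample mean."""
    x = _check_series(series)
    xbar = x.mean()
    num = np.sum((x[:-1] - xbar) * (x[1:] - xbar))
    den = np.sum((x - xbar) ** 2)
    alpha = num / den
    return _attach_theta(
        FitResult(method="YW", alpha_hat=float(alpha), theta_hat=math.nan,
                  mu_hat=float(xbar), n_used=x.size - 1)
    )


# ---------------------------------------------------------------------------
# conditional likelihood
# ---------------------------------------------------------------------------


def _pair_summary(x: np.ndarray):
    """Unique (previous, next) transition pairs with multiplicities.

    Collapsing repeated transitions makes a T = 1000 likelihood evaluation
    cost a few hundred log-sum-exp rows instead of a thousand.
    """
    xp, xn = x[:-1].astype(np.int64), x[1:].astype(np.int64)
    width = int(xn.max()) + 1
    codes, counts = np.unique(xp * width + xn, return_counts=True)
    return codes // width, codes % width, counts.astype(float)


def _pairs_loglik(j, i, counts, alpha: float, innov_logpmf: np.ndarray) -> float:
    terms = transition_logprob_pairs(i, j, alpha, innov_logpmf)
    return float(counts @ terms)


def conditional_loglik(series: CountSeries, params: ModelParams) -> float:
    """Conditional log-likelihood L = sum_t log P(X_{t+1} | X_t)."""
    x = series.values
    if x.size < 2:
        raise ValueError("need at least two observations")
    j, i, counts = _pair_summary(x)
    lp = _innov_logpmf_vector(int(x.max()), params)
    return _pairs_loglik(j, i, counts, params.alpha, lp)


def _cml_init(series: CountSeries, init: ModelParams | None) -> ModelParams:
    if init is not None:
        return init
    yw = fit_yw(series)
    alpha0 = float(np.clip(yw.alpha_hat, *ALPHA_CLIP))
    m = yw.mu_hat * (1.0 - alpha0)
    theta0 = theta_from_mean(m).theta if m > 0 else 0.1
    return ModelParams(alpha0, max(theta0, 1e-4))


def fit_cml(
    series: CountSeries,
    init: ModelParams | None = None,
    compute_cov: bool = False,
) -> FitResult:
    """Conditional maximum likelihood by BFGS with Yule-Walker start.

    The optimizer works on (logit alpha, log theta) so the search is
    unconstrained; gradients are numerical.  Non-convergence is reported
    through ``converged``/``flags``, never raised.  With
    ``compute_cov=True`` the observed-information covariance (inverse
    numerical Hessian on the natural scale) is attached.
    """
    x = _check_series(series)
    start = _cml_init(series, init)
    j, i, counts = _pair_summary(series.values)
    kmax = int(series.values.max())

    def negll_u(u: np.ndarray) -> float:
        alpha = float(special.expit(u[0]))
        theta = float(math.exp(u[1]))
        if not (1e-12 < alpha < 1 - 1e-12) or not (1e-12 < theta < 50):
            return 1e12
        lp = _innov_logpmf_vector(kmax, ModelParams(alpha, theta))
        return -_pairs_loglik(j, i, counts, alpha, lp)

    u0 = np.array([special.logit(start.alpha), math.log(start.theta)])
    res = optimize.minimize(negll_u, u0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 200})
    alpha_hat = float(special.expit(res.x[0]))
    theta_hat = float(math.exp(res.x[1]))
    mu_hat = theta_hat * math.exp(theta_hat) / (1.0 - alpha_hat)
    out = FitResult(
        method="CML",
        alpha_hat=alpha_hat,
        theta_hat=theta_hat,
        mu_hat=mu_hat,
        loglik=-float(res.fun),
        converged=bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3,
        n_used=x.size - 1,
    )
    if not out.converged:
        out.flags.append("optimizer-not-converged")
    if compute_cov:
        out.cov = _observed_info_cov(j, i, counts, kmax, alpha_hat, theta_hat)
    return out


def _observed_info_cov(j, i, counts, kmax, alpha, theta, h_rel=1e-4):
    def nll(a, t):
        lp = _innov_logpmf_vector(kmax, ModelParams(a, t))
        return -_pairs_loglik(j, i, counts, a, lp)

    ha = h_rel * max(alpha * (1 - alpha), 1e-3)
    ht = h_rel * max(theta, 1e-3)
    H = np.empty((2, 2))
    f0 = nll(alpha, theta)
    H[0, 0] = (nll(alpha + ha, theta) - 2 * f0 + nll(alpha - ha, theta)) / ha**2
    H[1, 1] = (nll(alpha, theta + ht) - 2 * f0 + nll(alpha, theta - ht)) / ht**2
    H[0, 1] = H[1, 0] = (
        nll(alpha + ha, theta + ht)
        - nll(alpha + ha, theta - ht)
        - nll(alpha - ha, theta + ht)
        + nll(alpha - ha, theta - ht)
    ) / (4 * ha * ht)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((2, 2), np.nan)


# ---------------------------------------------------------------------------
# asymptotics
# ---------------------------------------------------------------------------


def third_raw_moment(params: ModelParams) -> float:
    """Stationary third raw moment mu3 = E[X_t^3].

    Obtained by taking third moments in X = alpha o Y + eps with Y
    distributed as the stationary law (binomial third moment inside,
    Bell moments for eps) and solving the linear fixed-point equation;
    the innovation enters through its first three raw moments.
    """
    a = params.alpha
    mu_e, var_e = bell_moments(params.innovation)
    k3_e = bell_third_cumulant(params.innovation)
    m2_e = var_e + mu_e**2
    m3_e = k3_e + 3.0 * var_e * mu_e + mu_e**3
    mu = mu_e / (1.0 - a)
    m2 = mu_e * (1.0 + a + params.theta) / (1.0 - a**2) + mu**2
    num = (
        a * (1 - a) * (1 - 2 * a) * mu
        + 3 * a**2 * (1 - a) * m2
        + 3 * mu_e * (a * (1 - a) * mu + a**2 * m2)
        + 3 * a * mu * m2_e
        + m3_e
    )
    return num / (1.0 - a**3)


def cls_asymptotic_cov(params: ModelParams) -> AsymptoticCov:
    """Asymptotic covariance Sigma of sqrt(T)(alpha_hat_CLS - alpha, mu_hat_CLS - mu).

    Sandwich form for least squares with regressor z_t = (X_{t-1}, 1) and
    conditional variance v(x) = alpha(1-alpha) x + sigma_eps^2:

        A = V^{-1} W V^{-1},  V = E[z z'],  W = E[v(X) z z'],

    giving the covariance of (alpha_hat, mu_eps_hat); the Jacobian of
    (alpha, mu_eps) -> (alpha, mu = mu_eps/(1-alpha)) maps it to the
    reported scale.
    """
    a = params.alpha
    mu_e, var_e = bell_moments(params.innovation)
    mom_mu = mu_e / (1.0 - a)
    mom_var = mu_e * (1.0 + a + params.theta) / (1.0 - a**2)
    m2 = mom_var + mom_mu**2
    mu3 = third_raw_moment(params)

    V = np.array([[m2, mom_mu], [mom_mu, 1.0]])
    X_zz = np.array([[mu3, m2], [m2, mom_mu]])  # E[X z z']
    W = a * (1 - a) * X_zz + var_e * V
    Vinv = np.linalg.inv(V)
    A = Vinv @ W @ Vinv
    J = np.array([[1.0, 0.0], [mom_mu / (1.0 - a), 1.0 / (1.0 - a)]])
    sigma = J @ A @ J.T
    sigma = 0.5 * (sigma + sigma.T)
    return AsymptoticCov(sigma_matrix=sigma, mu3=mu3)


def delta_theta_se(fit: FitResult, acov: AsymptoticCov) -> float:
    """Delta-method standard error of theta-hat from the CLS asymptotics.

    theta = W(mu (1 - alpha)) with W the principal Lambert W branch and
    dW/dx = W / (x (1 + W)); the gradient in (alpha, mu) contracts the
    Sigma/T covariance.
    """
    alpha, mu = fit.alpha_hat, fit.mu_hat
    x = mu * (1.0 - alpha)
    if x <= 0 or not (0 < alpha < 1):
        raise ValueError("boundary estimates: delta-method SE undefined")
    w = float(special.lambertw(x).real)
    wprime = w / (x * (1.0 + w))
    grad = np.array([-mu * wprime, (1.0 - alpha) * wprime])
    T = fit.n_used + 1
    var = float(grad @ acov.sigma_matrix @ grad) / T
    return math.sqrt(max(var, 0.0))
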