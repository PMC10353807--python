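"""Quantile regression for unit-interval responses under the UEL law.

The distribution is reparametrized in its q-th quantile mu: solving the
quantile function for the scale parameter gives

    lam = (1 - A(q, theta)^(-1/delta)) / ln(mu),      A(q, theta) = 1 - (1-q)^(1/theta),

which is strictly positive because both the numerator and ln(mu) are
negative.  Covariates then model mu through a monotone link g on (0,1):
g(mu_i) = x_i' B.  Only the logit link is fully supported (coefficients are
log-odds of the conditional quantile); probit and complementary log-log are
wired behind the same interface but considered experimental.

The regression log-likelihood is the sum of UEL log-densities with the
per-observation scale lam_i substituted — the direct-substitution form is
used throughout because it is sign-safe for mu in (0,1), where ln(mu) is
negative (its log appears only through ln(-ln mu)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .distribution import UELParams, quantile

__all__ = [
    "QuantileParams",
    "RegressionFit",
    "lambda_from_mu",
    "link_logit",
    "link_logit_inverse",
    "inverse_link",
    "apply_link",
    "reg_loglik",
    "fit_regression",
    "predict_quantile",
    "LINKS",
]

_LOG_SHAPE_BOUNDS = (-12.0, 12.0)


@dataclass(frozen=True)
class QuantileParams:
    """(mu, delta, theta; q) parametrization of the UEL distribution."""

    mu: float
    delta: float
    theta: float
    q: float = 0.5

    def __post_init__(self):
        if not (0 < self.mu < 1):
            raise ValueError("mu must lie strictly in (0, 1)")
        if not (0 < self.q < 1):
            raise ValueError("q must lie strictly in (0, 1)")
        if self.delta <= 0 or self.theta <= 0:
            raise ValueError("delta and theta must be > 0")

    def to_uel(self) -> UELParams:
        return UELParams(
            self.delta, lambda_from_mu(self.mu, self.delta, self.theta, self.q), self.theta
        )


@dataclass
class RegressionFit:
    coefficients: np.ndarray
    delta: float
    theta: float
    se: np.ndarray | None
    vcov: np.ndarray | None
    loglik: float
    aic: float
    bic: float
    n: int
    q: float
    link: str
    converged: bool
    column_names: list[str] | None = None


def lambda_from_mu(mu, delta, theta, q=0.5):
    """Scale parameter implied by the q-th quantile mu (vectorized)."""
    mu = np.asarray(mu, dtype=float)
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly in (0, 1)")
    if not (0 < q < 1):
        raise ValueError("q must lie strictly in (0, 1)")
    # A = 1-(1-q)^(1/theta); numerator 1 - A^(-1/delta) < 0, ln(mu) < 0
    log_a = math.log(-math.expm1(math.log1p(-q) / theta))
    num = -np.expm1(-log_a / delta)
    out = num / np.log(mu)
    return out if out.ndim else float(out)


def link_logit(mu):
    """Logit link g(mu) = ln(mu/(1-mu))."""
    return special.logit(mu)


def link_logit_inverse(eta):
    """Numerically stable logistic; saturates inside (0, 1) at the extremes."""
    out = special.expit(np.asarray(eta, dtype=float))
    tiny = np.finfo(float).tiny
    out = np.clip(out, tiny, 1.0 - np.finfo(float).epsneg)
    return out if out.ndim else float(out)


LINKS = {
    "logit": (link_logit, link_logit_inverse),
    # experimental alternatives
    "probit": (
        lambda mu: special.ndtri(np.asarray(mu, dtype=float)),
        lambda eta: np.clip(special.ndtr(np.asarray(eta, dtype=float)), 1e-15, 1 - 1e-15),
    ),
    "cloglog": (
        lambda mu: np.log(-np.log1p(-np.asarray(mu, dtype=float))),
        lambda eta: np.clip(-np.expm1(-np.exp(np.asarray(eta, dtype=float))), 1e-15, 1 - 1e-15),
    ),
}


def apply_link(mu, link: str = "logit"):
    return LINKS[link][0](mu)


def inverse_link(eta, link: str = "logit"):
    return LINKS[link][1](eta)


def _validate_design(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.size != n:
            raise ValueError("response length does not match design")
        bad = np.nonzero(~((y > 0) & (y < 1)))[0]
        if bad.size:
            raise ValueError(
                f"responses must lie strictly in (0, 1); offending indices: {bad[:10].tolist()}"
            )
        if p >= n:
            raise ValueError("need more observations than parameters")
    return X, y


def reg_loglik(B, delta, theta, X, y, q=0.5, link: str = "logit") -> float:
    """Regression log-likelihood by direct substitution of lam_i.

    Equals the sum of UEL log-densities with lam_i = lambda_from_mu(mu_i)
    and mu_i = linkinv(x_i' B).
    """
    X, y = _validate_design(X, y)
    B = np.asarray(B, dtype=float)
    mu = inverse_link(X @ B, link)
    lam = lambda_from_mu(mu, delta, theta, q)
    ly = np.log(y)
    lt = np.log1p(-lam * ly)
    lomu = np.log1p(-np.exp(-delta * lt))
    return float(
        np.sum(np.log(lam * delta * theta) - ly - (delta + 1) * lt + (theta - 1) * lomu)
    )


def fit_regression(
    X,
    y,
    q: float = 0.5,
    init=None,
    link: str = "logit",
    column_names=None,
) -> RegressionFit:
    """ML fit of the UEL quantile-regression model.

    Coefficients are unconstrained; the shape parameters are optimized on
    the log scale.  Starting coefficients come from least squares of the
    linked response on X (with a multi-start fallback over the shape
    parameters); the covariance is the inverse observed information.
    """
    X, y = _validate_design(X, y)
    n, p = X.shape

    eta0, *_ = np.linalg.lstsq(X, apply_link(y, link), rcond=None)
    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    for ls in (0.0, math.log(5.0)):
        for lth in (0.0, math.log(5.0)):
            starts.append(np.concatenate([eta0, [ls, lth]]))

    ly = np.log(y)

    def nll(z):
        B = z[:p]
        d, t = np.exp(z[p:])
        with np.errstate(all="ignore"):
            mu = inverse_link(X @ B, link)
            log_a = math.log(-math.expm1(math.log1p(-q) / t))
            lam = -np.expm1(-log_a / d) / np.log(mu)
            lt = np.log1p(-lam * ly)
            lomu = np.log1p(-np.exp(-d * lt))
            val = -np.sum(np.log(lam * d * t) - ly - (d + 1) * lt + (t - 1) * lomu)
        return val if np.isfinite(val) else 1e12

    bounds = [(None, None)] * p + [_LOG_SHAPE_BOUNDS] * 2
    best = None
    for st in starts:
        res = optimize.minimize(
            nll, st, method="L-BFGS-B", bounds=bounds, options={"maxiter": 1000, "ftol": 1e-13}
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e11:
        raise RuntimeError("regression optimization failed from all starting points")

    z = best.x
    B = z[:p]
    delta, theta = np.exp(z[p:])
    ll = -best.fun

    vcov = se = None
    try:
        h = _numeric_hessian(nll, z)
        cov_z = np.linalg.inv(h)
        if np.all(np.isfinite(cov_z)) and np.all(np.diag(cov_z) > 0):
            # delta method for the two log-scale shape entries
            jac = np.ones(p + 2)
            jac[p] = delta
            jac[p + 1] = theta
            vcov = cov_z * np.outer(jac, jac)
            se = np.sqrt(np.diag(vcov))
    except np.linalg.LinAlgError:
        pass

    k = p + 2
    return RegressionFit(
        coefficients=B,
        delta=float(delta),
        theta=float(theta),
        se=se,
        vcov=vcov,
        loglik=ll,
        aic=2 * k - 2 * ll,
        bic=k * math.log(n) - 2 * ll,
        n=n,
        q=q,
        link=link,
        converged=bool(best.success),
        column_names=list(column_names) if column_names is not None else None,
    )


def _numeric_hessian(fun, x, step: float = 1e-4) -> np.ndarray:
    k = x.size
    h = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            if i == j:
                h[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step**2
            else:
                h[i, j] = h[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * step**2)
    return h


def predict_quantile(fit: RegressionFit, X_new) -> np.ndarray:
    """Fitted conditional q-th quantiles ``linkinv(x' B)`` for new rows."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != fit.coefficients.size:
        raise ValueError(
            f"X_new must have {fit.coefficients.size} columns to match the fit"
        )
    return inverse_link(X_new @ fit.coefficients, fit.link)
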