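"""Frequentist estimation for the UEL distribution.

Two point estimators are provided: maximum likelihood (ML) and maximum
product of spacings (MPS).  Both maximize their objective over the positive
octant by quasi-Newton iteration on log-parameters, so positivity is
enforced by construction.  The ML path uses the closed-form score (chain
ruled onto the log scale); MPS uses finite-difference gradients because its
objective involves differences of CDF values.

Interval procedures: normal-theory (asymptotic) intervals from the inverse
observed information, and nonparametric bootstrap intervals in percentile
(BP) and studentized (BT) flavours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .distribution import UELParams, cdf, logpdf

__all__ = [
    "FitResult",
    "IntervalSet",
    "loglik",
    "score",
    "fit_mle",
    "mps_objective",
    "fit_mps",
    "asymptotic_ci",
    "bootstrap_ci",
]

_PARAM_NAMES = ("delta", "lam", "theta")
# box for the optimizer on the log scale; wide enough for the extreme
# ridge solutions seen in real-data fits while avoiding overflow
_LOG_BOUNDS = (-12.0, 12.0)
_DEFAULT_GRID = (0.5, 1.0, 5.0)


@dataclass
class FitResult:
    """Point estimates with curvature-based uncertainty for one estimator."""

    estimates: UELParams
    se: np.ndarray | None
    vcov: np.ndarray | None
    objective: float
    method: str
    converged: bool
    n: int
    grad_norm: float = math.nan
    message: str = ""

    @property
    def params_array(self) -> np.ndarray:
        return self.estimates.as_array()


@dataclass
class IntervalSet:
    """Per-parameter confidence/credible limits of one interval type."""

    kind: str
    level: float
    lower: dict[str, float]
    upper: dict[str, float]
    notes: list[str] = field(default_factory=list)

    @property
    def lengths(self) -> dict[str, float]:
        return {k: self.upper[k] - self.lower[k] for k in self.lower}


def _validate_data(data) -> np.ndarray:
    y = np.asarray(data, dtype=float)
    if y.ndim != 1:
        y = y.ravel()
    bad = np.nonzero(~((y > 0) & (y < 1)))[0]
    if bad.size:
        raise ValueError(
            f"observations must lie strictly in (0, 1); offending indices: {bad[:10].tolist()}"
        )
    return y


def loglik(data, params: UELParams) -> float:
    """Log-likelihood of an i.i.d. UEL sample.

    Evaluated from the analytic expansion
    ``n ln(lam*delta*theta) - sum ln y - (delta+1) sum ln(1 - lam ln y)
    + (theta-1) sum ln{1 - (1 - lam ln y)^(-delta)}``,
    which equals the sum of log-densities.
    """
    y = _validate_data(data)
    d, l, t = params.delta, params.lam, params.theta
    ly = np.log(y)
    lt = np.log1p(-l * ly)
    lomu = np.log1p(-np.exp(-d * lt))
    return float(
        y.size * math.log(l * d * t) - ly.sum() - (d + 1) * lt.sum() + (t - 1) * lomu.sum()
    )


def score(data, params: UELParams) -> np.ndarray:
    """Score vector (dl/d delta, dl/d lam, dl/d theta) on the natural scale."""
    y = _validate_data(data)
    d, l, t = params.delta, params.lam, params.theta
    ly = np.log(y)
    big_t = 1.0 - l * ly
    lt = np.log(big_t)
    u = np.exp(-d * lt)
    omu = -np.expm1(-d * lt)
    n = y.size
    gd = n / d - lt.sum() + (t - 1) * (lt * u / omu).sum()
    gt = n / t + np.log(omu).sum()
    gl = n / l + (d + 1) * (ly / big_t).sum() - (t - 1) * d * ((u / big_t) * ly / omu).sum()
    return np.array([gd, gl, gt])


def _nll_and_grad(logp: np.ndarray, y: np.ndarray, ly: np.ndarray):
    """Negative log-likelihood and gradient on the log-parameter scale."""
    d, l, t = np.exp(logp)
    n = y.size
    with np.errstate(all="ignore"):
        big_t = 1.0 - l * ly
        lt = np.log(big_t)
        u = np.exp(-d * lt)
        omu = -np.expm1(-d * lt)
        ll = n * np.log(l * d * t) - ly.sum() - (d + 1) * lt.sum() + (t - 1) * np.log(omu).sum()
        gd = n / d - lt.sum() + (t - 1) * (lt * u / omu).sum()
        gt = n / t + np.log(omu).sum()
        gl = n / l + (d + 1) * (ly / big_t).sum() - (t - 1) * d * ((u / big_t) * ly / omu).sum()
    if not np.isfinite(ll):
        return 1e12, np.zeros(3)
    grad = np.array([gd * d, gl * l, gt * t])
    grad[~np.isfinite(grad)] = 0.0
    return -ll, -grad


def _default_starts(init: UELParams | None) -> list[np.ndarray]:
    starts = [] if init is None else [np.log(init.as_array())]
    starts += [
        np.log([a, b, c])
        for a in _DEFAULT_GRID
        for b in _DEFAULT_GRID
        for c in _DEFAULT_GRID
    ]
    return starts


def _hessian_log_scale(fun, logp: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of ``fun`` at ``logp`` (3x3, symmetric)."""
    k = logp.size
    h = np.empty((k, k))
    f0 = fun(logp)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            if i == j:
                h[i, i] = (fun(logp + ei) - 2 * f0 + fun(logp - ei)) / step**2
            else:
                h[i, j] = h[j, i] = (
                    fun(logp + ei + ej)
                    - fun(logp + ei - ej)
                    - fun(logp - ei + ej)
                    + fun(logp - ei - ej)
                ) / (4 * step**2)
    return h


def _vcov_from_hessian(neg_obj_log, logp: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Back-transform inverse observed information to the natural scale."""
    try:
        h = _hessian_log_scale(neg_obj_log, logp)
        cov_log = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return None, None
    if not np.all(np.isfinite(cov_log)) or np.any(np.diag(cov_log) <= 0):
        return None, None
    # delta method: d(param)/d(log param) = param
    d = np.diag(np.exp(logp))
    vcov = d @ cov_log @ d
    vcov = 0.5 * (vcov + vcov.T)
    return vcov, np.sqrt(np.diag(vcov))


def _maximize(objective, data, init, method_label: str, starts=None, with_vcov=True) -> FitResult:
    y = _validate_data(data)
    if y.size < 4:
        raise ValueError(f"need at least 4 observations to fit 3 parameters, got {y.size}")
    if starts is None:
        starts = _default_starts(init)
    elif init is not None:
        starts = [np.log(init.as_array())] + list(starts)
    best = None
    for st in starts:
        res = optimize.minimize(
            objective,
            np.clip(st, *_LOG_BOUNDS),
            jac=True,
            method="L-BFGS-B",
            bounds=[_LOG_BOUNDS] * 3,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e11:
        raise RuntimeError(f"{method_label} optimization failed from all starting points")
    logp = best.x
    grad_norm = float(np.max(np.abs(best.jac)))
    vcov = se = None
    if with_vcov:
        vcov, se = _vcov_from_hessian(lambda lp: objective(lp)[0], logp)
    d, l, t = np.exp(logp)
    # MPS gradients are finite-difference approximations, so its stationarity
    # check has to be looser than the analytic-gradient ML check
    gtol = 1e-5 if method_label == "ML" else 1e-3
    return FitResult(
        estimates=UELParams(d, l, t),
        se=se,
        vcov=vcov,
        objective=-best.fun,
        method=method_label,
        converged=bool(best.success) and grad_norm < gtol * max(1.0, abs(best.fun)),
        n=y.size,
        grad_norm=grad_norm,
        message=str(best.message),
    )


def fit_mle(data, init: UELParams | None = None, *, starts=None, with_vcov=True) -> FitResult:
    """Maximum-likelihood fit by multi-start quasi-Newton on log-parameters.

    ``starts`` overrides the default 3x3x3 grid of starting values (sequence
    of log-parameter vectors); ``init`` is always tried first when given.
    """
    y = _validate_data(data)
    ly = np.log(y)
    return _maximize(
        lambda lp: _nll_and_grad(lp, y, ly), y, init, "ML", starts=starts, with_vcov=with_vcov
    )


def mps_objective(sorted_data, params: UELParams) -> float:
    """Mean log spacing of CDF values over the n+1 gaps.

    Spacings are ``F(y_(i)) - F(y_(i-1))`` with ``F(y_(0)) = 0`` and
    ``F(y_(n+1)) = 1``.  A zero spacing caused by tied observations is
    replaced by the density at the tied point (Cheng-Amin convention).
    """
    y = np.asarray(sorted_data, dtype=float)
    u = cdf(y, params)
    sp = np.diff(np.concatenate(([0.0], u, [1.0])))
    with np.errstate(divide="ignore"):
        logs = np.log(sp)
    tied = np.nonzero(sp[1:-1] <= 0.0)[0]
    if tied.size:
        logs[tied + 1] = logpdf(y[tied + 1], params)
    if sp[0] <= 0:
        logs[0] = logpdf(y[0], params)
    if sp[-1] <= 0:
        logs[-1] = logpdf(y[-1], params)
    return float(np.mean(logs))


def fit_mps(data, init: UELParams | None = None, *, starts=None, with_vcov=True) -> FitResult:
    """Maximum-product-of-spacings fit (same optimizer setup as ML)."""
    y = np.sort(_validate_data(data))

    def objective(logp):
        d, l, t = np.exp(logp)
        with np.errstate(all="ignore"):
            try:
                val = -mps_objective(y, UELParams(d, l, t))
            except (ValueError, FloatingPointError):
                return 1e12, np.zeros(3)
        if not np.isfinite(val):
            return 1e12, np.zeros(3)
        grad = optimize.approx_fprime(logp, lambda lp: _mps_neg(lp, y), 1e-6)
        grad[~np.isfinite(grad)] = 0.0
        return val, grad

    return _maximize(objective, y, init, "MPS", starts=starts, with_vcov=with_vcov)


def _mps_neg(logp, y):
    d, l, t = np.exp(logp)
    with np.errstate(all="ignore"):
        try:
            val = -mps_objective(y, UELParams(d, l, t))
        except (ValueError, FloatingPointError):
            return 1e12
    return val if np.isfinite(val) else 1e12


def asymptotic_ci(fit: FitResult, level: float = 0.95) -> IntervalSet:
    """Normal-theory interval ``estimate +/- z * se`` on the natural scale.

    Lower limits are truncated at zero, since the parameters are positive.
    """
    if fit.se is None:
        raise ValueError("fit carries no usable covariance; asymptotic CI unavailable")
    z = stats.norm.ppf(0.5 + level / 2)
    est = fit.params_array
    lower, upper, notes = {}, {}, []
    for i, name in enumerate(_PARAM_NAMES):
        lo = est[i] - z * fit.se[i]
        if lo < 0:
            notes.append(f"{name}: lower limit truncated at 0")
            lo = 0.0
        lower[name] = lo
        upper[name] = est[i] + z * fit.se[i]
    return IntervalSet(kind="asymptotic", level=level, lower=lower, upper=upper, notes=notes)


def bootstrap_ci(
    data,
    fit: FitResult,
    B: int = 1000,
    kind: str = "BP",
    seed=None,
    level: float = 0.95,
) -> IntervalSet:
    """Nonparametric bootstrap interval.

    ``kind='BP'`` is the percentile interval of the B resample estimates;
    ``kind='BT'`` is the studentized (bootstrap-t) interval using the
    asymptotic SE within each resample.  Failed resample fits are dropped
    and counted in ``notes``.
    """
    kind = kind.upper()
    if kind not in ("BP", "BT"):
        raise ValueError(f"bootstrap kind must be 'BP' or 'BT', got {kind!r}")
    y = _validate_data(data)
    notes = []
    if B < 100:
        notes.append(f"B={B} is small; intervals will be noisy")
    rng = np.random.default_rng(seed)
    fitter = fit_mps if fit.method == "MPS" else fit_mle
    ests, ses = [], []
    failures = 0
    start = [np.log(fit.params_array)]
    for _ in range(B):
        yb = y[rng.integers(0, y.size, size=y.size)]
        try:
            fb = fitter(yb, starts=start, with_vcov=(kind == "BT"))
        except (RuntimeError, ValueError):
            failures += 1
            continue
        if kind == "BT" and fb.se is None:
            failures += 1
            continue
        ests.append(fb.params_array)
        if kind == "BT":
            ses.append(fb.se)
    if failures:
        notes.append(f"{failures} of {B} resample fits failed and were dropped")
    if not ests:
        raise RuntimeError("all bootstrap resample fits failed")
    ests = np.array(ests)
    alpha = 1.0 - level
    lower, upper = {}, {}
    if kind == "BP":
        lo = np.quantile(ests, alpha / 2, axis=0)
        hi = np.quantile(ests, 1 - alpha / 2, axis=0)
    else:
        ses = np.array(ses)
        if fit.se is None:
            raise ValueError("BT interval needs an SE for the original fit")
        tstat = (ests - fit.params_array) / ses
        tq_lo = np.quantile(tstat, alpha / 2, axis=0)
        tq_hi = np.quantile(tstat, 1 - alpha / 2, axis=0)
        lo = fit.params_array - tq_hi * fit.se
        hi = fit.params_array - tq_lo * fit.se
    for i, name in enumerate(_PARAM_NAMES):
        l_i = float(lo[i])
        if l_i < 0:
            notes.append(f"{name}: lower limit truncated at 0")
            l_i = 0.0
        lower[name] = l_i
        upper[name] = float(hi[i])
    return IntervalSet(kind=kind, level=level, lower=lower, upper=upper, notes=notes)
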