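"""Bayesian inference for the UEL distribution under independent gamma priors.

The joint posterior factorizes into full conditionals in which the exponent
parameter theta is conjugate: given (delta, lam) it is exactly

    theta | delta, lam, y  ~  Gamma(n + a3, rate = s3 - sum ln{1 - (1 - lam ln y_i)^(-delta)})

(the sum of logs is negative, so the rate is always positive for positive
hyperparameters).  The delta- and lam-conditionals are non-standard, so the
sampler is Metropolis-within-Gibbs: theta is drawn exactly from its gamma
conditional and delta, lam are updated by random-walk Metropolis on the log
scale.  Step sizes adapt during burn-in toward a 20-40% acceptance rate and
are frozen afterwards, preserving detailed balance for the retained draws.

Point estimates are posterior means (the Bayes rule under squared-error
loss, SELF); interval summaries are highest-posterior-density intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distribution import UELParams

__all__ = ["PriorSpec", "PosteriorSample", "log_full_conditionals", "fit_bayes", "hpd_interval"]

_PARAM_NAMES = ("delta", "lam", "theta")


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gamma(a, rate=s) priors for delta, lam and theta.

    The defaults a = s = 0.01 give a weakly informative prior with mean 1
    and variance 100 for every parameter, letting the likelihood dominate.
    """

    a1: float = 0.01
    s1: float = 0.01
    a2: float = 0.01
    s2: float = 0.01
    a3: float = 0.01
    s3: float = 0.01

    def __post_init__(self):
        for name in ("a1", "s1", "a2", "s2", "a3", "s3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be > 0")


@dataclass
class PosteriorSample:
    """MCMC output: retained draws with SELF point estimates and HPD limits."""

    draws: np.ndarray  # (m, 3) retained (delta, lam, theta) triples
    n_iter: int
    burn_in: int
    thin: int
    acceptance: dict[str, float]
    point: UELParams
    hpd: dict[str, tuple[float, float]]
    level: float

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]


def _suffstats(data) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(data, dtype=float)
    if y.size and np.any((y <= 0) | (y >= 1)):
        raise ValueError("observations must lie strictly in (0, 1)")
    return y, np.log(y)


def _log_cond_delta(d, l, t, ly, prior) -> float:
    n = ly.size
    lt = np.log1p(-l * ly)
    lomu = np.log1p(-np.exp(-d * lt))
    return (n + prior.a1 - 1) * math.log(d) - d * (prior.s1 + lt.sum()) + (t - 1) * lomu.sum()


def _log_cond_lam(d, l, t, ly, prior) -> float:
    n = ly.size
    lt = np.log1p(-l * ly)
    lomu = np.log1p(-np.exp(-d * lt))
    return (
        (n + prior.a2 - 1) * math.log(l)
        - prior.s2 * l
        - (d + 1) * lt.sum()
        + (t - 1) * lomu.sum()
    )


def theta_conditional(delta: float, lam: float, data, prior: PriorSpec) -> tuple[float, float]:
    """(shape, rate) of the exact gamma full conditional of theta."""
    y, ly = _suffstats(data)
    lomu = np.log1p(-np.exp(-delta * np.log1p(-lam * ly)))
    rate = prior.s3 - lomu.sum()
    if rate <= 0:
        raise FloatingPointError("gamma rate for the theta-conditional is non-positive")
    return y.size + prior.a3, rate


def log_full_conditionals(params: UELParams, data, prior: PriorSpec) -> tuple[float, float, float]:
    """Log full-conditional densities (up to constants) at ``params``.

    Returns ``(log pi(delta|.), log pi(lam|.), log pi(theta|.))``; with no
    data each reduces to the corresponding gamma log-prior.
    """
    y, ly = _suffstats(data)
    d, l, t = params.delta, params.lam, params.theta
    ld = _log_cond_delta(d, l, t, ly, prior)
    ll = _log_cond_lam(d, l, t, ly, prior)
    shape, rate = theta_conditional(d, l, y, prior)
    lt_cond = (shape - 1) * math.log(t) - rate * t
    return ld, ll, lt_cond


def fit_bayes(
    data,
    prior: PriorSpec | None = None,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    thin: int = 1,
    seed=None,
    level: float = 0.95,
    init: UELParams | None = None,
) -> PosteriorSample:
    """Metropolis-within-Gibbs sampler for the UEL posterior.

    Each scan draws theta exactly from its gamma conditional, then updates
    delta and lam by random-walk Metropolis on the log scale.  The chain is
    fully reproducible given ``seed``.
    """
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    prior = prior or PriorSpec()
    y, ly = _suffstats(np.asarray(data, dtype=float))
    if y.size < 1:
        raise ValueError("need at least one observation")
    rng = np.random.default_rng(seed)

    state = (init or UELParams(1.0, 1.0, 1.0)).as_array().copy()
    steps = {"delta": 0.3, "lam": 0.3}
    window = {"delta": [0, 0], "lam": [0, 0]}  # accepted, proposed
    accepted = {"delta": 0, "lam": 0}
    proposed = {"delta": 0, "lam": 0}

    log_conds = {"delta": _log_cond_delta, "lam": _log_cond_lam}
    idx = {"delta": 0, "lam": 1}

    keep = []
    for it in range(n_iter):
        d, l, t = state
        # exact gamma draw for theta
        lomu_sum = np.log1p(-np.exp(-d * np.log1p(-l * ly))).sum()
        rate = prior.s3 - lomu_sum
        t = rng.gamma(y.size + prior.a3) / rate
        state[2] = t
        # random-walk MH on log(delta), log(lam)
        for name in ("delta", "lam"):
            i = idx[name]
            cur = state[i]
            prop = cur * math.exp(steps[name] * rng.normal())
            args_cur = list(state)
            args_prop = list(state)
            args_prop[i] = prop
            with np.errstate(all="ignore"):
                lp_cur = log_conds[name](args_cur[0], args_cur[1], args_cur[2], ly, prior)
                lp_prop = log_conds[name](args_prop[0], args_prop[1], args_prop[2], ly, prior)
            # log-scale proposal: include the Jacobian of the transform
            ratio = (lp_prop + math.log(prop)) - (lp_cur + math.log(cur))
            ok = np.isfinite(lp_prop) and math.log(rng.uniform()) < ratio
            if ok:
                state[i] = prop
            if it < burn_in:
                window[name][1] += 1
                window[name][0] += ok
                if window[name][1] == 50:
                    acc = window[name][0] / 50
                    if acc < 0.2:
                        steps[name] *= 0.8
                    elif acc > 0.4:
                        steps[name] *= 1.25
                    window[name] = [0, 0]
            else:
                proposed[name] += 1
                accepted[name] += ok
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep.append(state.copy())

    draws = np.array(keep)
    rates = {k: accepted[k] / max(proposed[k], 1) for k in accepted}
    for name, r in rates.items():
        if r < 0.01:
            raise RuntimeError(
                f"MH acceptance for {name} is {r:.3%} after adaptation; review step sizes"
            )
    point = UELParams(*draws.mean(axis=0))
    hpd = {
        name: hpd_interval(draws[:, i], level) for i, name in enumerate(_PARAM_NAMES)
    }
    return PosteriorSample(
        draws=draws,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        acceptance=rates,
        point=point,
        hpd=hpd,
        level=level,
    )


def hpd_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(level * m)`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    m = x.size
    if m < 100:
        raise ValueError(f"need at least 100 draws for an HPD interval, got {m}")
    k = int(math.ceil(level * m))
    if k >= m:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: m - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])
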