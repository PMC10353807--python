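"""Infinite-series expansions of UEL moments, PWMs and entropy integrals.

These closed-form double/triple series (binomial expansions of the density
followed by termwise beta-function integrals) serve as independent
cross-checks of the canonical quadrature routines; they are *not* the
primary computational path.  The inner beta terms ``B(1+j, c-j)`` exist
only while ``c - j > 0``, so for small shape values the inner sum must be
cut at the last valid term, after which the expansion is only an
approximation; results carry a ``truncated`` flag for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import special

from .distribution import UELParams

__all__ = ["SeriesValue", "series_raw_moment", "series_pwm", "series_density_power"]


@dataclass(frozen=True)
class SeriesValue:
    value: float
    truncated: bool  # True if any inner sum hit an invalid beta argument
    terms: int


def _inner_beta_sum(rate: float, c: float, jmax: int) -> tuple[float, bool, int]:
    """``sum_j (-rate)^j / j! * B(1+j, c-j)`` over valid j (c - j > 0)."""
    total = 0.0
    truncated = False
    used = 0
    for j in range(jmax + 1):
        if c - j <= 0:
            truncated = True
            break
        total += (-rate) ** j / special.factorial(j) * special.beta(1 + j, c - j)
        used += 1
    return total, truncated, used


def series_raw_moment(s: int, params: UELParams, kmax: int = 200, jmax: int = 200) -> SeriesValue:
    """Raw moment by the binomial/beta double series.

    ``mu_s' = sum_k (-1)^k C(theta-1, k) delta*theta *
    sum_j (-s/lam)^j / j! * B(1+j, delta(k+1) - j)``.
    """
    d, l, t = params.delta, params.lam, params.theta
    total = 0.0
    truncated = False
    terms = 0
    for k in range(kmax + 1):
        ck = special.binom(t - 1, k)
        if ck == 0.0 and k > t - 1:
            break
        inner, trunc, used = _inner_beta_sum(s / l, d * (k + 1), jmax)
        total += (-1) ** k * ck * d * t * inner
        truncated |= trunc
        terms += used
    return SeriesValue(value=total, truncated=truncated, terms=terms)


def series_pwm(h: int, s: int, params: UELParams, mmax: int = 200, jmax: int = 200) -> SeriesValue:
    """PWM ``Psi_{h,s}`` by the triple series (finite outer sum over u <= s)."""
    d, l, t = params.delta, params.lam, params.theta
    total = 0.0
    truncated = False
    terms = 0
    for u in range(s + 1):
        cu = special.binom(s, u)
        for m in range(mmax + 1):
            cm = special.binom(t * (u + 1) - 1, m)
            if cm == 0.0 and m > t * (u + 1) - 1:
                break
            inner, trunc, used = _inner_beta_sum(h / l, d * (m + 1), jmax)
            total += (-1) ** (u + m) * cu * cm * d * t * inner
            truncated |= trunc
            terms += used
    return SeriesValue(value=total, truncated=truncated, terms=terms)


def series_density_power(omega: float, params: UELParams, mmax: int = 200, jmax: int = 200) -> SeriesValue:
    """``I(omega) = integral f^omega`` by the expansion

    ``I = (lam*delta*theta)^omega / lam * sum_m (-1)^m C(omega(theta-1), m) *
    sum_j ((omega-1)/lam)^j / j! * B(1+j, omega(delta+1) + delta*m - 1 - j)``.

    Feeds the series cross-checks of the three entropy measures.  (The
    ``-1`` in the second beta argument comes from the absence of a ``1/y``
    factor in ``f^omega``'s substitution; dropping it does not reproduce the
    quadrature value.)
    """
    if omega <= 0 or omega == 1:
        raise ValueError("entropy order must be positive and different from 1")
    d, l, t = params.delta, params.lam, params.theta
    pref = (l * d * t) ** omega / l
    total = 0.0
    truncated = False
    terms = 0
    for m in range(mmax + 1):
        cm = special.binom(omega * (t - 1), m)
        if cm == 0.0 and m > omega * (t - 1):
            break
        c = omega * (d + 1) + d * m - 1.0
        # inner sum with rate (1-omega)/lam: sum_j (-(1-omega)/lam)^j/j! B(1+j, c-j)
        inner, trunc, used = _inner_beta_sum((1.0 - omega) / l, c, jmax)
        total += (-1) ** m * cm * inner
        truncated |= trunc
        terms += used
    return SeriesValue(value=pref * total, truncated=truncated, terms=terms)
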