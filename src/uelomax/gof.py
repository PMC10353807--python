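"""Goodness-of-fit statistics and information criteria for fitted UEL models.

All empirical-distribution statistics are built from the probability
integral transform u_i = F(y_(i)): the Kolmogorov-Smirnov sup-distance, the
Cramer-von Mises statistic and the Anderson-Darling statistic in their
standard computational forms.  Information criteria (AIC, BIC, CAIC, HQIC)
follow their usual penalized-likelihood definitions; both the criteria and
their negatives are reported, since comparison tables are often printed on
the negated scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distribution import UELParams, cdf
from .estimation import loglik

__all__ = ["GofReport", "evaluate_fit"]

_CLIP = 1e-12


@dataclass
class GofReport:
    ksd: float
    ks_pvalue: float
    cvmc: float
    adc: float
    loglik: float
    aic: float
    bic: float
    caic: float
    hqic: float
    k: int
    n: int

    @property
    def neg_aic(self) -> float:
        return -self.aic

    @property
    def neg_bic(self) -> float:
        return -self.bic

    @property
    def neg_caic(self) -> float:
        return -self.caic

    @property
    def neg_hqic(self) -> float:
        return -self.hqic

    def row(self) -> dict[str, float]:
        """Comparison-table row (negated criteria, as usually printed)."""
        return {
            "KSD": self.ksd,
            "P-Value": self.ks_pvalue,
            "-AIC": self.neg_aic,
            "-BIC": self.neg_bic,
            "-CAIC": self.neg_caic,
            "-HQIC": self.neg_hqic,
            "CVMC": self.cvmc,
            "ADC": self.adc,
        }


def evaluate_fit(data, params: UELParams, k: int = 3) -> GofReport:
    """EDF statistics and information criteria of ``params`` on ``data``.

    ``k`` is the number of fitted parameters entering the penalties.  The KS
    p-value uses the asymptotic Kolmogorov law; no correction is applied for
    parameters having been estimated from the same data, which matches the
    comparative (not inferential) use of these statistics.
    """
    y = np.sort(np.asarray(data, dtype=float))
    n = y.size
    if k < 1:
        raise ValueError("fitted-parameter count k must be >= 1")
    if n <= k + 1:
        raise ValueError("need n > k+1 observations for the corrected AIC")
    u = np.asarray(cdf(y, params), dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        warnings.warn(
            "PIT values at 0 or 1 clipped to [1e-12, 1-1e-12]; AD logs are affected",
            RuntimeWarning,
            stacklevel=2,
        )
        u = np.clip(u, _CLIP, 1 - _CLIP)
    i = np.arange(1, n + 1)
    ksd = float(max((i / n - u).max(), (u - (i - 1) / n).max()))
    cvmc = float(1.0 / (12 * n) + ((u - (2 * i - 1) / (2 * n)) ** 2).sum())
    adc = float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))
    ks_pvalue = float(stats.kstwobign.sf(math.sqrt(n) * ksd))
    ll = loglik(y, params)
    aic = 2 * k - 2 * ll
    return GofReport(
        ksd=ksd,
        ks_pvalue=ks_pvalue,
        cvmc=cvmc,
        adc=adc,
        loglik=ll,
        aic=aic,
        bic=k * math.log(n) - 2 * ll,
        caic=aic + 2 * k * (k + 1) / (n - k - 1),
        hqic=2 * k * math.log(math.log(n)) - 2 * ll,
        k=k,
        n=n,
    )
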