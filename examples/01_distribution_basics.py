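"""Distributional quantities of the unit-exponentiated Lomax law.

Builds one parameter set, evaluates the CDF/density/quantile machinery and
the moment and entropy summaries computed by adaptive quadrature.
"""

from uelomax import (
    UELParams,
    cdf,
    moment_summary,
    omega_entropy,
    pdf,
    quantile,
    renyi_entropy,
    stress_strength,
)

p = UELParams(delta=1.5, lam=0.5, theta=0.5)

print(f"parameters: delta={p.delta}, lam={p.lam}, theta={p.theta}")
print(f"F(0.5)  = {cdf(0.5, p):.6f}   (probability of a value below one half)")
print(f"f(0.5)  = {pdf(0.5, p):.6f}   (density there)")
print(f"median  = {quantile(0.5, p):.6f}")

ms = moment_summary(p)
print(f"mean    = {ms.raw[0]:.4f}, variance = {ms.variance:.4f}")
print(f"skewness = {ms.skewness:.4f} (negative: left tail dominates)")
print(f"kurtosis = {ms.kurtosis:.4f} (beta2 convention; 3 would be normal-like)")

print(f"Renyi entropy (omega=0.5) = {renyi_entropy(0.5, p):.4f}")
print(f"xi entropy    (omega=0.9) = {omega_entropy(0.9, p):.4f}")

# stress-strength: P(stress < strength) for shared delta, lam
print(f"P(Y2 < Y1) with theta1=1, theta2=3: {stress_strength(1.0, 3.0):.2f}")
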