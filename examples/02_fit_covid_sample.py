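"""Fit the UEL distribution to the bundled Covid-19 mortality-rate sample.

Fits by maximum likelihood and by maximum product of spacings, then prints
the goodness-of-fit battery.  Note the enormous fitted delta/theta: the
likelihood is maximized along a ridge on which the model approaches a
two-parameter Kumaraswamy limit, so the fitted CDF (and every statistic
computed from it) is stable even though the individual shape parameters are
not separately well determined.
"""

from uelomax import covid_fixture, evaluate_fit, fit_mle, fit_mps

ds = covid_fixture()
print(f"{ds.name}: n={len(ds)} daily mortality rates in (0,1)")

ml = fit_mle(ds.values)
mps = fit_mps(ds.values)
print(f"ML  estimates: delta={ml.estimates.delta:.4g}, lam={ml.estimates.lam:.4g}, "
      f"theta={ml.estimates.theta:.4g}, loglik={ml.objective:.4f}")
print(f"MPS estimates: delta={mps.estimates.delta:.4g}, lam={mps.estimates.lam:.4g}, "
      f"theta={mps.estimates.theta:.4g}")

rep = evaluate_fit(ds.values, ml.estimates, k=3)
row = rep.row()
print("goodness of fit (smaller KSD/CVMC/ADC and larger -AIC mean a better fit):")
for k, v in row.items():
    print(f"  {k:8s} {v:10.4f}")
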