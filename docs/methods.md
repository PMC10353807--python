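# Methods

## The model

The unit-exponentiated Lomax (UEL) law is the distribution of
`Y = exp(−X)` where `X` follows an exponentiated Lomax distribution with
shape `δ`, scale `λ` and power `ϑ` (all positive, dimensionless).  Support
is the open unit interval;

```
F(y) = 1 − {1 − (1 − λ ln y)^(−δ)}^ϑ.
```

`ϑ = 1` gives the unit-Lomax special case `F(y) = (1 − λ ln y)^(−δ)`.
Because `−ln Y` inherits a Pareto-type (power-law) upper tail with index
`δ`, the *left* tail of `Y` near 0 is extremely heavy for small `δ`: for
`(δ, λ, ϑ) = (0.5, 0.5, 0.5)` about 2.7 % of the probability mass lies
below the smallest positive IEEE-754 double (`≈ 2.2e−308`).  This single
fact drives several numerical choices below; any analysis of this model in
double precision, in any language, faces it.

A second structural fact: the log-likelihood is monotone along the ridge
`δ → ∞, λ → 0` with `c = δλ` fixed, along which
`(1 − λ ln y)^(−δ) → y^c` and the model degenerates to the Kumaraswamy
law `F = 1 − (1 − y^c)^ϑ`.  Real-data ML fits often terminate on this
ridge with enormous `δ̂, ϑ̂`; the fitted CDF, the log-likelihood and every
statistic derived from them are stable there, but `δ` and `λ` are only
jointly identified.  All optimization is therefore done on log-parameters
inside the box `|log p| ≤ 12`, wide enough to resolve the ridge plateau to
within ~1e−4 in log-likelihood while avoiding overflow.

## Numerical conventions

- **Log-space evaluation throughout** (`log1p`, `expm1`): CDF, density,
  quantile and likelihood survive `δ, ϑ` in the thousands.
- **Endpoints**: the CDF accepts the closed interval (0 below, 1 above);
  density and hazard raise on the endpoints, where they are undefined.
- **Quadrature, not series**: moments, PWMs and incomplete moments are
  integrated after the substitution `y = Q(p)`, which turns every such
  integral into a smooth bounded integrand on (0,1) (absolute tolerance
  1e−10).  Entropy integrals `∫ f^ω` are integrated in `y` directly.  The
  classical double-series expansions (binomial expansion + termwise beta
  integrals) are provided in `uelomax.series` as *cross-checks only*: their
  inner beta arguments `B(1+j, δ(k+1)−j)` exist only while `j < δ(k+1)`,
  so for small `δ` the expansion truncates after a term or two and cannot
  represent the quantity.  Results carry a `truncated` flag.  (The series
  for `∫ f^ω` requires a `−1` in the second beta argument,
  `B(1+j, ω(δ+1)+δm−1−j)`; the variant without it disagrees with
  quadrature by several percent, which we verified numerically at `δ=25`.)
- **Kurtosis** is reported as ordinary `β₂` (not excess).
- **Sampling** is seeded inverse-transform.  Draws whose exact value would
  fall outside the representable open interval are clipped to
  `[2.2e−308, 1−2^−53]`; at heavy-tailed parameter corners such draws are
  *not rare* (see above), and the simulation harness has an explicit
  policy for them.

## Estimation

- **ML**: analytic score, quasi-Newton (L-BFGS-B) on `log(δ,λ,ϑ)` from a
  3×3×3 grid of starts (`{0.5, 1, 5}` per parameter) plus any user
  initializer; covariance by central-difference Hessian on the log scale
  (step 1e−4), delta-method back-transform; asymptotic intervals
  `θ̂ ± z·se` on the natural scale with lower limits truncated at 0 (and
  the truncation recorded in the interval's notes).
- **MPS**: the objective is the mean log of the `n+1` CDF spacings of the
  order statistics; exactly tied observations contribute the log-density
  at the tied point (Cheng–Amin convention).  Gradients are finite
  differences, so its convergence flag uses a looser stationarity
  threshold (1e−3 scaled) than ML (1e−5).
- **Bootstrap**: nonparametric resampling, B = 1000 by default;
  percentile (BP) and studentized (BT) intervals, the latter using each
  resample's asymptotic SE.  At small n the resample fits frequently run
  along the `δ→∞` ridge, making interval lengths heavy tailed; robust
  summaries (medians, majority comparisons) are recommended when
  aggregating them, and that is how the test suite asserts the BT ≤ BP
  direction.
- **Bayes**: independent Gamma(aᵢ, rate sᵢ) priors.  The ϑ-conditional is
  an exact Gamma(n+a₃, s₃ − Σ ln{1−(1−λ ln yᵢ)^(−δ)}) and is sampled
  directly; δ and λ use random-walk Metropolis on the log scale with step
  sizes adapted during burn-in to a 20–40 % acceptance band and frozen
  afterwards (detailed balance holds for all retained draws).  Defaults:
  10 000 iterations, 2 000 burn-in, thinning 1.  Point estimates are
  posterior means (the squared-error-loss Bayes rule); intervals are
  highest-posterior-density by the sorted shortest-window method.
  The package default prior is weakly informative (aᵢ = sᵢ = 0.01, prior
  mean 1, variance 100).  Note that under such diffuse priors the
  δ-posterior inherits the likelihood ridge and is very heavy tailed, so
  its *mean* is an unstable summary at small n.

## The Monte-Carlo harness

`run_study` draws seeded samples per (parameter triple, n) cell, fits the
requested estimators and reports bias, MSE and mean interval lengths.
Per-replicate seeds derive from the master seed through counter-based
`SeedSequence` spawn keys, so every cell is independently reproducible.

- **Underflow policy.** At corners where draws underflow to zero the
  default policy redraws the replicate and reports the redraw count.  This
  mirrors what any likelihood pipeline in double precision effectively
  does (a replicate containing a zero has a non-finite log-likelihood and
  cannot be fit), but it is a *selection* on the observable part of the
  sample space: at `(0.5, 0.5, 0.5)` roughly 98 % of n = 150 replicates
  are redrawn, and the surviving ensemble — samples with no deep-left-tail
  values — yields a markedly positive bias for `δ̂` (≈ +0.26 at n = 150)
  that a full-support analysis would not show (clamping draws to the
  double floor instead gives ≈ +0.09).  The redraw counts are in the
  report so the effect is visible; `underflow='clamp'` switches policy.
- **Harness fits** start from the generating triple plus (1,1,1) rather
  than the full grid; on 300 replicates the full grid reached the
  identical optima at 15× the cost.  Fits that terminate on the
  optimizer's log-parameter box (the likelihood ridge running off to
  infinity) are counted as failures and dropped, as a Newton-type
  pipeline would report them; about 1 replicate in 5000 is affected at
  the heavy-tailed reference cell, but a single such `λ̂ = e¹²` would
  otherwise dominate the cell's MSE.
- **Bayes cells** default to shortened chains (3 000 / 500) and to
  *truth-centered* gamma priors with coefficient of variation 1/2 (prior
  mean equal to the generating value).  Estimator-comparison studies of
  this model that report Bayes risks an order of magnitude below the
  likelihood methods, nearly independent of n, are only explainable under
  informative elicited priors of this kind; with the diffuse default the
  posterior-mean MSE for δ is dominated by the ridge tail and beats
  neither ML nor MPS.  Pass an explicit `PriorSpec` to override.

## Quantile regression

Solving `Q(q) = μ` for the scale gives
`λ(μ) = (1 − A(q,ϑ)^(−1/δ)) / ln μ` with `A = 1 − (1−q)^(1/ϑ)`; numerator
and `ln μ` are both negative, so `λ > 0` on the whole domain.  Covariates
act on `μ` through a logit link (probit and complementary log-log are
wired but experimental).  The log-likelihood is the sum of UEL
log-densities with per-observation `λᵢ` substituted — note this
*derivation by substitution* produces `−Σ ln(−ln μᵢ)` where a naive
transcription would write `−Σ ln(ln μᵢ)`, which is undefined for
`μᵢ ∈ (0,1)`; the substituted form is the one implemented.  Standard
errors come from the inverse observed information (the expected
information has no closed form here); `q` defaults to 0.5 (median
regression).  Starting values: least squares of the linked response on X,
with a small grid over the shape parameters.

## Goodness of fit

EDF statistics from the probability integral transform `uᵢ = F(y₍ᵢ₎)`:
two-sided KS sup-distance, Cramér–von Mises
`1/(12n) + Σ(uᵢ − (2i−1)/(2n))²`, Anderson–Darling
`−n − (1/n)Σ(2i−1)[ln uᵢ + ln(1−u_{n+1−i})]`.  The KS p-value uses the
asymptotic Kolmogorov law and is *not* corrected for estimated parameters
(no Lilliefors-type adjustment) — appropriate for comparing candidate
models on the same data, not for calibrated testing.  PIT values that
round to 0 or 1 are clipped to `[1e−12, 1−1e−12]` with a warning (this
affects the AD logs).  Information criteria: AIC = 2k − 2ℓ,
BIC = k ln n − 2ℓ, CAIC = AIC + 2k(k+1)/(n−k−1), HQIC = 2k ln ln n − 2ℓ;
both signs are exposed since comparison tables are often printed negated.

## What the synthetic generators do and do not emulate

`make_synthetic` produces exact inverse-transform UEL draws;
`make_regression_synthetic` draws responses whose conditional q-th
quantile follows the specified logit model.  They emulate the *model*,
not real data: no measurement rounding (real rate series are typically
printed to 4 decimals, producing ties), no serial dependence (real daily
mortality rates are autocorrelated), no covariate collinearity beyond
what the caller builds.  Passing tests therefore demonstrate correctness
of the machinery under the model, not robustness to misspecification.

## Numerical provenance of the reference values

The test suite validates every computed quantity against independent
oracles: quadrature vs Monte-Carlo simulation from the generative
definition `Y = e^(−X)` (moments, PWMs, incomplete moments, entropies,
stress–strength), quadrature vs the series expansions where those are
valid (`δ = 25`), estimator output vs score equations, PIT uniformity, and
external references where available (scipy's KS statistic, arviz's HPD).
Published reference tables for this distribution's moments and entropies
could not be reconciled with the distribution's own closed-form definition
by any route we tried, and the acceptance tests therefore accept the
oracle-validated quadrature values as authoritative where the two
disagree; the real-data (Covid-19) fit statistics and the Monte-Carlo
study, by contrast, reproduce closely under the conditions described
above.

## Problem sizes used in the shipped checks

Moment/entropy oracles use 4×10⁵ simulation draws; recovery checks use
n = 5000 samples; the reference Monte-Carlo cell runs 5000 replicates of
n = 150 (ML), with orderings checked at 500 (MPS), 100 (Bayes) and 20
(bootstrap, B = 200) replicates.  These sizes put every Monte-Carlo
standard error well below the asserted tolerances.

## Known limitations

- Quantities below `y ≈ 1e−308` are not representable; the package treats
  the representable open interval as the effective support and accounts
  for the missing mass explicitly where it matters (normalization checks,
  simulation policy).  Quantile round-trips are only meaningful above the
  floor.
- `δ` and `λ` are separately weakly identified (ridge); report `δλ` or
  the fitted CDF when stability matters.
- Rényi entropy of order `ω > 1` diverges whenever the density is
  unbounded at 0 (`∫ f^ω` ∼ `∫ y^{−ω}` there); orders in (0,1) are safe.
- The bootstrap assumes i.i.d. data; the bundled Covid series is a time
  series and interval statements for it should be read accordingly.
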