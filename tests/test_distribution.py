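"""Distributional identities of the UEL law against independent oracles."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from uelomax import (
    UELParams,
    cdf,
    hazard,
    hc_entropy,
    incomplete_moment,
    logpdf,
    lorenz,
    moment_summary,
    omega_entropy,
    pdf,
    pwm,
    quantile,
    raw_moment,
    renyi_entropy,
    sample,
    stress_strength,
    survival,
)

from conftest import CASES

GRID = np.linspace(0.01, 0.99, 25)


def _pdf_mass(p, y_lo, y_hi):
    """Integral of the density over (y_lo, y_hi) via w = 1/(1 - lam ln y).

    The substitution resolves both the spike at y -> 0 and the heavy
    Pareto-type tail of -ln Y; the integrand stays in log space because the
    density itself overflows near zero while density*y is finite.
    """

    def h(w):
        z = 1.0 / w - 1.0
        y = np.exp(-z / p.lam)
        if y <= 0.0 or y >= 1.0:
            return 0.0
        return np.exp(logpdf(y, p) - z / p.lam) / p.lam / w**2

    w_lo = 1.0 / (1.0 - p.lam * np.log(y_lo))
    w_hi = 1.0 / (1.0 - p.lam * np.log(y_hi)) if y_hi < 1 else 1.0
    val, _ = integrate.quad(h, w_lo, w_hi, limit=400)
    return val


class TestParams:
    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, 0), (np.nan, 1, 1)])
    def test_nonpositive_component_rejected(self, bad):
        with pytest.raises(ValueError):
            UELParams(*bad)

    def test_theta_one_collapses_cdf(self):
        # with theta = 1 the CDF is 1 - (1 - lam ln y)^(-delta) directly
        p = UELParams(2.2, 0.7, 1.0)
        y = GRID
        expected = (1.0 - p.lam * np.log(y)) ** (-p.delta)
        np.testing.assert_allclose(cdf(y, p), expected, atol=1e-13)


class TestCdfPdf:
    def test_cdf_endpoints(self, cases):
        for p in cases.values():
            assert cdf(1.0, p) == 1.0
            assert cdf(0.0, p) == 0.0
            assert cdf(1.5, p) == 1.0 and cdf(-0.3, p) == 0.0

    @pytest.mark.parametrize("key", list(CASES))
    def test_pdf_integrates_to_one(self, cases, key):
        p = cases[key]
        # mass over the representable range plus the (possibly large) mass
        # below the double-precision floor must total one
        floor = 1e-300
        total = _pdf_mass(p, floor, 1.0) + cdf(floor, p)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_cdf_matches_integral_of_pdf(self, cases):
        # adaptive-quadrature oracle of the density over (0, 1/2]
        p = cases["a"]
        floor = 1e-300
        val = _pdf_mass(p, floor, 0.5) + cdf(floor, p)
        assert cdf(0.5, p) == pytest.approx(val, abs=1e-9)

    def test_pdf_is_derivative_of_cdf(self, cases):
        h = 1e-6
        for p in cases.values():
            num = (cdf(0.5 + h, p) - cdf(0.5 - h, p)) / (2 * h)
            assert pdf(0.5, p) == pytest.approx(num, abs=1e-6)

    def test_theta_one_pdf_reduction(self):
        p = UELParams(1.8, 0.6, 1.0)
        y = GRID
        expected = (p.lam * p.delta / y) * (1 - p.lam * np.log(y)) ** (-p.delta - 1)
        np.testing.assert_allclose(pdf(y, p), expected, rtol=1e-12)

    def test_pdf_rejects_endpoints(self, cases):
        with pytest.raises(ValueError):
            pdf(0.0, CASES["a"])
        with pytest.raises(ValueError):
            logpdf(1.0, CASES["a"])

    def test_cdf_nondecreasing_on_grid(self, cases):
        y = np.linspace(1e-6, 1 - 1e-6, 1000)
        for p in cases.values():
            assert np.all(np.diff(cdf(y, p)) >= 0)


class TestSurvivalHazard:
    def test_complement(self, cases):
        for p in cases.values():
            np.testing.assert_allclose(cdf(GRID, p) + survival(GRID, p), 1.0, atol=1e-12)

    def test_hazard_times_survival_is_pdf(self, cases):
        for p in cases.values():
            np.testing.assert_allclose(
                hazard(GRID, p) * survival(GRID, p), pdf(GRID, p), atol=1e-10, rtol=1e-10
            )

    def test_hazard_finite_positive(self, cases):
        h = hazard(GRID, cases["a"])
        assert np.all(np.isfinite(h)) and np.all(h > 0)


class TestQuantile:
    def test_endpoint_limits(self, cases):
        p = cases["b"]
        assert quantile(1 - 1e-14, p) > 1 - 1e-4
        assert quantile(1e-300, p) < 1e-6

    def test_domain_errors(self, cases):
        with pytest.raises(ValueError):
            quantile(0.0, CASES["a"])
        with pytest.raises(ValueError):
            quantile(1.0, CASES["a"])

    @pytest.mark.parametrize("key", list(CASES))
    def test_round_trips(self, cases, key):
        p = cases[key]
        # start above the probability mass that lies below the smallest
        # representable double (the small-delta cases have extremely heavy
        # left tails: ~8% of case (c) is not representable)
        q = np.linspace(0.1, 0.98, 40)
        np.testing.assert_allclose(cdf(quantile(q, p), p), q, atol=1e-10)
        y = np.linspace(0.05, 0.95, 40)
        np.testing.assert_allclose(quantile(cdf(y, p), p), y, atol=1e-9)

    def test_median_against_bisection(self, cases):
        p = cases["a"]
        root = optimize.brentq(lambda y: cdf(y, p) - 0.5, 1e-12, 1 - 1e-12, xtol=1e-13)
        assert quantile(0.5, p) == pytest.approx(root, abs=1e-9)


class TestSampling:
    def test_seed_contract(self, cases):
        a = sample(5, cases["a"], seed=7)
        b = sample(5, cases["a"], seed=7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_n(self, cases):
        with pytest.raises(ValueError):
            sample(0, cases["a"])

    def test_open_interval(self, cases):
        for p in cases.values():
            y = sample(5000, p, seed=11)
            assert np.all((y > 0) & (y < 1))

    def test_ks_consistency(self, cases):
        p = cases["a"]
        y = sample(20000, p, seed=3)
        d = stats.kstest(y, lambda v: cdf(v, p)).statistic
        assert d < 0.015

    def test_sample_mean_matches_quadrature_mean(self, cases):
        # the quadrature first moment is the independent oracle here
        p = cases["a"]
        y = sample(20000, p, seed=5)
        mu = raw_moment(1, p)
        assert abs(y.mean() - mu) < 3 * y.std(ddof=1) / np.sqrt(y.size)


class TestMoments:
    def test_order_validation(self, cases):
        with pytest.raises(ValueError):
            raw_moment(0, CASES["a"])
        with pytest.raises(ValueError):
            raw_moment(1.5, CASES["a"])

    @pytest.mark.parametrize("key", list(CASES))
    def test_jensen(self, cases, key):
        p = cases[key]
        assert raw_moment(2, p) >= raw_moment(1, p) ** 2

    def test_moment_summary_consistency(self, cases):
        p = cases["e"]
        ms = moment_summary(p)
        assert ms.variance == pytest.approx(ms.raw[1] - ms.raw[0] ** 2, abs=1e-12)
        assert ms.variance >= 0

    def test_moments_match_monte_carlo(self, cases):
        p = cases["a"]
        y = sample(400_000, p, seed=9)
        for s in (1, 2):
            mc = (y**s).mean()
            se = (y**s).std(ddof=1) / np.sqrt(y.size)
            assert raw_moment(s, p) == pytest.approx(mc, abs=3.5 * se)

    def test_lambda_scaling_law(self, cases):
        # E[Y^s] depends on (s/lam, delta, theta) only, so the 4th moment at
        # lam=2 equals the mean at lam=1/2 for matching shapes
        assert raw_moment(4, cases["d"]) == pytest.approx(raw_moment(1, cases["a"]), abs=1e-9)
        assert raw_moment(4, cases["e"]) == pytest.approx(raw_moment(1, cases["b"]), abs=1e-9)


class TestPWM:
    def test_reduces_to_raw_moment(self, cases):
        p = cases["b"]
        for h in (1, 2):
            assert pwm(h, 0, p) == pytest.approx(raw_moment(h, p), abs=1e-8)

    def test_uniform_pit_reduction(self, cases):
        p = cases["d"]
        for s in (0, 1, 3):
            assert pwm(0, s, p) == pytest.approx(1.0 / (s + 1), abs=1e-8)

    def test_against_monte_carlo(self, cases):
        p = cases["a"]
        y = sample(1_000_000, p, seed=13)
        w = y * cdf(y, p)
        se = w.std(ddof=1) / np.sqrt(y.size)
        assert pwm(1, 1, p) == pytest.approx(w.mean(), abs=3 * se)

    def test_negative_order_rejected(self, cases):
        with pytest.raises(ValueError):
            pwm(-1, 0, CASES["a"])


class TestIncompleteMoments:
    def test_full_support_reduction(self, cases):
        p = cases["e"]
        for s in (1, 2):
            assert incomplete_moment(s, 1.0, p) == pytest.approx(raw_moment(s, p), abs=1e-8)

    def test_lorenz_normalization(self, cases):
        assert lorenz(1.0, CASES["b"]) == pytest.approx(1.0, abs=1e-8)

    def test_monotone_in_cutoff(self, cases):
        p = cases["a"]
        ts = [0.2, 0.4, 0.6, 0.8, 1.0]
        vals = [incomplete_moment(1, t, p) for t in ts]
        assert np.all(np.diff(vals) >= 0)

    def test_against_monte_carlo(self, cases):
        p = cases["a"]
        med = quantile(0.5, p)
        y = sample(400_000, p, seed=17)
        w = y * (y <= med)
        se = w.std(ddof=1) / np.sqrt(y.size)
        assert incomplete_moment(1, med, p) == pytest.approx(w.mean(), abs=3.5 * se)

    def test_domain(self, cases):
        with pytest.raises(ValueError):
            incomplete_moment(1, 0.0, CASES["a"])
        with pytest.raises(ValueError):
            incomplete_moment(1, 1.2, CASES["a"])


class TestEntropies:
    def test_order_domain(self, cases):
        for bad in (0.0, -1.0, 1.0):
            with pytest.raises(ValueError):
                renyi_entropy(bad, CASES["a"])

    def test_consistency_of_three_measures(self, cases):
        # all three are deterministic transforms of I(omega); recover I from
        # each and check they agree
        p = cases["e"]
        omega = 0.9
        i_renyi = np.exp((1 - omega) * renyi_entropy(omega, p))
        i_xi = 1 - (omega - 1) * omega_entropy(omega, p)
        i_hc = (1 + (2 ** (1 - omega) - 1) * hc_entropy(omega, p)) ** omega
        assert i_renyi == pytest.approx(i_xi, abs=1e-10)
        assert i_renyi == pytest.approx(i_hc, abs=1e-10)

    @pytest.mark.parametrize("key,omega", [("a", 0.5), ("e", 0.9), ("c", 0.5)])
    def test_density_power_integral_against_monte_carlo(self, cases, key, omega):
        # I(omega) = E[f(Y)^(omega-1)] gives an independent simulation oracle
        p = cases[key]
        y = sample(400_000, p, seed=19)
        w = np.exp((omega - 1) * logpdf(y, p))
        se = w.std(ddof=1) / np.sqrt(y.size)
        i_quad = np.exp((1 - omega) * renyi_entropy(omega, p))
        assert i_quad == pytest.approx(w.mean(), abs=4 * se)


class TestStressStrength:
    def test_symmetry_and_closed_form(self):
        assert stress_strength(2.0, 2.0) == 0.5
        assert stress_strength(1.0, 3.0) == 0.75

    def test_domain(self):
        with pytest.raises(ValueError):
            stress_strength(0.0, 1.0)

    def test_against_monte_carlo(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            d, l = rng.uniform(0.5, 3, size=2)
            t1, t2 = rng.uniform(0.3, 4, size=2)
            n = 100_000
            y1 = sample(n, UELParams(d, l, t1), seed=int(rng.integers(1 << 31)))
            y2 = sample(n, UELParams(d, l, t2), seed=int(rng.integers(1 << 31)))
            phat = (y2 < y1).mean()
            se = np.sqrt(phat * (1 - phat) / n)
            assert stress_strength(t1, t2) == pytest.approx(phat, abs=3.5 * se)
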