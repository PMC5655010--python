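"""Densities, samplers and derivatives of the magnitude observation models."""

import numpy as np
import pytest
from scipy import integrate

from ricianreg import (
    NoiseModel,
    ObsParams,
    dlogpdf,
    gaussian_logpdf,
    magnitude_mean,
    magnitude_var,
    ncchi_logpdf,
    rician_logpdf,
    sample_magnitude,
)
from ricianreg.noise_models import log_bessel_i, side_terms

from conftest import bessel_i_series


class TestLogDensities:
    def test_rician_central_limit_is_rayleigh(self):
        # I0(0)=1 so p(y) = y exp(-y^2/2) at mu=0, phi=1
        assert rician_logpdf(1.0, 0.0, 1.0) == pytest.approx(-0.5, abs=1e-12)

    def test_rician_value_against_series_oracle(self):
        # p = (y/phi) exp(-(y^2+mu^2)/2phi) I0(y mu/phi) with I0 from the
        # independent 50-term ascending series
        y, mu, phi = 2.0, 1.0, 1.0
        expected = np.log(2.0) - 2.5 + np.log(bessel_i_series(0, 2.0))
        assert rician_logpdf(y, mu, phi) == pytest.approx(expected, rel=1e-12)

    def test_ncchi_value_against_series_oracle(self):
        y = mu = phi = 1.0
        L = 3.0
        expected = (L * np.log(y) - np.log(phi) - (L - 1) * np.log(mu)
                    - (y**2 + mu**2) / (2 * phi)
                    + np.log(bessel_i_series(2, y * mu / phi)))
        assert ncchi_logpdf(y, mu, phi, L) == pytest.approx(expected, rel=1e-12)

    def test_ncchi_reduces_to_rician_at_L1(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0.05, 8.0, 100)
        mu = rng.uniform(0.05, 6.0, 100)
        phi = rng.uniform(0.1, 4.0, 100)
        np.testing.assert_allclose(ncchi_logpdf(y, mu, phi, 1.0),
                                   rician_logpdf(y, mu, phi), rtol=1e-14)

    @pytest.mark.parametrize("mu,phi,L", [
        (0.5, 0.5, 1.0), (2.0, 1.0, 1.0), (10.0, 2.0, 3.0),
        (1.0, 0.1, 4.5), (0.01, 1.0, 1.0), (30.0, 0.5, 2.0),
    ])
    def test_density_normalizes(self, mu, phi, L):
        val, err = integrate.quad(
            lambda y: np.exp(ncchi_logpdf(y, mu, phi, L)), 0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_gaussian_normalizes_and_center_value(self):
        p = ObsParams(mu=2.0, phi=0.7)
        assert gaussian_logpdf(2.0, p.mu, p.phi) == pytest.approx(
            -0.5 * np.log(2 * np.pi * 0.7))
        assert gaussian_logpdf(2.0 + np.sqrt(0.7), p.mu, p.phi) == pytest.approx(
            -0.5 * np.log(2 * np.pi * 0.7) - 0.5)
        val, _ = integrate.quad(lambda y: np.exp(gaussian_logpdf(y, 2.0, 0.7)),
                                -np.inf, np.inf)
        assert val == pytest.approx(1.0, abs=1e-10)

    def test_no_overflow_at_extreme_bessel_argument(self):
        # y*mu/phi up to 1e6 must stay finite (log-space Bessel)
        val = rician_logpdf(1e3, 1e3, 1.0)
        assert np.isfinite(val)
        val2 = ncchi_logpdf(1e4, 1e2, 1.0, L=4.0)
        assert np.isfinite(val2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rician_logpdf(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            rician_logpdf(1.0, 1.0, -1.0)
        with pytest.raises(ValueError):
            ncchi_logpdf(1.0, 1.0, 1.0, L=0.5)
        with pytest.raises(ValueError):
            ObsParams(mu=1.0, phi=0.0)

    def test_high_snr_gaussian_approximation(self):
        # the Rician approaches N(sqrt(mu^2+phi), phi) as mu/sqrt(phi) grows:
        # the central-mass log-density gap is O(snr^-2) and shrinks monotonely
        phi = 1.0

        def central_gap(mu):
            m = np.sqrt(mu**2 + phi)
            y = np.linspace(m - 2.58 * np.sqrt(phi), m + 2.58 * np.sqrt(phi), 200)
            return np.max(np.abs(rician_logpdf(y, mu, phi) - gaussian_logpdf(y, m, phi)))

        gaps = [central_gap(mu) for mu in (10.0, 20.0, 40.0)]
        assert gaps[0] < 2e-2
        assert gaps[1] < 1e-2
        assert gaps[0] > gaps[1] > gaps[2]


class TestLogBessel:
    @pytest.mark.parametrize("nu,x", [(0, 1e-3), (0, 1.0), (0, 50.0), (0, 1e6),
                                      (2, 0.5), (2.5, 700.0), (5, 1e-8)])
    def test_matches_series_or_asymptotics(self, nu, x):
        if x < 100:
            expected = np.log(bessel_i_series(nu, x, terms=200))
            assert log_bessel_i(nu, x) == pytest.approx(expected, rel=1e-10)
        else:
            # asymptotic: log I_nu(x) ~ x - 0.5 log(2 pi x)
            assert log_bessel_i(nu, x) == pytest.approx(
                x - 0.5 * np.log(2 * np.pi * x), rel=1e-3)


class TestDerivatives:
    @pytest.mark.parametrize("family,L", [("rician", 1.0), ("ncchi", 3.0),
                                          ("ncchi", 2.5), ("gaussian", 1.0)])
    def test_against_finite_differences(self, family, L):
        model = NoiseModel(family, L)
        rng = np.random.default_rng(42)
        h1 = 1e-5   # first differences
        h2 = 1e-4   # second differences (larger h balances roundoff)
        for _ in range(25):
            y = rng.uniform(0.2, 5.0)
            mu = rng.uniform(0.2, 5.0)
            phi = rng.uniform(0.3, 3.0)

            def f(m, p):
                if family == "gaussian":
                    return gaussian_logpdf(y, m, p)
                return ncchi_logpdf(y, m, p, L)

            d = dlogpdf(y, mu, phi, model)
            fd = {
                "dmu": (f(mu + h1, phi) - f(mu - h1, phi)) / (2 * h1),
                "dphi": (f(mu, phi + h1) - f(mu, phi - h1)) / (2 * h1),
                "dmu2": (f(mu + h2, phi) - 2 * f(mu, phi) + f(mu - h2, phi)) / h2**2,
                "dphi2": (f(mu, phi + h2) - 2 * f(mu, phi) + f(mu, phi - h2)) / h2**2,
                "dmudphi": (f(mu + h2, phi + h2) - f(mu + h2, phi - h2)
                            - f(mu - h2, phi + h2) + f(mu - h2, phi - h2)) / (4 * h2 * h2),
            }
            for key, fd_val in fd.items():
                scale = max(1.0, abs(fd_val))
                assert abs(float(d[key]) - fd_val) / scale < 1e-5, key

    def test_gaussian_score_closed_form(self):
        d = dlogpdf(2.0, 1.5, 0.5, NoiseModel("gaussian"))
        assert float(d["dmu"]) == pytest.approx((2.0 - 1.5) / 0.5)

    def test_rician_score_stable_near_zero_mean(self):
        # d/dmu -> -mu/phi (1 - y^2/(2 phi)) as mu -> 0 (series limit)
        y, phi = 1.3, 0.8
        for mu in (1e-4, 1e-6, 1e-9):
            d = dlogpdf(y, mu, phi, NoiseModel("rician"))
            limit = -mu / phi * (1.0 - y**2 / (2 * phi))
            assert float(d["dmu"]) == pytest.approx(limit, rel=1e-3)
            assert np.isfinite(float(d["dmu2"]))

    @pytest.mark.parametrize("family,L,side", [
        ("rician", 1.0, "mu"), ("rician", 1.0, "phi"),
        ("ncchi", 3.0, "mu"), ("ncchi", 3.0, "phi"),
        ("gaussian", 1.0, "mu"), ("gaussian", 1.0, "phi"),
    ])
    def test_fused_terms_match_reference(self, family, L, side):
        # the sampler's fused hot path must agree with the reference
        # logpdf/dlogpdf implementations
        from ricianreg import logpdf

        model = NoiseModel(family, L)
        rng = np.random.default_rng(3)
        y = rng.uniform(0.2, 5.0, 40)
        mu = rng.uniform(0.2, 5.0, 40)
        phi = rng.uniform(0.3, 3.0, 40)
        ll, d1, d2 = side_terms(y, mu, phi, model, side)
        assert ll == pytest.approx(float(np.sum(logpdf(y, mu, phi, model))), rel=1e-12)
        ref = dlogpdf(y, mu, phi, model)
        np.testing.assert_allclose(d1, ref["dmu" if side == "mu" else "dphi"], rtol=1e-10)
        np.testing.assert_allclose(d2, ref["dmu2" if side == "mu" else "dphi2"], rtol=1e-10)


class TestSampling:
    @pytest.mark.parametrize("family,L,mu", [("rician", 1.0, 2.0),
                                             ("ncchi", 3.0, 2.0),
                                             ("ncchi", 2.5, 1.0)])
    def test_second_moment_identity(self, family, L, mu):
        # E[y^2] = mu^2 + 2 L phi from the 2L-component construction
        model = NoiseModel(family, L)
        n = 200_000
        y = sample_magnitude(mu, 1.0, model, n=n, rng=np.random.default_rng(1))
        expected = mu**2 + 2 * model.effective_L
        se = np.std(y**2) / np.sqrt(n)
        assert abs(np.mean(y**2) - expected) < 4 * se

    def test_rayleigh_limit_mean(self):
        y = sample_magnitude(0.0, 1.0, NoiseModel("rician"), n=200_000,
                             rng=np.random.default_rng(2))
        assert np.mean(y) == pytest.approx(np.sqrt(np.pi / 2), abs=0.01)

    def test_moment_functions_match_samples(self):
        model = NoiseModel("ncchi", 3.0)
        y = sample_magnitude(2.0, 1.0, model, n=200_000, rng=np.random.default_rng(3))
        assert float(magnitude_mean(2.0, 1.0, model)) == pytest.approx(np.mean(y), abs=0.02)
        assert float(magnitude_var(2.0, 1.0, model)) == pytest.approx(np.var(y), rel=0.05)

    def test_samples_match_density_histogram(self):
        # KS-style check of the constructive sampler against the analytic CDF
        from scipy import stats

        mu, phi = 1.5, 0.7
        y = sample_magnitude(mu, phi, NoiseModel("rician"), n=50_000,
                             rng=np.random.default_rng(4))
        # Rician CDF via the noncentral chi-square representation of y^2
        cdf = stats.ncx2(df=2, nc=mu**2 / phi, scale=phi).cdf
        stat = stats.kstest(y**2, cdf).statistic
        assert stat < 0.01

    def test_reproducible_under_seed(self):
        a = sample_magnitude(2.0, 1.0, NoiseModel("ncchi", 2.0), n=100, rng=123)
        b = sample_magnitude(2.0, 1.0, NoiseModel("ncchi", 2.0), n=100, rng=123)
        np.testing.assert_array_equal(a, b)
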