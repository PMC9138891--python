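"""The ex-Gaussian engine: density, moments, sampling and MLE fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import exponnorm, norm

from exgauss_workload.errors import (
    DataError,
    DegenerateDataError,
    ParameterError,
    TooFewObservationsError,
)
from exgauss_workload.exgauss import (
    ExGaussParams,
    exgauss_loglik,
    exgauss_moments,
    exgauss_pdf,
    fit_exgauss,
    moment_init,
    sample_exgauss,
    sample_skewness,
)


def scipy_pdf(x, p):
    # scipy parameterises the same distribution by K = tau / sigma
    return exponnorm.pdf(x, p.tau / p.sigma, loc=p.mu, scale=p.sigma)


class TestPdf:
    def test_closed_form_standard_point(self):
        # f(0; mu=0, sigma=1, tau=1) = e^{1/2} Phi(-1), also the value of the
        # convolution integral of a standard normal with a unit exponential
        expected = math.exp(0.5) * norm.cdf(-1.0)
        assert exgauss_pdf(0.0, ExGaussParams(0, 1, 1)) == pytest.approx(expected, rel=1e-12)
        conv, _ = quad(lambda u: norm.pdf(-u) * math.exp(-u), 0, 50)
        assert exgauss_pdf(0.0, ExGaussParams(0, 1, 1)) == pytest.approx(conv, rel=1e-8)

    @pytest.mark.parametrize("mu,sigma,tau", [(500, 50, 150), (0, 1, 0.1), (-3, 2, 20), (10, 5, 0.5)])
    def test_matches_exponnorm_across_shapes(self, mu, sigma, tau):
        p = ExGaussParams(mu, sigma, tau)
        x = np.linspace(mu - 5 * sigma, mu + 5 * sigma + 10 * tau, 41)
        np.testing.assert_allclose(exgauss_pdf(x, p), scipy_pdf(x, p), rtol=1e-9)

    @pytest.mark.parametrize("ratio", [0.1, 0.5, 1.0, 2.0, 10.0])
    def test_normalises_to_one(self, ratio):
        p = ExGaussParams(500.0, 50.0, 50.0 / ratio)
        total, _ = quad(lambda x: exgauss_pdf(x, p), p.mu - 12 * p.sigma,
                        p.mu + 12 * p.sigma + 40 * p.tau, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_left_tail_vanishes(self):
        p = ExGaussParams(500, 50, 150)
        assert exgauss_pdf(-1e4, p) == pytest.approx(0.0, abs=1e-300)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ParameterError):
            ExGaussParams(0, -1, 1)
        with pytest.raises(ParameterError):
            ExGaussParams(0, 1, 0)
        with pytest.raises(DataError):
            exgauss_pdf(float("nan"), ExGaussParams(0, 1, 1))


class TestLoglik:
    def test_single_point_is_log_density(self):
        p = ExGaussParams(2, 1, 3)
        assert exgauss_loglik([4.0], p) == pytest.approx(math.log(exgauss_pdf(4.0, p)))

    def test_permutation_invariant(self, rng):
        p = ExGaussParams(0, 1, 1)
        x = sample_exgauss(50, p, rng)
        assert exgauss_loglik(x, p) == pytest.approx(exgauss_loglik(x[::-1], p))

    def test_generating_params_beat_shifted_mu(self):
        p = ExGaussParams(500, 50, 150)
        x = sample_exgauss(500, p, 7)
        shifted = ExGaussParams(p.mu + 5 * p.sigma, p.sigma, p.tau)
        assert exgauss_loglik(x, p) > exgauss_loglik(x, shifted)

    def test_empty_series_errors(self):
        with pytest.raises(DataError):
            exgauss_loglik([], ExGaussParams(0, 1, 1))


class TestSampling:
    def test_reproducible_and_mean_converges(self):
        p = ExGaussParams(500, 50, 150)
        a = sample_exgauss(100_000, p, 3)
        b = sample_exgauss(100_000, p, 3)
        np.testing.assert_array_equal(a, b)
        assert abs(a.mean() - 650) / 650 < 0.01
        assert abs(a.var(ddof=1) - p.variance) / p.variance < 0.05

    def test_larger_tau_gives_larger_skewness(self):
        big = sample_exgauss(100_000, ExGaussParams(500, 50, 150), 5)
        small = sample_exgauss(100_000, ExGaussParams(500, 50, 15), 5)
        assert sample_skewness(big) > sample_skewness(small)
        # consistent with the closed forms
        assert exgauss_moments(ExGaussParams(500, 50, 150))[2] > \
            exgauss_moments(ExGaussParams(500, 50, 15))[2]

    def test_n_below_one_errors(self):
        with pytest.raises(DataError):
            sample_exgauss(0, ExGaussParams(0, 1, 1), 0)


class TestMoments:
    def test_closed_forms_standard(self):
        mean, var, skew = exgauss_moments(ExGaussParams(0, 1, 1))
        assert (mean, var) == (1.0, 2.0)
        assert skew == pytest.approx(2 / 2**1.5)

    def test_skewness_matches_large_sample(self):
        p = ExGaussParams(0, 1, 2)
        x = sample_exgauss(400_000, p, 11)
        assert sample_skewness(x) == pytest.approx(exgauss_moments(p)[2], rel=0.05)

    def test_gaussian_limit(self):
        _, _, skew = exgauss_moments(ExGaussParams(0, 1, 1e-9))
        assert skew == pytest.approx(0.0, abs=1e-20)

    def test_skewness_monotone_in_tau(self):
        skews = [exgauss_moments(ExGaussParams(0, 1, t))[2] for t in (0.1, 0.5, 1, 2, 5, 20)]
        assert all(a < b for a, b in zip(skews, skews[1:]))


class TestSampleSkewness:
    def test_symmetric_series_is_zero(self):
        assert sample_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_invariant_under_positive_affine_map(self, a, b):
        x = np.array([0.3, 1.2, 5.0, 2.2, 0.9, 7.5])
        assert sample_skewness(a * x + b) == pytest.approx(sample_skewness(x), rel=1e-6)

    def test_degenerate_and_short_series_error(self):
        with pytest.raises(DegenerateDataError):
            sample_skewness([2.0, 2.0, 2.0])
        with pytest.raises(TooFewObservationsError):
            sample_skewness([1.0, 2.0])


def grid_min_nll(x):
    """Brute-force oracle: exhaustive NLL minimum over the parameter grid
    mu in mean +/- 2 sd (21 steps), sigma and tau in (0.05..2) sd (20 each)."""
    m, sd = x.mean(), x.std(ddof=1)
    best = np.inf
    for mu in np.linspace(m - 2 * sd, m + 2 * sd, 21):
        for sigma in np.linspace(0.05 * sd, 2 * sd, 20):
            for tau in np.linspace(0.05 * sd, 2 * sd, 20):
                nll = -exgauss_loglik(x, ExGaussParams(mu, sigma, tau))
                best = min(best, nll)
    return best


class TestFit:
    def test_recovers_generating_parameters(self):
        truth = ExGaussParams(500, 50, 150)
        res = fit_exgauss(sample_exgauss(2000, truth, 21))
        assert res.converged
        for name in ("mu", "sigma", "tau"):
            est, true = getattr(res.params, name), getattr(truth, name)
            assert abs(est - true) / true < 0.10

    def test_beats_grid_oracle_on_small_sample(self):
        x = sample_exgauss(40, ExGaussParams(10, 2, 5), 99)
        res = fit_exgauss(x)
        assert res.neg_log_likelihood <= grid_min_nll(x) + 1e-3

    def test_shift_equivariance(self):
        x = sample_exgauss(300, ExGaussParams(5, 1, 2), 17)
        base = fit_exgauss(x)
        shifted = fit_exgauss(x + 123.0)
        assert shifted.params.mu == pytest.approx(base.params.mu + 123.0, abs=0.05)
        assert shifted.params.sigma == pytest.approx(base.params.sigma, rel=0.02)
        assert shifted.params.tau == pytest.approx(base.params.tau, rel=0.02)

    def test_never_worse_than_moment_start(self):
        x = sample_exgauss(60, ExGaussParams(1, 0.3, 0.2), 5)
        res = fit_exgauss(x)
        start_nll = -exgauss_loglik(x, moment_init(x))
        assert res.neg_log_likelihood <= start_nll + 1e-9

    def test_gaussian_limit_mean_recovery(self):
        # nearly Gaussian data: fitted mu + tau tracks the sample mean
        x = sample_exgauss(3000, ExGaussParams(100, 10, 0.1), 13)
        res = fit_exgauss(x)
        assert res.params.mean == pytest.approx(x.mean(), rel=0.01)

    def test_errors_name_threshold_and_degeneracy(self):
        with pytest.raises(TooFewObservationsError, match="5"):
            fit_exgauss([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DegenerateDataError):
            fit_exgauss([3.0] * 10)
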