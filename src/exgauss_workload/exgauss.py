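"""The exponentially modified Gaussian (ex-Gaussian) distribution.

An ex-Gaussian random variable is the sum of a Normal(mu, sigma^2) and an
independent Exponential(tau) variable.  It is the standard model for
positively skewed response-time-like series: ``mu`` and ``sigma`` describe
the typical (Gaussian) performance mode, while ``tau`` is the mean of the
exponential right tail, the part of the distribution that holds the rare,
prolonged observations usually read as attentional lapses.

This module provides the density (evaluated in log space for numerical
stability), the log-likelihood, sampling, closed-form moments, and
maximum-likelihood fitting with moment-based initialisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr

from .errors import DataError, DegenerateDataError, ParameterError, TooFewObservationsError

__all__ = [
    "ExGaussParams",
    "FitResult",
    "MIN_FIT_OBSERVATIONS",
    "exgauss_pdf",
    "exgauss_logpdf",
    "exgauss_loglik",
    "sample_exgauss",
    "exgauss_moments",
    "sample_skewness",
    "moment_init",
    "fit_exgauss",
]

#: Minimum series length accepted by :func:`fit_exgauss` (after any trimming).
#: The shortest series the pipeline produces is a 10-s windowed count over a
#: 90-s task part: 9 values, 7 after extreme-value trimming.
MIN_FIT_OBSERVATIONS = 5


@dataclass(frozen=True)
class ExGaussParams:
    """Parameter triple of one ex-Gaussian distribution.

    Attributes
    ----------
    mu : float
        Location of the normal component, in measure units (s, deg, count).
    sigma : float
        Standard deviation of the normal component; strictly positive.
    tau : float
        Mean of the exponential component; strictly positive.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self):
        for name in ("mu", "sigma", "tau"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float, np.floating, np.integer)) and math.isfinite(float(v))):
                raise ParameterError(f"{name} must be a finite number, got {v!r}")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")

    @property
    def mean(self) -> float:
        return float(self.mu + self.tau)

    @property
    def variance(self) -> float:
        return float(self.sigma**2 + self.tau**2)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood ex-Gaussian fit."""

    params: ExGaussParams
    neg_log_likelihood: float
    converged: bool
    n_obs: int
    n_iter: int
    start: ExGaussParams

    def __post_init__(self):
        if self.converged and not math.isfinite(self.neg_log_likelihood):
            raise ParameterError("converged fit must have a finite negative log-likelihood")
        if self.n_obs < MIN_FIT_OBSERVATIONS:
            raise ParameterError(f"n_obs={self.n_obs} below minimum of {MIN_FIT_OBSERVATIONS}")


def _logpdf_raw(x: np.ndarray, mu: float, sigma: float, tau: float) -> np.ndarray:
    # log f(x) = -log tau + sigma^2/(2 tau^2) - (x-mu)/tau + log Phi((x-mu)/sigma - sigma/tau)
    # Working entirely in logs keeps the exp * Phi product stable even when
    # sigma/tau is large and both factors over/underflow individually.
    r = sigma / tau
    u = (x - mu) / sigma - r
    return -np.log(tau) + 0.5 * r * r - (x - mu) / tau + log_ndtr(u)


def _check_x(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("x must be finite")
    return arr


def exgauss_logpdf(x, params: ExGaussParams) -> np.ndarray | float:
    """Log-density of the ex-Gaussian distribution at ``x`` (scalar or array)."""
    arr = _check_x(x)
    out = _logpdf_raw(arr, params.mu, params.sigma, params.tau)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def exgauss_pdf(x, params: ExGaussParams) -> np.ndarray | float:
    """Density of the ex-Gaussian distribution at ``x`` (scalar or array)."""
    lp = exgauss_logpdf(x, params)
    return np.exp(lp) if isinstance(lp, np.ndarray) else math.exp(lp)


def exgauss_loglik(data, params: ExGaussParams) -> float:
    """Sum of log densities over a series.

    Returns ``-inf`` when any point has numerically zero density (the caller
    decides how to flag that); raises on an empty series.
    """
    arr = _check_x(data)
    if arr.size == 0:
        raise DataError("log-likelihood of an empty series is undefined")
    lp = _logpdf_raw(arr, params.mu, params.sigma, params.tau)
    total = float(np.sum(lp))
    return total if math.isfinite(total) else float("-inf")


def sample_exgauss(n: int, params: ExGaussParams, seed) -> np.ndarray:
    """Draw ``n`` variates as Normal(mu, sigma^2) + Exponential(tau).

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a ``Generator``.
    """
    if n < 1:
        raise DataError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(params.mu, params.sigma, int(n)) + rng.exponential(params.tau, int(n))


def exgauss_moments(params: ExGaussParams) -> tuple[float, float, float]:
    """Closed-form (mean, variance, skewness).

    mean = mu + tau, variance = sigma^2 + tau^2,
    skewness = 2 tau^3 / (sigma^2 + tau^2)^{3/2}; positive whenever tau > 0.
    """
    var = params.variance
    skew = 2.0 * params.tau**3 / var**1.5
    return params.mean, var, skew


def sample_skewness(data) -> float:
    """Moment estimator g1 = m3 / m2^{3/2} with central sample moments."""
    arr = _check_x(data)
    if arr.size < 3:
        raise TooFewObservationsError(f"skewness needs >= 3 observations, got {arr.size}")
    centered = arr - arr.mean()
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        raise DegenerateDataError("skewness undefined for a zero-variance series")
    m3 = float(np.mean(centered**3))
    return m3 / m2**1.5


def moment_init(data) -> ExGaussParams:
    """Moment-based starting point for the MLE.

    tau0 = sd * (g1/2)^{1/3} clipped to [0.05 sd, 0.95 sd]; mu0 = mean - tau0;
    sigma0 = sqrt(max(var - tau0^2, (0.05 sd)^2)).  The clipping keeps the
    start valid when the sample skewness is non-positive.
    """
    arr = _check_x(data)
    if arr.size < 3:
        raise TooFewObservationsError(f"moment initialisation needs >= 3 observations, got {arr.size}")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("cannot initialise on a zero-variance series")
    g1 = sample_skewness(arr)
    tau0 = sd * (max(g1, 0.0) / 2.0) ** (1.0 / 3.0)
    tau0 = float(np.clip(tau0, 0.05 * sd, 0.95 * sd))
    mu0 = float(np.mean(arr)) - tau0
    sigma0 = math.sqrt(max(sd**2 - tau0**2, (0.05 * sd) ** 2))
    return ExGaussParams(mu0, sigma0, tau0)


def fit_exgauss(
    data,
    *,
    min_n: int = MIN_FIT_OBSERVATIONS,
    fatol: float = 1e-8,
    xatol: float = 1e-8,
    maxiter: int = 2000,
) -> FitResult:
    """Maximum-likelihood ex-Gaussian fit.

    Minimises the negative log-likelihood with Nelder-Mead simplex search on
    ``(mu, log sigma, log tau)`` — the log transform enforces positivity —
    starting from :func:`moment_init`.  Simplex search never accepts an
    uphill step, so the fitted NLL is at most the NLL of the starting point.

    Raises
    ------
    TooFewObservationsError
        When the series is shorter than ``min_n``.
    DegenerateDataError
        When the series has zero variance.
    """
    arr = _check_x(data)
    if arr.size < min_n:
        raise TooFewObservationsError(
            f"ex-Gaussian fitting needs >= {min_n} observations, got {arr.size}"
        )
    if float(np.std(arr)) == 0.0:
        raise DegenerateDataError("cannot fit a zero-variance series")

    start = moment_init(arr)
    theta0 = np.array([start.mu, math.log(start.sigma), math.log(start.tau)])

    def nll(theta: np.ndarray) -> float:
        mu, ls, lt = theta
        if abs(ls) > 40 or abs(lt) > 40:
            return float("inf")
        with np.errstate(over="ignore", under="ignore"):
            lp = _logpdf_raw(arr, mu, math.exp(ls), math.exp(lt))
        total = float(np.sum(lp))
        return -total if math.isfinite(total) else float("inf")

    res = minimize(
        nll,
        theta0,
        method="Nelder-Mead",
        options={"fatol": fatol, "xatol": xatol, "maxiter": maxiter, "maxfev": 4 * maxiter},
    )
    mu_hat, ls_hat, lt_hat = res.x
    params = ExGaussParams(float(mu_hat), math.exp(float(ls_hat)), math.exp(float(lt_hat)))
    return FitResult(
        params=params,
        neg_log_likelihood=float(res.fun),
        converged=bool(res.success) and math.isfinite(float(res.fun)),
        n_obs=int(arr.size),
        n_iter=int(res.nit),
        start=start,
    )
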