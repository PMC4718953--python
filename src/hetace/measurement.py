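"""Graded-response probit measurement model for 3-category twin items.

Each ordinal item score X in {0, 1, 2} is generated by cutting a latent
propensity  y* = alpha * theta + eps  at two ordered thresholds
(tau1 < tau2); eps has unit variance (probit convention) and is
correlated across co-twins with item- and zygosity-specific residual
correlation r, capturing item-specific familial variance beyond the
latent phenotype.

Exact bivariate rectangle probabilities are provided for likelihood
tests; the MCMC sampler itself uses kernel augmentation and only needs
the univariate category probabilities.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.special import ndtr

from hetace.params import MeasurementParams

__all__ = [
    "category_probabilities",
    "pair_item_loglikelihood",
    "propensity_residual_cov",
    "bvn_cdf",
    "rectangle_probability",
]


def category_probabilities(theta, alpha, tau1, tau2):
    """P(X = 0), P(X = 1), P(X = 2) for a graded-response probit item.

    Returns ``(Phi(tau1 - alpha*theta), Phi(tau2 - alpha*theta) -
    Phi(tau1 - alpha*theta), 1 - Phi(tau2 - alpha*theta))``; the triple
    sums to one.  Broadcasts over array-valued ``theta``.
    """
    if not np.all(np.asarray(tau1) < np.asarray(tau2)):
        raise ValueError("thresholds must satisfy tau1 < tau2")
    theta = np.asarray(theta, dtype=float)
    lo = ndtr(tau1 - alpha * theta)
    hi = ndtr(tau2 - alpha * theta)
    return lo, hi - lo, 1.0 - hi


def _bvn_cdf_scalar(a: float, b: float, rho: float) -> float:
    """P(Z1 < a, Z2 < b) for standard bivariate normal with correlation rho.

    Uses the Plackett identity  Phi2(a,b;rho) = Phi(a)Phi(b)
    + (1/2pi) * int_0^rho exp(-(a^2 - 2abt + b^2)/(2(1-t^2))) / sqrt(1-t^2) dt,
    evaluated by adaptive quadrature; deterministic with absolute error
    well below 1e-10.
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("correlation must be in (-1, 1)")
    if math.isinf(a) or math.isinf(b):
        if a == -math.inf or b == -math.inf:
            return 0.0
        if a == math.inf:
            return float(ndtr(b))
        return float(ndtr(a))
    base = float(ndtr(a)) * float(ndtr(b))
    if rho == 0.0:
        return base

    def integrand(t: float) -> float:
        om = 1.0 - t * t
        return math.exp(-(a * a - 2.0 * a * b * t + b * b) / (2.0 * om)) / math.sqrt(om)

    corr, _ = quad(integrand, 0.0, rho, epsabs=1e-13, epsrel=1e-12)
    val = base + corr / (2.0 * math.pi)
    return min(1.0, max(0.0, val))


def bvn_cdf(a, b, rho):
    """Vectorised standard bivariate normal CDF (see :func:`_bvn_cdf_scalar`)."""
    return np.vectorize(_bvn_cdf_scalar, otypes=[float])(a, b, rho)


def rectangle_probability(lo1: float, hi1: float, lo2: float, hi2: float, rho: float) -> float:
    """P(lo1 < Z1 < hi1, lo2 < Z2 < hi2) under correlation rho."""
    return (
        _bvn_cdf_scalar(hi1, hi2, rho)
        - _bvn_cdf_scalar(lo1, hi2, rho)
        - _bvn_cdf_scalar(hi1, lo2, rho)
        + _bvn_cdf_scalar(lo1, lo2, rho)
    )


def _category_bounds(x: int, tau1: float, tau2: float) -> tuple[float, float]:
    if x == 0:
        return -math.inf, tau1
    if x == 1:
        return tau1, tau2
    if x == 2:
        return tau2, math.inf
    raise ValueError(f"score must be 0, 1 or 2; got {x!r}")


def pair_item_loglikelihood(x1, x2, theta1: float, theta2: float, params: MeasurementParams, item: int, zygosity: str) -> float:
    """Exact log-probability of one item's scores for both twins.

    The propensities (y*_1, y*_2) are jointly normal with means
    (alpha*theta1, alpha*theta2), unit variances and correlation
    ``r_MZ`` or ``r_DZ`` per zygosity; the score pair identifies a
    rectangle whose probability is computed exactly.  A missing member
    (``None`` or NaN) is marginalised out; both missing yields 0.
    """
    for th in (theta1, theta2):
        if th is not None and not math.isfinite(th):
            raise ValueError("non-finite theta")
    alpha = params.alpha[item]
    tau1, tau2 = params.tau1[item], params.tau2[item]
    rho = float(params.r(zygosity)[item])

    def missing(x) -> bool:
        return x is None or (isinstance(x, float) and math.isnan(x))

    if missing(x1) and missing(x2):
        return 0.0
    if missing(x1) or missing(x2):
        x, theta = (x2, theta2) if missing(x1) else (x1, theta1)
        lo, hi = _category_bounds(int(x), tau1, tau2)
        hi_cdf = float(ndtr(hi - alpha * theta)) if math.isfinite(hi) else 1.0
        lo_cdf = float(ndtr(lo - alpha * theta)) if math.isfinite(lo) else 0.0
        return math.log(max(hi_cdf - lo_cdf, 1e-300))
    lo1, hi1 = _category_bounds(int(x1), tau1, tau2)
    lo2, hi2 = _category_bounds(int(x2), tau1, tau2)
    m1, m2 = alpha * theta1, alpha * theta2
    p = rectangle_probability(lo1 - m1, hi1 - m1, lo2 - m2, hi2 - m2, rho)
    return math.log(max(p, 1e-300))


def propensity_residual_cov(zygosity: str, params: MeasurementParams) -> np.ndarray:
    """Per-item 2x2 residual covariance of the co-twin propensities.

    Unit variances with off-diagonal r_zyg per item; shape (n_items, 2, 2).
    """
    r = params.r(zygosity)
    out = np.empty((params.n_items, 2, 2))
    out[:, 0, 0] = out[:, 1, 1] = 1.0
    out[:, 0, 1] = out[:, 1, 0] = r
    return out
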