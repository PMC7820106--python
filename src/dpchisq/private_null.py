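"""The privatized null distribution: chi-squared plus Laplace noise.

Releasing ``chi2 + Laplace(beta)`` with ``beta = Delta/epsilon`` changes the
null distribution of the released statistic: under the null hypothesis the
statistic is (approximately) chi-squared with ``v`` degrees of freedom, so
the released value follows the additive convolution

    g_{v,Delta,eps}(x) = int_0^inf  Lap_{mu,beta}(x) * f_{chi2_v}(mu) dmu ,

where ``Lap_{mu,beta}`` is the Laplace density centered at ``mu``.  Decisions
calibrated against the classical chi-squared table would be anti-conservative
or conservative depending on the noise scale; instead the rejection threshold
``t`` solves  P_g(X >= t) = alpha  and the private p-value is the upper tail
of ``g`` at the released statistic.

Numerics
--------
The upper tail is never computed by integrating the density twice.  Exchanging
the order of integration gives

    P(X >= x) = int_0^inf f_{chi2_v}(mu) * S_L(x - mu; beta) dmu ,

with ``S_L`` the closed-form Laplace survival function.  Splitting at
``mu = x`` leaves one well-conditioned finite integral plus closed forms:

    P(X >= x) = S_v(x) + 1/2 * I(x) - 1/2 * exp(x/b - v/2 log k) * S_v(k x),
    I(x)      = int_0^x f_{chi2_v}(mu) exp(-(x-mu)/b) dmu,   k = 1 + 2/b,

using  int_x^inf f_v(mu) e^{-mu/b} dmu = k^{-v/2} S_v(k x)  (a rescaled
chi-squared tail) and, for x <= 0, the exact Laplace transform
``P(X >= x) = 1 - exp(x/b) * (1+2/b)^{-v/2} / 2``.  The remaining integral
``I(x)`` is evaluated by adaptive quadrature after a substitution that removes
both the ``mu^{v/2-1}`` endpoint singularity (v = 1) and the exponential
boundary layer at ``mu = x`` when ``beta`` is small.  The density ``g`` uses
the same pieces.  All exponentials are assembled in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import exp, lgamma, log, sqrt, pi

import numpy as np
from scipy import integrate, optimize
from scipy.stats import chi2 as _chi2

from .exceptions import BracketError, QuadratureError

__all__ = [
    "PrivateNull",
    "noisy_null_pdf",
    "noisy_null_upper_tail",
    "critical_value",
]

_SQRT_2_OVER_PI = sqrt(2.0 / pi)


def _chi2_logsf(x: float, v: int) -> float:
    """log of the chi-squared survival function, safe for extreme tails.

    scipy's logsf underflows to -inf once sf(x) < the smallest double,
    which happens routinely here: the closed-form tail piece evaluates
    S_v(kappa * x) with kappa ~ 2/beta, enormous when the noise is small.
    Beyond the representable range, use the standard asymptotic series
    Gamma(a, z) ~ z^{a-1} e^{-z} (1 + (a-1)/z + (a-1)(a-2)/z^2 + ...).
    """
    from scipy.special import gammaincc

    a, z = 0.5 * v, 0.5 * x
    direct = gammaincc(a, z)
    if direct > 1e-280:
        return log(direct)
    series = 1.0
    term = 1.0
    for k in range(1, 12):
        term *= (a - k) / z
        series += term
        if abs(term) < 1e-17:
            break
    return -z + (a - 1.0) * log(z) - lgamma(a) + log(max(series, 1e-300))


def _chi2_pdf(x: float, v: int) -> float:
    # Scalar chi-squared density; quadrature integrands call this hot, and
    # the scipy distribution machinery is ~20x slower per scalar call.
    if x <= 0.0:
        return 0.5 if (v == 2 and x == 0.0) else 0.0
    return exp(
        (0.5 * v - 1.0) * log(x) - 0.5 * x - 0.5 * v * log(2.0) - lgamma(0.5 * v)
    )


@dataclass(frozen=True)
class PrivateNull:
    """Parameters (v, Delta, epsilon) of the Laplace-convolved null."""

    dof: int
    sensitivity: float
    epsilon: float

    def __post_init__(self):
        if self.dof < 1:
            raise ValueError(f"dof must be >= 1, got {self.dof}")
        if not self.sensitivity > 0:
            raise ValueError(f"sensitivity must be > 0, got {self.sensitivity}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")

    @property
    def scale(self) -> float:
        """Laplace scale beta = Delta / epsilon."""
        return self.sensitivity / self.epsilon


def _exp_tilted_chi2_integral(v: int, beta: float, x: float, epsabs: float) -> float:
    """I(x) = int_0^x chi2_v.pdf(mu) * exp(-(x - mu)/beta) dmu.

    Two parameterizations, chosen by the boundary-layer width x/beta:

    * wide layer (x/beta < 40): for v = 1 substitute mu = y^2, which turns
      the singular density into sqrt(2/pi) e^{-y^2/2}; for v >= 2 integrate
      in w = (x - mu)/beta directly over the full range.
    * narrow layer (x/beta >= 40): integrate in w over [0, ~45]; the
      discarded mass is below e^-40 of the total.  For v = 1 the upper
      limit additionally stays 3 scales clear of the mu = 0 singularity,
      which then carries weight < e^-37.
    """
    if x <= 0:
        return 0.0
    ratio = x / beta
    if v == 1 and ratio < 40.0:
        def f(y):
            return _SQRT_2_OVER_PI * exp(-0.5 * y * y - (x - y * y) / beta)

        val, err = integrate.quad(f, 0.0, sqrt(x), epsabs=epsabs, limit=200)
    else:
        upper = min(ratio - 3.0, 45.0) if v == 1 else min(ratio, 45.0)

        def f(w):
            return _chi2_pdf(x - beta * w, v) * exp(-w)

        val, err = integrate.quad(f, 0.0, upper, epsabs=epsabs, limit=200)
        val *= beta
        err *= beta
    if err > max(1e-8, 1e-6 * abs(val)):
        raise QuadratureError(
            f"quadrature error {err:.2e} for I({x}) at v={v}, beta={beta}",
            achieved=err,
        )
    return val


def _log_upper_piece(v: int, beta: float, x: float) -> float:
    """log of  exp(x/beta) * kappa^{-v/2} * S_v(kappa * max(x, 0))."""
    kappa = 1.0 + 2.0 / beta
    tail = _chi2_logsf(kappa * x, v) if x > 0 else 0.0
    return x / beta - 0.5 * v * log(kappa) + tail


def noisy_null_pdf(x: float, null: PrivateNull) -> float:
    """Density g_{v,Delta,eps}(x) of chi-squared-plus-Laplace."""
    v, beta = null.dof, null.scale
    if x <= 0:
        return exp(_log_upper_piece(v, beta, x)) / (2.0 * beta)
    i_mid = _exp_tilted_chi2_integral(v, beta, x, epsabs=1e-12)
    return (i_mid + exp(_log_upper_piece(v, beta, x))) / (2.0 * beta)


def noisy_null_upper_tail(x: float, null: PrivateNull) -> float:
    """P(X >= x) for X ~ g_{v,Delta,eps}; the private p-value at x.

    Defined for every real ``x`` (the noisy statistic can be negative).
    """
    v, beta = null.dof, null.scale
    if x <= 0:
        value = 1.0 - 0.5 * exp(_log_upper_piece(v, beta, x))
    else:
        i_mid = _exp_tilted_chi2_integral(v, beta, x, epsabs=1e-11)
        value = (
            _chi2.sf(x, v)
            + 0.5 * i_mid
            - 0.5 * exp(_log_upper_piece(v, beta, x))
        )
    return min(1.0, max(0.0, float(value)))


@lru_cache(maxsize=100_000)
def _critical_value_cached(v: int, sensitivity: float, epsilon: float, alpha: float) -> float:
    null = PrivateNull(v, sensitivity, epsilon)
    beta = null.scale

    def f(t):
        return noisy_null_upper_tail(t, null) - alpha

    spread = beta * log(1.0 / (2.0 * alpha)) if alpha < 0.5 else beta
    lo = -spread - 1.0
    hi = float(_chi2.ppf(1.0 - alpha, v)) + spread + 1.0
    f_lo, f_hi = f(lo), f(hi)
    width = hi - lo
    for _ in range(60):
        if f_lo > 0 >= f_hi:
            break
        width *= 2.0
        if f_lo <= 0:
            lo -= width
            f_lo = f(lo)
        if f_hi > 0:
            hi += width
            f_hi = f(hi)
    else:
        raise BracketError(
            f"could not bracket critical value for v={v}, beta={beta}, alpha={alpha}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, maxiter=200))


def critical_value(null: PrivateNull, alpha: float) -> float:
    """Threshold t with P_g(X >= t) = alpha; the calibrated rejection cutoff.

    Found by bracketed root refinement on the strictly decreasing tail.
    Results are memoized per (v, Delta, epsilon, alpha) within the process.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return _critical_value_cached(null.dof, null.sensitivity, null.epsilon, float(alpha))
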