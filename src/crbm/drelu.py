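"""Double-rectified-linear-unit (dReLU) hidden-unit mathematics.

The dReLU potential on a real-valued hidden unit ``h`` is

    U(h) = 1/2 gamma_plus h_+^2 + theta_plus h_+
         + 1/2 gamma_minus h_-^2 + theta_minus h_-,

with ``h_+ = max(h, 0)`` and ``h_- = min(h, 0)``.  Depending on its four
parameters the potential is quadratic (``gamma_+ = gamma_-``,
``theta_+ = theta_-``), ReLU-like, or a double well, which is what makes
the unit's conditional distribution Gaussian, rectified or bimodal.

Given the linear input ``I`` from the visible layer, the conditional
density of the unit is ``p(h | I) ∝ exp(-U(h) + h I)``: a two-component
mixture of Gaussians truncated to the positive and negative half-lines.
Everything in this module follows from that observation:

* the cumulant generating function ``Gamma(I) = log ∫ exp(-U(h) + h I) dh``
  is the log of the sum of the two truncated-Gaussian normalisers,
* ``Gamma'(I)`` and ``Gamma''(I)`` are the conditional mean and variance,
* exact sampling picks a branch by its probability mass and then draws a
  truncated Gaussian by inverse CDF.

All evaluations are routed through :func:`scipy.special.log_ndtr`,
:func:`scipy.special.erfcx` and :func:`scipy.special.ndtri_exp` so that
no finite input ever produces a NaN or Inf: extreme inputs fall back to
the asymptotically exact tail expressions those functions implement.

Every function broadcasts: ``I`` may be an array of shape ``(..., M)``
against per-unit parameter vectors of shape ``(M,)``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import erfcx, expit, log_ndtr, ndtri_exp

__all__ = [
    "DReLUMoments",
    "drelu_potential",
    "cumulant",
    "moments",
    "sample",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


def _validate_gammas(gamma_plus, gamma_minus) -> None:
    if np.any(np.asarray(gamma_plus) <= 0) or np.any(np.asarray(gamma_minus) <= 0):
        raise ValueError("dReLU curvatures gamma_plus and gamma_minus must be > 0")


def drelu_potential(h, gamma_plus, gamma_minus, theta_plus, theta_minus):
    """Evaluate the dReLU potential U(h) elementwise.

    ``U(0) = 0`` by construction (both half-line branches vanish there).
    """
    _validate_gammas(gamma_plus, gamma_minus)
    h = np.asarray(h, dtype=float)
    hp = np.maximum(h, 0.0)
    hm = np.minimum(h, 0.0)
    return (
        0.5 * gamma_plus * hp**2
        + theta_plus * hp
        + 0.5 * gamma_minus * hm**2
        + theta_minus * hm
    )


def _inverse_mills(alpha):
    """phi(alpha) / Phi(-alpha), stable for arbitrarily large |alpha|."""
    return _SQRT_2_OVER_PI / erfcx(alpha / np.sqrt(2.0))


def _branch_log_partitions(I, gamma_plus, gamma_minus, theta_plus, theta_minus):
    """Log normalisers of the positive- and negative-branch integrals.

    log Z+ = log ∫_0^∞ exp(-1/2 g+ h^2 + (I - t+) h) dh and the mirror
    image for Z-.  Completing the square gives a Gaussian CDF factor that
    is evaluated in log space.
    """
    a_p = I - theta_plus
    a_m = I - theta_minus
    log_zp = (
        a_p**2 / (2.0 * gamma_plus)
        + _HALF_LOG_2PI
        - 0.5 * np.log(gamma_plus)
        + log_ndtr(a_p / np.sqrt(gamma_plus))
    )
    log_zm = (
        a_m**2 / (2.0 * gamma_minus)
        + _HALF_LOG_2PI
        - 0.5 * np.log(gamma_minus)
        + log_ndtr(-a_m / np.sqrt(gamma_minus))
    )
    return log_zp, log_zm


def cumulant(I, gamma_plus, gamma_minus, theta_plus, theta_minus):
    """Cumulant generating function Gamma(I) of the dReLU unit."""
    _validate_gammas(gamma_plus, gamma_minus)
    I = np.asarray(I, dtype=float)
    log_zp, log_zm = _branch_log_partitions(
        I, gamma_plus, gamma_minus, theta_plus, theta_minus
    )
    return np.logaddexp(log_zp, log_zm)


class DReLUMoments(NamedTuple):
    """Conditional moments of a dReLU unit given its input.

    ``mean`` is Gamma'(I) and ``var`` is Gamma''(I).  The rectified
    moments ``hp_mean = <h_+ | I>``, ``hp_sq_mean = <h_+^2 | I>`` (and the
    negative-branch analogues) are the sufficient statistics that appear
    in the likelihood gradients for theta_± and gamma_±.
    """

    log_partition: np.ndarray
    p_plus: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    hp_mean: np.ndarray
    hp_sq_mean: np.ndarray
    hm_mean: np.ndarray
    hm_sq_mean: np.ndarray


def moments(I, gamma_plus, gamma_minus, theta_plus, theta_minus) -> DReLUMoments:
    """Closed-form conditional moments of h given input I.

    The conditional law is a mixture of a Gaussian truncated to h >= 0
    (weight ``p_plus``) and one truncated to h <= 0.  Branch means and
    variances use the inverse Mills ratio through ``erfcx``; the mixture
    variance is assembled in the cancellation-free form
    ``p+ v+ + p- v- + p+ p- (mu+ - mu-)^2`` so Gamma''(I) > 0 always.
    """
    _validate_gammas(gamma_plus, gamma_minus)
    I = np.asarray(I, dtype=float)
    log_zp, log_zm = _branch_log_partitions(
        I, gamma_plus, gamma_minus, theta_plus, theta_minus
    )
    log_partition = np.logaddexp(log_zp, log_zm)
    p_plus = expit(log_zp - log_zm)
    p_minus = 1.0 - p_plus

    a_p = I - theta_plus
    a_m = I - theta_minus
    sigma_p = 1.0 / np.sqrt(gamma_plus)
    sigma_m = 1.0 / np.sqrt(gamma_minus)
    m_p = a_p / gamma_plus
    m_m = a_m / gamma_minus

    # Positive branch: N(m_p, sigma_p^2) truncated to [0, inf).
    alpha = -a_p / np.sqrt(gamma_plus)  # standardized lower bound
    lam = _inverse_mills(alpha)
    mu_p = m_p + sigma_p * lam
    var_p = np.maximum(sigma_p**2 * (1.0 + alpha * lam - lam**2), 0.0)

    # Negative branch: N(m_m, sigma_m^2) truncated to (-inf, 0].
    beta = -a_m / np.sqrt(gamma_minus)  # standardized upper bound
    delta = _inverse_mills(-beta)  # phi(beta) / Phi(beta)
    mu_m = m_m - sigma_m * delta
    var_m = np.maximum(sigma_m**2 * (1.0 - beta * delta - delta**2), 0.0)

    mean = p_plus * mu_p + p_minus * mu_m
    var = p_plus * var_p + p_minus * var_m + p_plus * p_minus * (mu_p - mu_m) ** 2

    return DReLUMoments(
        log_partition=log_partition,
        p_plus=p_plus,
        mean=mean,
        var=var,
        hp_mean=p_plus * mu_p,
        hp_sq_mean=p_plus * (var_p + mu_p**2),
        hm_mean=p_minus * mu_m,
        hm_sq_mean=p_minus * (var_m + mu_m**2),
    )


def _sample_lower_truncated(alpha, u):
    """Draw xi ~ N(0,1) conditioned on xi > alpha via inverse CDF.

    Uses the survival-function parameterisation
    ``Phi(-xi) = u * Phi(-alpha)`` evaluated entirely in log space
    (``ndtri_exp`` inverts ``log_ndtr``), which stays exact arbitrarily
    deep in the tail.
    """
    log_u = np.log1p(-u)  # u in [0,1) -> log of a (0,1] variate
    return -ndtri_exp(log_u + log_ndtr(-alpha))


def sample(I, gamma_plus, gamma_minus, theta_plus, theta_minus, rng: np.random.Generator):
    """Exact sample of h ~ p(h | I) for each element of ``I``.

    Selects the positive/negative branch with probability equal to its
    share of the partition function, then inverse-CDF samples the
    truncated Gaussian of that branch.
    """
    _validate_gammas(gamma_plus, gamma_minus)
    I = np.asarray(I, dtype=float)
    log_zp, log_zm = _branch_log_partitions(
        I, gamma_plus, gamma_minus, theta_plus, theta_minus
    )
    p_plus = expit(log_zp - log_zm)

    take_plus = rng.random(size=I.shape) < p_plus
    u = rng.random(size=I.shape)

    a_p = I - theta_plus
    a_m = I - theta_minus
    sigma_p = 1.0 / np.sqrt(gamma_plus)
    sigma_m = 1.0 / np.sqrt(gamma_minus)

    alpha = -a_p / np.sqrt(gamma_plus)
    h_pos = a_p / gamma_plus + sigma_p * _sample_lower_truncated(
        np.broadcast_to(alpha, I.shape), u
    )
    beta = -a_m / np.sqrt(gamma_minus)
    # h < 0 with standardized upper bound beta: negate a lower-truncated draw.
    h_neg = a_m / gamma_minus - sigma_m * _sample_lower_truncated(
        np.broadcast_to(-beta, I.shape), u
    )

    h = np.where(take_plus, np.maximum(h_pos, 0.0), np.minimum(h_neg, 0.0))
    return h
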