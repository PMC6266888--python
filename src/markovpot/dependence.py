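"""Frechet marginal transform and the bivariate logistic extreme-value model.

The marginal cdf on the negated scale is

    F(x) = 1 - lambda_u [1 + xi (x - u)/sigma]^(-1/xi),   x >= u,

censored at F(u) = 1 - lambda_u below the threshold.  The transform

    z = -1 / log F(x)

puts observations on the standard Frechet scale (P(Z <= z) = exp(-1/z)).
Lag-1 pairs follow the logistic bivariate extreme-value distribution

    G(z1, z2) = exp(-V),    V = (z1^(-1/a) + z2^(-1/a))^a,   0 < a <= 1,

where a = 1 is independence and a -> 0 complete dependence.  The censored
pair density has four regions relative to the threshold: a full mixed
partial when both coordinates exceed u, a single partial derivative
evaluated at the censoring point when one does, and the point mass
G(z_u, z_u) = (1 - lambda_u)^(2^a) when neither does.

All densities are computed in log space; derivatives are analytic (the
numerical-differentiation fallback lives in the test suite only).

The ``frechet_rate`` switch selects the marginal transform: "empirical"
(the default; lambda_u estimated from the data, which keeps the censored
mass non-degenerate) or "unit" (lambda = 1 in the above-threshold
transform only — the textbook transform of the exceedance distribution
itself, kept for comparison).
"""

from __future__ import annotations

import math

import numpy as np

from .gpd import GPDTail, _log_tail_terms

REGIONS = ("both-above", "first-above", "second-above", "both-below")


def classify_region(x_t: float, x_prev: float, u: float) -> str:
    """Region of a lag-1 pair relative to the threshold u."""
    at, ap = x_t > u, x_prev > u
    if at and ap:
        return "both-above"
    if at:
        return "first-above"
    if ap:
        return "second-above"
    return "both-below"


def _transform_rate(tail: GPDTail, frechet_rate: str) -> float:
    if frechet_rate == "empirical":
        return tail.lambda_u
    if frechet_rate == "unit":
        return 1.0
    raise ValueError(f"unknown frechet_rate {frechet_rate!r}")


def _marginal_quantities(x, tail: GPDTail, frechet_rate="empirical"):
    """(logF, logz, log dz/dx) at exceedances x >= u.

    dz/dx = F'(x) / (F (log F)^2) with F'(x) = lambda h(x); in log form
    log dz/dx = log(lam) + log h - log F + 2 log z.
    """
    lam = _transform_rate(tail, frechet_rate)
    terms = _log_tail_terms(x, tail.u, tail.sigma, tail.xi)
    if terms is None:
        raise ValueError("x outside the support of the fitted tail")
    logsf, logh = terms
    lam_sf = lam * np.exp(logsf)
    if np.any(lam_sf >= 1.0):
        raise ValueError("marginal cdf <= 0; cannot map to Frechet")
    logF = np.log1p(-lam_sf)  # stays negative even when F rounds to 1
    if np.any(logF == 0.0):
        raise ValueError("marginal cdf rounds to 1; cannot map to Frechet")
    logz = -np.log(-logF)
    log_dzdx = math.log(lam) + logh - logF + 2.0 * logz
    return logF, logz, log_dzdx


def frechet_threshold(tail: GPDTail) -> float:
    """Frechet-scale image of the threshold, z_u = -1/log(1 - lambda_u)."""
    if tail.lambda_u >= 1.0:
        return 0.0
    return -1.0 / math.log1p(-tail.lambda_u)


def to_frechet(x, tail: GPDTail, frechet_rate: str = "empirical"):
    """Map negated-scale observations to the standard Frechet scale.

    Values below the threshold are censored: they map to the threshold's
    Frechet value z_u.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    z = np.full(x.shape, frechet_threshold(tail))
    above = x >= tail.u
    if np.any(above):
        _, logz, _ = _marginal_quantities(x[above], tail, frechet_rate)
        z[above] = np.exp(logz)
    return float(z[0]) if scalar else z


def from_frechet(z, tail: GPDTail, frechet_rate: str = "empirical"):
    """Inverse of :func:`to_frechet` on the uncensored branch (z > z_u)."""
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    if np.any(z <= 0):
        raise ValueError("Frechet values must be positive")
    lam = _transform_rate(tail, frechet_rate)
    sf = -np.expm1(-1.0 / z) / lam  # (1 - F)/lam without rounding F to 1
    if np.any(sf >= 1.0) or np.any(sf <= 0.0):
        raise ValueError("z below the censoring point; inverse undefined")
    if tail.xi == 0.0:
        x = tail.u - tail.sigma * np.log(sf)
    else:
        x = tail.u + tail.sigma / tail.xi * (sf ** -tail.xi - 1.0)
    return float(x[0]) if scalar else x


# ---------------------------------------------------------------------------
# logistic family on the Frechet scale


def _check_alpha(alpha: float) -> float:
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return float(alpha)


def logistic_joint_cdf(z1, z2, alpha):
    """G(z1, z2) = exp(-(z1^(-1/a) + z2^(-1/a))^a); symmetric in (z1, z2)."""
    a = _check_alpha(alpha)
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.any(z1 <= 0) or np.any(z2 <= 0):
        raise ValueError("Frechet values must be positive")
    with np.errstate(divide="ignore"):
        V = (z1 ** (-1.0 / a) + z2 ** (-1.0 / a)) ** a
    out = np.exp(-V)
    return float(out) if out.ndim == 0 else out


def chi_measure(alpha) -> float:
    """Tail-dependence coefficient chi = 2 - 2^alpha of the logistic model.

    For the logistic family the level-q dependence measure
    2 - log C(q, q)/log q is constant in q, so chi is exact at every
    threshold level, not only in the limit.
    """
    return 2.0 - 2.0 ** _check_alpha(alpha)


def _logs_pair(logz1, logz2, a):
    """log s with s = z1^(-1/a) + z2^(-1/a), stably via logaddexp."""
    return np.logaddexp(-logz1 / a, -logz2 / a)


def _log_density_z(logz1, logz2, a):
    """log of the mixed partial of G wrt (z1, z2) at (z1, z2).

    d2G/dz1 dz2 = G z1^(-1/a-1) z2^(-1/a-1) s^(a-2) (s^a + (1-a)/a).
    """
    logs = _logs_pair(logz1, logz2, a)
    V = np.exp(a * logs)
    return (
        -V
        + (a - 2.0) * logs
        + (-1.0 / a - 1.0) * (logz1 + logz2)
        + np.log(V + (1.0 - a) / a)
    )


def _log_partial_z(logz_free, logz_cens, a):
    """log dG/dz_free at (z_free, z_cens): G s^(a-1) z_free^(-1/a-1)."""
    logs = _logs_pair(logz_free, logz_cens, a)
    V = np.exp(a * logs)
    return -V + (a - 1.0) * logs + (-1.0 / a - 1.0) * logz_free


def logistic_conditional_cdf(z2, z1, alpha):
    """P(Z_t <= z2 | Z_{t-1} = z1) under the logistic pair law.

    Equals (dG/dz1) / g(z1) with g the standard Frechet density:
    exp(1/z1 - V) s^(a-1) z1^(1 - 1/a).  Monotone increasing in z2 from
    0 to 1; at a = 1 it reduces to exp(-1/z2).
    """
    a = _check_alpha(alpha)
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    logz1, logz2 = np.log(z1), np.log(z2)
    logs = _logs_pair(logz1, logz2, a)
    V = np.exp(a * logs)
    out = np.exp(1.0 / z1 - V + (a - 1.0) * logs + (1.0 - 1.0 / a) * logz1)
    return float(out) if out.ndim == 0 else out


def censored_both_below_logmass(tail: GPDTail, alpha) -> float:
    """log G(z_u, z_u) = 2^alpha * log(1 - lambda_u)."""
    a = _check_alpha(alpha)
    if tail.lambda_u >= 1.0:
        return -math.inf
    return (2.0 ** a) * math.log1p(-tail.lambda_u)


def censored_pair_density(
    x_t: float,
    x_prev: float,
    tail: GPDTail,
    alpha: float,
    frechet_rate: str = "empirical",
) -> float:
    """Four-region censored density of a lag-1 pair on the negated scale.

    both-above: full mixed partial of G composed with the marginal
    transform (chain rule, analytic); one-above: partial derivative of the
    joint cdf in the uncensored argument, evaluated at the threshold in
    the other; both-below: the probability mass G(z_u, z_u).  Summed and
    integrated over the four regions the total is 1.
    """
    a = _check_alpha(alpha)
    region = classify_region(x_t, x_prev, tail.u)
    logzu = math.log(frechet_threshold(tail)) if tail.lambda_u < 1.0 else -math.inf
    if region == "both-above":
        _, logz, logj = _marginal_quantities(
            np.array([x_t, x_prev]), tail, frechet_rate
        )
        return float(
            np.exp(_log_density_z(logz[0], logz[1], a) + logj[0] + logj[1])
        )
    if region in ("first-above", "second-above"):
        x_above = x_t if region == "first-above" else x_prev
        _, logz, logj = _marginal_quantities(np.array([x_above]), tail, frechet_rate)
        return float(np.exp(_log_partial_z(logz[0], logzu, a) + logj[0]))
    return float(math.exp(censored_both_below_logmass(tail, a)))
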