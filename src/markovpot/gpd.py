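"""Generalized Pareto exceedance model on the negated scale.

For a threshold ``u`` (negated scale), exceedances ``y > u`` follow

    H(y) = 1 - [1 + xi (y - u) / sigma]^(-1/xi),      sigma > 0,

with the exponential limit ``H(y) = 1 - exp(-(y - u)/sigma)`` at xi = 0.
For xi < 0 the support is bounded above by ``u - sigma/xi``.  The
exceedance rate ``lambda_u`` (the marginal probability of exceeding u,
estimated by the sample fraction) completes the marginal model

    F(x) = 1 - lambda_u [1 + xi (x - u)/sigma]^(-1/xi),   x >= u,

needed by the Frechet transform and return levels.

Public cdf/pdf/quantile go through :class:`scipy.stats.genpareto`; the
private ``_log_tail_terms`` helper computes log-survival and log-density
with plain numpy for the likelihood hot path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._numdiff import central_hessian
from .errors import ConvergenceError

XI_MIN, XI_MAX = -0.99, 5.0
SIGMA_MIN = 1e-8


@dataclass(frozen=True)
class GPDTail:
    """Marginal tail model (u, sigma, xi, lambda_u) on the negated scale."""

    u: float
    sigma: float
    xi: float
    lambda_u: float = 1.0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 < self.lambda_u <= 1.0:
            raise ValueError(f"lambda_u must be in (0, 1], got {self.lambda_u}")

    @property
    def upper(self) -> float:
        """Upper support endpoint (finite iff xi < 0)."""
        if self.xi < 0:
            return self.u - self.sigma / self.xi
        return math.inf

    def distribution(self):
        """The scipy frozen distribution of exceedances."""
        return stats.genpareto(self.xi, loc=self.u, scale=self.sigma)


def gpd_cdf(y, tail: GPDTail):
    """H(y) for y >= u; values beyond the upper endpoint clamp to 1."""
    y = np.asarray(y, dtype=float)
    if np.any(y < tail.u):
        raise ValueError(f"y below threshold u={tail.u}")
    out = tail.distribution().cdf(y)
    return float(out) if out.ndim == 0 else out


def gpd_pdf(y, tail: GPDTail):
    """h(y) for y >= u; 0 beyond the upper endpoint."""
    y = np.asarray(y, dtype=float)
    if np.any(y < tail.u):
        raise ValueError(f"y below threshold u={tail.u}")
    out = tail.distribution().pdf(y)
    return float(out) if out.ndim == 0 else out


def gpd_quantile(p, tail: GPDTail):
    """Inverse of :func:`gpd_cdf`: the q with H(q) = p, 0 < p < 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly in (0, 1)")
    out = tail.distribution().ppf(p)
    return float(out) if out.ndim == 0 else out


def _log_tail_terms(x, u, sigma, xi):
    """(log survival, log density) of the GPD at exceedances ``x``.

    Returns None when the parameters are outside the optimizer box or any
    point falls outside the support (the likelihood maps that to -inf).
    """
    if not (sigma > SIGMA_MIN and XI_MIN < xi < XI_MAX):
        return None
    e = (np.asarray(x, dtype=float) - u) / sigma
    if np.any(e < 0):
        return None
    if xi == 0.0:
        return -e, -math.log(sigma) - e
    xe = xi * e
    if np.any(xe <= -1.0):
        return None
    logt = np.log1p(xe)  # log1p keeps the xi -> 0 limit smooth
    logsf = -logt / xi
    logh = -math.log(sigma) - (1.0 + 1.0 / xi) * logt
    return logsf, logh


# ---------------------------------------------------------------------------
# mean residual life


def mean_residual_life(data, thresholds=None, n_grid: int = 30) -> pd.DataFrame:
    """Mean-excess table for threshold selection.

    e(u) = mean(y - u | y > u) with a normal-approximation 95% CI
    e(u) +/- 1.96 sd/sqrt(n_u).  Where the GPD holds, e(u) is linear in u
    (flat for xi = 0).  Grid points with fewer than 5 exceedances (in
    particular, points at or above the sample maximum) are excluded.

    ``data`` may be a Dataset (values pooled over sites) or an array on
    the negated scale.
    """
    values = data.all_values() if hasattr(data, "all_values") else np.asarray(data, float)
    if thresholds is None:
        thresholds = np.linspace(
            np.min(values), np.quantile(values, 0.98), n_grid
        )
    rows = []
    vmax = np.max(values)
    for u in np.atleast_1d(np.asarray(thresholds, dtype=float)):
        exc = values[values > u] - u
        if u >= vmax or len(exc) < 2:
            continue  # at/above the maximum: no mean excess
        m = float(np.mean(exc))
        # the normal-approximation CI needs a handful of exceedances
        se = (
            float(np.std(exc, ddof=1) / math.sqrt(len(exc)))
            if len(exc) >= 5
            else math.nan
        )
        rows.append(
            {
                "threshold": float(u),
                "n_exceed": len(exc),
                "mean_excess": m,
                "se": se,
                "ci_low": m - 1.96 * se,
                "ci_high": m + 1.96 * se,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# independent POT baseline


@dataclass
class POTResults:
    """MLE of the independent-exceedance GPD (the POT baseline).

    ``params`` is (sigma, xi); standard errors come from the inverse
    observed information at the optimum.
    """

    tail: GPDTail
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    llf: float
    n_exceed: int
    n_total: int
    converged: bool = True

    @property
    def sigma(self) -> float:
        return float(self.params[0])

    @property
    def xi(self) -> float:
        return float(self.params[1])

    def summary(self) -> str:
        lines = [
            "Independent POT (GPD) fit",
            f"  threshold u        {self.tail.u:.6g}",
            f"  exceedances        {self.n_exceed} of {self.n_total}"
            f"  (lambda_u = {self.tail.lambda_u:.4f})",
            f"  log-likelihood     {self.llf:.4f}",
            f"  sigma              {self.sigma:.4f} (se {self.bse[0]:.4f})",
            f"  xi                 {self.xi:.4f} (se {self.bse[1]:.4f})",
        ]
        return "\n".join(lines)


def _gpd_nll_exceedances(theta, exc, u):
    sigma = math.exp(theta[0])
    xi = theta[1]
    terms = _log_tail_terms(exc, u, sigma, xi)
    if terms is None:
        return 1e10
    return -float(np.sum(terms[1]))


def _moment_start(exc, u):
    y = exc - u
    m, v = float(np.mean(y)), float(np.var(y, ddof=1))
    if v <= 0:
        return np.array([math.log(max(m, 1e-6)), 0.1])
    xi0 = 0.5 * (1.0 - m * m / v)
    xi0 = min(max(xi0, -0.8), 0.8)
    sigma0 = max(0.5 * m * (m * m / v + 1.0), 1e-6)
    if xi0 < 0:
        # keep the start inside the support: upper endpoint must clear
        # the largest excess
        sigma0 = max(sigma0, 1.1 * -xi0 * float(np.max(y)))
    return np.array([math.log(sigma0), xi0])


def fit_pot_independent(data, u: float) -> POTResults:
    """Fit the GPD to pooled exceedances over ``u`` by maximum likelihood.

    ``data`` may be a Dataset (negated scale) or a plain array.  Requires
    at least 2 non-degenerate exceedances.
    """
    values = data.all_values() if hasattr(data, "all_values") else np.asarray(data, float)
    exc = values[values > u]
    if len(exc) < 2:
        raise ValueError(f"need >= 2 exceedances above u={u}, got {len(exc)}")
    if np.ptp(exc) == 0:
        raise ValueError("exceedances are all equal; GPD fit is degenerate")

    theta0 = _moment_start(exc, u)
    nm = optimize.minimize(
        _gpd_nll_exceedances,
        theta0,
        args=(exc, u),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    polish = optimize.minimize(
        _gpd_nll_exceedances,
        nm.x,
        args=(exc, u),
        method="BFGS",
        options={"gtol": 1e-9, "maxiter": 500},
    )
    best = polish if polish.fun <= nm.fun else nm
    if not np.isfinite(best.fun) or best.fun >= 1e9:
        raise ConvergenceError("independent POT fit failed", trace=(nm, polish))

    sigma, xi = math.exp(best.x[0]), float(best.x[1])
    params = np.array([sigma, xi])

    def nll_nat(p):
        if p[0] <= 0:
            return 1e10
        return _gpd_nll_exceedances([math.log(p[0]), p[1]], exc, u)

    hess = central_hessian(nll_nat, params)
    try:
        cov = np.linalg.inv(hess)
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(bse)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
        bse = np.full(2, np.nan)

    lam = len(exc) / len(values)
    return POTResults(
        tail=GPDTail(u=u, sigma=sigma, xi=xi, lambda_u=lam),
        params=params,
        bse=bse,
        cov=cov,
        llf=-float(best.fun),
        n_exceed=len(exc),
        n_total=len(values),
        converged=bool(np.isfinite(best.fun)),
    )
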