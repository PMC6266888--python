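"""Autocorrelation and model-fit diagnostic arrays.

``acf`` is the sample autocorrelation function with the standard biased
denominator and +/-1.96/sqrt(n) white-noise bounds — the conventional
reading of "autoregressive coefficient" plots with dotted confidence
lines.  ``diagnostic_arrays`` produces the probability (PP), quantile
(QQ) and return-level arrays for the fitted exceedance model, with 95%
bands by the delta method from the parameter covariance (for the PP/QQ
point scatter the band additionally carries the order-statistic sampling
variance), or by a parametric bootstrap on request.

Conventions: Weibull plotting positions i/(n+1); return periods m are in
observations (months), pooled across sites, so the return level z_m
solves lambda_u (1 - H(z_m)) = 1/m, giving

    z_m = u + (sigma/xi) [(lambda_u m)^xi - 1],

with z_m = u at m = 1/lambda_u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf

from .gpd import gpd_cdf, gpd_quantile


@dataclass
class ACFResult:
    lags: np.ndarray
    coefficients: np.ndarray
    conf_bound: float

    def significant_lags(self) -> np.ndarray:
        """Lags >= 1 whose coefficient exceeds the white-noise bound."""
        mask = np.abs(self.coefficients[1:]) > self.conf_bound
        return self.lags[1:][mask]


def acf(series, max_lag: int = 24) -> ACFResult:
    """Sample autocorrelation of one series up to ``max_lag``."""
    values = np.asarray(getattr(series, "values", series), dtype=float)
    n = len(values)
    if n <= max_lag + 1:
        raise ValueError(f"series length {n} too short for max_lag={max_lag}")
    if np.ptp(values) == 0:
        raise ValueError("constant series: autocorrelation undefined")
    coeff = _sm_acf(values, nlags=max_lag, fft=n > 1000)
    return ACFResult(
        lags=np.arange(max_lag + 1),
        coefficients=np.asarray(coeff),
        conf_bound=1.96 / math.sqrt(n),
    )


@dataclass
class DiagnosticArrays:
    pp: pd.DataFrame
    qq: pd.DataFrame
    return_levels: pd.DataFrame
    bands: bool = True


def _quantile_gradient(pos, tail):
    """d q(p)/d(sigma, xi) for q(p) = u + (sigma/xi)((1-p)^(-xi) - 1)."""
    sigma, xi = tail.sigma, tail.xi
    t = (1.0 - pos) ** -xi
    if xi == 0.0:
        dq_dsigma = -np.log1p(-pos)
        dq_dxi = 0.5 * sigma * np.log1p(-pos) ** 2
    else:
        dq_dsigma = (t - 1.0) / xi
        dq_dxi = sigma * (-xi * t * np.log1p(-pos) - (t - 1.0)) / xi**2
    return np.column_stack([dq_dsigma, dq_dxi])


def _return_level_gradient(m, tail):
    sigma, xi, lam = tail.sigma, tail.xi, tail.lambda_u
    lm = lam * m
    if xi == 0.0:
        dz_dsigma = np.log(lm)
        dz_dxi = 0.5 * sigma * np.log(lm) ** 2
    else:
        t = lm**xi
        dz_dsigma = (t - 1.0) / xi
        dz_dxi = sigma * (xi * t * np.log(lm) - (t - 1.0)) / xi**2
    return np.column_stack([dz_dsigma, dz_dxi])


def _cdf_gradient(y, tail):
    """d H(y)/d(sigma, xi) at exceedances y."""
    sigma, xi, u = tail.sigma, tail.xi, tail.u
    e = (np.asarray(y) - u) / sigma
    if xi == 0.0:
        sf = np.exp(-e)
        dH_dsigma = -sf * e / sigma
        dH_dxi = -sf * e**2 / 2.0
    else:
        t = 1.0 + xi * e
        sf = t ** (-1.0 / xi)
        dH_dsigma = -sf * e / (sigma * t)
        dH_dxi = -sf * (np.log(t) / xi**2 - e / (xi * t))
    return np.column_stack([dH_dsigma, dH_dxi])


def _delta_se(grad, cov2):
    return np.sqrt(np.einsum("ij,jk,ik->i", grad, cov2, grad))


def return_level(m, tail):
    """Level exceeded once per m observations on average (negated scale)."""
    m = np.asarray(m, dtype=float)
    lm = tail.lambda_u * m
    if np.any(lm < 1.0):
        raise ValueError("return period below 1/lambda_u has no exceedance level")
    if tail.xi == 0.0:
        out = tail.u + tail.sigma * np.log(lm)
    else:
        out = tail.u + tail.sigma / tail.xi * (lm**tail.xi - 1.0)
    return float(out) if out.ndim == 0 else out


def diagnostic_arrays(
    fit,
    m_grid=None,
    method: str = "delta",
    n_boot: int = 500,
    seed: int = 0,
) -> DiagnosticArrays:
    """PP/QQ/return-level arrays with 95% bands for a fitted model.

    ``fit`` is a MarkovPOTResults (POTResults also works for the delta
    method if it carries ``cov``).  If the parameter covariance is
    flagged unreliable the bands are suppressed.
    """
    tail = fit.tail
    model = getattr(fit, "model", None)
    struct = model._structure if model is not None else None
    exc = np.sort(struct.x_exc if struct is not None else fit.exceedances)
    n = len(exc)
    if n < 5:
        raise ValueError("need >= 5 exceedances for diagnostics")
    pos = np.arange(1, n + 1) / (n + 1.0)

    model_prob = gpd_cdf(exc, tail)
    model_q = gpd_quantile(pos, tail)

    if m_grid is None:
        m_lo = 1.0 / tail.lambda_u
        m_grid = np.geomspace(m_lo * 1.0001, 10.0 * (struct.n_total if struct else n), 50)
    m_grid = np.asarray(m_grid, dtype=float)
    levels = return_level(m_grid, tail)

    bands = True
    cov_ok = getattr(fit, "cov_reliable", True)
    cov = None
    if cov_ok:
        try:
            full = fit.cov_params() if callable(getattr(fit, "cov_params", None)) else fit.cov
            cov = np.asarray(full)[:2, :2]
            if not np.all(np.isfinite(cov)):
                cov = None
        except Exception:
            cov = None
    if cov is None:
        bands = False

    if bands and method == "delta":
        # PP/QQ bands are for the plotted points, so they combine the
        # delta-method parameter variance with the (iid-approximation)
        # order-statistic sampling variance; the return-level band is a
        # confidence band for the fitted curve itself.
        from .gpd import gpd_pdf

        h_q = gpd_pdf(model_q, tail)
        var_os_q = pos * (1.0 - pos) / ((n + 2.0) * h_q**2)
        var_os_p = pos * (1.0 - pos) / (n + 2.0)
        se_q = np.sqrt(
            _delta_se(_quantile_gradient(pos, tail), cov) ** 2 + var_os_q
        )
        se_p = np.sqrt(_delta_se(_cdf_gradient(exc, tail), cov) ** 2 + var_os_p)
        se_rl = _delta_se(_return_level_gradient(m_grid, tail), cov)
        qq_lo, qq_hi = model_q - 1.96 * se_q, model_q + 1.96 * se_q
        pp_lo = np.clip(model_prob - 1.96 * se_p, 0.0, 1.0)
        pp_hi = np.clip(model_prob + 1.96 * se_p, 0.0, 1.0)
        rl_lo, rl_hi = levels - 1.96 * se_rl, levels + 1.96 * se_rl
    elif bands and method == "bootstrap":
        # parametric bootstrap of the fitted tail
        qs, ps, rls = [], [], []
        from ._likelihood import ChainStructure, fit_structure
        from .simulate import simulate_uniform_chains, uniforms_to_negated

        seg_lengths = model.segment_lengths
        n_seg = len(seg_lengths)
        max_len = max(seg_lengths)
        V = simulate_uniform_chains(n_boot * n_seg, max_len, fit.alpha, seed)
        X = uniforms_to_negated(V, tail)
        from .gpd import GPDTail as _Tail

        for b in range(n_boot):
            segs = [X[b * n_seg + j, :seg_lengths[j]] for j in range(n_seg)]
            st = ChainStructure.from_segments(segs, tail.u)
            if st.n_exc < 3:
                continue
            try:
                prm, _, _, _ = fit_structure(
                    st, start=(fit.sigma, fit.xi, min(fit.alpha, 1 - 1e-6)),
                    tight=False,
                )
            except Exception:
                continue
            bt = _Tail(tail.u, prm[0], prm[1], lambda_u=tail.lambda_u)
            qs.append(gpd_quantile(pos, bt))
            ps.append(gpd_cdf(exc, bt))
            rls.append(return_level(m_grid, bt))
        qq_lo, qq_hi = np.percentile(qs, [2.5, 97.5], axis=0)
        pp_lo, pp_hi = np.percentile(ps, [2.5, 97.5], axis=0)
        rl_lo, rl_hi = np.percentile(rls, [2.5, 97.5], axis=0)
    elif bands:
        raise ValueError(f"unknown band method {method!r}")

    if not bands:
        import warnings

        warnings.warn("parameter covariance unreliable; bands suppressed")
        nan = np.nan
        qq_lo = qq_hi = np.full(n, nan)
        pp_lo = pp_hi = np.full(n, nan)
        rl_lo = rl_hi = np.full(len(m_grid), nan)

    pp = pd.DataFrame(
        {"empirical": pos, "model": model_prob, "ci_low": pp_lo, "ci_high": pp_hi}
    )
    qq = pd.DataFrame(
        {"model": model_q, "empirical": exc, "ci_low": qq_lo, "ci_high": qq_hi}
    )
    rl = pd.DataFrame(
        {"return_period": m_grid, "level": levels, "ci_low": rl_lo, "ci_high": rl_hi}
    )
    return DiagnosticArrays(pp=pp, qq=qq, return_levels=rl, bands=bands)


def plot_diagnostics(arrays: DiagnosticArrays, path=None):
    """Render the three panels; returns the matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    pp, qq, rl = arrays.pp, arrays.qq, arrays.return_levels

    axes[0].plot([0, 1], [0, 1], "k-", lw=0.8)
    axes[0].plot(pp["empirical"], pp["model"], "o", ms=3)
    if arrays.bands:
        axes[0].plot(pp["empirical"], pp["ci_low"], "k:", lw=0.8)
        axes[0].plot(pp["empirical"], pp["ci_high"], "k:", lw=0.8)
    axes[0].set(title="Probability plot", xlabel="empirical", ylabel="model")

    axes[1].plot(qq["model"], qq["empirical"], "o", ms=3)
    lim = [qq["model"].min(), qq["model"].max()]
    axes[1].plot(lim, lim, "k-", lw=0.8)
    if arrays.bands:
        axes[1].plot(qq["ci_low"], qq["empirical"], "k:", lw=0.8)
        axes[1].plot(qq["ci_high"], qq["empirical"], "k:", lw=0.8)
    axes[1].set(title="QQ plot", xlabel="model", ylabel="empirical")

    axes[2].semilogx(rl["return_period"], rl["level"], "-")
    if arrays.bands:
        axes[2].semilogx(rl["return_period"], rl["ci_low"], "k:", lw=0.8)
        axes[2].semilogx(rl["return_period"], rl["ci_high"], "k:", lw=0.8)
    axes[2].set(
        title="Return level", xlabel="return period (months)", ylabel="level"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
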