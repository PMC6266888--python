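"""The Markov peaks-over-threshold model and its results object.

``MarkovPOT`` couples a GPD exceedance margin with logistic lag-1
extremal dependence under a first-order Markov assumption, fitted by
censored maximum likelihood on the negated (minima -> maxima) scale.
Usage follows the statsmodels pattern::

    model = MarkovPOT.from_concentrations(dataset, threshold=-1.0)
    res = model.fit()
    print(res.summary())
    res.reference_condition(0.25)
    res.bootstrap_ci(p=0.25, n_boot=1000, seed=1)

Free parameters are (sigma, xi, alpha); the exceedance rate lambda_u is
fixed at its sample estimate.  Standard errors come from the inverse of
a central-difference Hessian of the negative log-likelihood at the
optimum.
"""

from __future__ import annotations

import numpy as np

from . import inference as _inference
from ._likelihood import ChainStructure, fit_structure, negative_log_likelihood
from ._numdiff import central_hessian
from .data import NEGATED, Dataset
from .gpd import GPDTail

PARAM_NAMES = ("sigma", "xi", "alpha")


class MarkovPOT:
    """Censored Markov POT model for one variable across sites.

    Parameters
    ----------
    dataset : Dataset
        Must be on the negated scale (use :meth:`from_concentrations` to
        negate raw concentrations).  Each site series — and each
        contiguous run within a gapped series — is an independent chain.
    threshold : float
        Threshold u on the negated scale (e.g. -1.0 for TN in mg/L).
    frechet_rate : {"empirical", "unit"}
        Marginal transform convention; see :mod:`markovpot.dependence`.
    """

    def __init__(self, dataset: Dataset, threshold: float, frechet_rate="empirical"):
        if dataset.scale != NEGATED:
            raise ValueError(
                "MarkovPOT expects the negated scale; use "
                "MarkovPOT.from_concentrations for raw concentrations"
            )
        self.dataset = dataset
        self.threshold = float(threshold)
        self.frechet_rate = frechet_rate
        self._segments = dataset.all_segments()
        self._structure = ChainStructure.from_segments(self._segments, self.threshold)
        if self._structure.n_exc < 2:
            raise ValueError(
                f"only {self._structure.n_exc} exceedances above "
                f"u={threshold}; need >= 2"
            )

    @classmethod
    def from_concentrations(cls, dataset: Dataset, threshold: float, **kw):
        """Build the model from original-scale concentrations (negates)."""
        return cls(dataset.negate(), threshold, **kw)

    @property
    def lambda_u(self) -> float:
        return self._structure.lambda_u

    @property
    def n_exceed(self) -> int:
        return self._structure.n_exc

    @property
    def n_obs(self) -> int:
        return self._structure.n_total

    @property
    def segment_lengths(self) -> list[int]:
        return [len(s) for s in self._segments]

    def nloglik(self, params) -> float:
        """Negative log-likelihood at (sigma, xi, alpha); +inf off-support."""
        return negative_log_likelihood(params, self._structure, self.frechet_rate)

    def loglike(self, params) -> float:
        return -self.nloglik(params)

    def fit(
        self,
        start=None,
        fix_alpha=None,
        alpha_grid=(0.2, 0.5, 0.8, 0.95),
        compute_cov: bool = True,
    ) -> "MarkovPOTResults":
        """Maximize the censored Markov likelihood.

        ``start`` is an optional (sigma, xi, alpha) start; the default
        start takes sigma/xi from the independent POT fit with alpha=0.8
        and falls back on a small alpha multi-start grid.  ``fix_alpha``
        freezes the dependence parameter (fix_alpha=1.0 is the
        independent censored model).
        """
        params, llf, converged, info = fit_structure(
            self._structure,
            start=start,
            fix_alpha=fix_alpha,
            frechet_rate=self.frechet_rate,
            alpha_grid=alpha_grid,
            tight=True,
        )
        cov, cov_reliable = None, False
        if compute_cov:
            cov, cov_reliable = self._covariance(params, fix_alpha)
        return MarkovPOTResults(
            model=self,
            params=params,
            llf=llf,
            converged=converged,
            cov=cov,
            cov_reliable=cov_reliable,
            fixed_alpha=fix_alpha,
            settings=info,
        )

    def _covariance(self, params, fix_alpha):
        """Inverse observed information in (sigma, xi, alpha) space.

        When alpha is fixed (or pinned at the boundary) only the
        (sigma, xi) block is differentiated and the alpha row/column is
        set to NaN.
        """
        sigma, xi, alpha = params
        free_alpha = fix_alpha is None and alpha < 1.0 - 1e-4
        if free_alpha:
            x0 = np.array([sigma, xi, alpha])
            steps = np.array(
                [
                    max(1e-5, 1e-4 * sigma),
                    max(1e-5, 1e-4 * abs(xi)),
                    min(max(1e-5, 1e-4 * alpha), 0.49 * (1.0 - alpha)),
                ]
            )
            f = lambda p: self.nloglik(p)
        else:
            x0 = np.array([sigma, xi])
            steps = np.array(
                [max(1e-5, 1e-4 * sigma), max(1e-5, 1e-4 * abs(xi))]
            )
            f = lambda p: self.nloglik([p[0], p[1], alpha])
        H = central_hessian(f, x0, steps)
        cov = np.full((3, 3), np.nan)
        reliable = False
        try:
            np.linalg.cholesky(H)
            block = np.linalg.inv(H)
            reliable = bool(np.all(np.diag(block) > 0))
        except np.linalg.LinAlgError:
            block = np.linalg.pinv(H)
        k = block.shape[0]
        cov[:k, :k] = block
        return cov, reliable


class MarkovPOTResults:
    """Fitted-model container: estimates, uncertainty, derived quantities."""

    def __init__(
        self,
        model: MarkovPOT,
        params,
        llf,
        converged,
        cov=None,
        cov_reliable=False,
        fixed_alpha=None,
        settings=None,
    ):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self._cov = cov
        self.cov_reliable = bool(cov_reliable)
        self.fixed_alpha = fixed_alpha
        self.settings = dict(settings or {})
        self.n_effective = model.n_exceed

    # -- parameter access ---------------------------------------------------

    @property
    def sigma(self) -> float:
        return float(self.params[0])

    @property
    def xi(self) -> float:
        return float(self.params[1])

    @property
    def alpha(self) -> float:
        return float(self.params[2])

    @property
    def tail(self) -> GPDTail:
        return GPDTail(
            u=self.model.threshold,
            sigma=self.sigma,
            xi=self.xi,
            lambda_u=self.model.lambda_u,
        )

    def cov_params(self) -> np.ndarray:
        if self._cov is None:
            raise ValueError("covariance was not computed (compute_cov=False)")
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        cov = self.cov_params()
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(cov))

    # -- derived quantities -------------------------------------------------

    def reference_condition(self, p: float = 0.25) -> float:
        """The p-quantile of the minima model on the original scale."""
        return _inference.reference_condition(self, p)

    def bootstrap_ci(self, p=0.25, n_boot=1000, seed=0, kind="parametric", **kw):
        return _inference.bootstrap_ci(
            self, p=p, n_boot=n_boot, seed=seed, kind=kind, **kw
        )

    def diagnostics(self, **kw):
        from . import diagnostics as _diag

        return _diag.diagnostic_arrays(self, **kw)

    def simulate(self, n_sites=None, chain_length=None, seed=0, body_floor=None):
        """Simulate a dataset from the fitted model (negated scale)."""
        from .simulate import SimulationSpec, simulate_chain

        if n_sites is None:
            n_sites = len(self.model.dataset)
        if chain_length is None:
            chain_length = max(self.model.segment_lengths)
        spec = SimulationSpec(
            tail=self.tail,
            alpha=self.alpha,
            n_sites=n_sites,
            chain_length=chain_length,
            body_floor=body_floor,
            seed=seed,
            variable=self.model.dataset.variable,
        )
        return simulate_chain(spec)

    # -- reporting ----------------------------------------------------------

    def to_dict(self) -> dict:
        cov = self._cov
        se = self.bse if cov is not None else np.full(3, np.nan)

        def _clean(x):
            return None if x is None or (np.isscalar(x) and not np.isfinite(x)) else x

        return {
            "variable": self.model.dataset.variable,
            "threshold": self.model.threshold,
            "lambda_u": self.model.lambda_u,
            "frechet_rate": self.model.frechet_rate,
            "params": {k: float(v) for k, v in zip(PARAM_NAMES, self.params)},
            "se": {k: _clean(float(v)) for k, v in zip(PARAM_NAMES, se)},
            "cov": None if cov is None else np.where(np.isfinite(cov), cov, None).tolist(),
            "cov_reliable": self.cov_reliable,
            "loglik": self.llf,
            "n_effective": self.n_effective,
            "n_total": self.model.n_obs,
            "converged": self.converged,
            "fixed_alpha": self.fixed_alpha,
            "settings": self.settings,
        }

    def summary(self) -> str:
        se = (
            self.bse
            if self._cov is not None
            else np.full(3, np.nan)
        )
        lines = [
            "Markov POT (censored logistic) fit",
            "=" * 46,
            f"variable: {self.model.dataset.variable}"
            f"    chains: {len(self.model.segment_lengths)}",
            f"threshold u (negated): {self.model.threshold:.6g}",
            f"observations: {self.model.n_obs}"
            f"    effective (exceedances): {self.n_effective}",
            f"lambda_u: {self.model.lambda_u:.4f}"
            f"    log-likelihood: {self.llf:.4f}",
            f"converged: {self.converged}"
            f"    cov reliable: {self.cov_reliable}",
            "-" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name, val, s in zip(PARAM_NAMES, self.params, se):
            s_txt = f"{s:>12.4f}" if np.isfinite(s) else f"{'--':>12}"
            lines.append(f"{name:<8}{val:>12.4f}{s_txt}")
        if self.fixed_alpha is not None:
            lines.append(f"(alpha fixed at {self.fixed_alpha})")
        return "\n".join(lines)

    def __repr__(self):
        p = ", ".join(f"{k}={v:.4g}" for k, v in zip(PARAM_NAMES, self.params))
        return f"<MarkovPOTResults {p}, llf={self.llf:.4g}>"
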