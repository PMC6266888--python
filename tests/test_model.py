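import numpy as np
import pytest

import markovpot as mp
from markovpot._likelihood import ChainStructure, negative_log_likelihood
from markovpot._numdiff import central_gradient, central_hessian

from _oracles import slow_markov_nll


def _structure(segments, u=0.0):
    return ChainStructure.from_segments(
        [np.asarray(s, dtype=float) for s in segments], u
    )


class TestLikelihood:
    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        segments = [rng.normal(0.0, 1.0, size=n) for n in (12, 7, 2, 1, 30)]
        st = _structure(segments)
        for params in [(1.0, -0.2, 0.6), (0.7, 0.1, 1.0), (1.3, -0.4, 0.25)]:
            fast = negative_log_likelihood(params, st)
            slow = slow_markov_nll(params, segments, 0.0)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_two_point_chain_both_below(self):
        # a length-2 chain entirely below u contributes exactly
        # -log F(u, u): m(x1) * f(x1, x2)/m(x1) = F(u, u)
        segments = [[-1.0, -2.0], [0.5, 1.2, -1.0, 0.3]]
        st = _structure(segments)
        st_other = _structure([segments[1]])
        lam = st.lambda_u
        sigma, xi = 0.8, -0.2
        for a in (0.3, 0.7, 1.0):
            with_chain = negative_log_likelihood((sigma, xi, a), st)
            # hand computation of the rest of the likelihood at pooled lam
            tail = mp.GPDTail(0.0, sigma, xi, lam)
            ll = np.log(lam * mp.gpd_pdf(0.5, tail))
            for x_prev, x_t in [(0.5, 1.2), (1.2, -1.0), (-1.0, 0.3)]:
                m_prev = (
                    lam * mp.gpd_pdf(x_prev, tail) if x_prev > 0 else 1 - lam
                )
                ll += np.log(
                    mp.censored_pair_density(x_t, x_prev, tail, a) / m_prev
                )
            log_Fuu = (2.0**a) * np.log1p(-lam)
            assert with_chain == pytest.approx(-(ll + log_Fuu), rel=1e-12)

    def test_independence_case_equals_censored_gpd(self):
        rng = np.random.default_rng(1)
        segments = [rng.normal(0, 1, size=50) for _ in range(3)]
        st = _structure(segments)
        lam = st.lambda_u
        sigma, xi = 0.9, -0.15
        tail = mp.GPDTail(0.0, sigma, xi, lam)
        exc = st.x_exc
        indep = -(
            np.sum(np.log(lam * mp.gpd_pdf(exc, tail)))
            + (st.n_total - st.n_exc) * np.log1p(-lam)
        )
        assert negative_log_likelihood((sigma, xi, 1.0), st) == pytest.approx(
            indep, rel=1e-8
        )

    def test_support_violation_returns_inf(self):
        st = _structure([[0.5, 3.0, -1.0]])
        assert negative_log_likelihood((0.5, -0.5, 0.8), st) == np.inf  # 3.0 > u - s/x
        assert negative_log_likelihood((0.5, 0.2, 1.5), st) == np.inf  # bad alpha

    def test_likelihood_prefers_truth_direction_on_dependent_data(self):
        spec = mp.SimulationSpec(
            tail=mp.GPDTail(0.0, 1.0, -0.3, 0.3), alpha=0.5,
            n_sites=4, chain_length=144, seed=3,
        )
        ds = mp.simulate_chain(spec)
        st = ChainStructure.from_dataset(ds, 0.0)
        nll_at = lambda a: negative_log_likelihood((1.0, -0.3, a), st)
        assert nll_at(0.55) < nll_at(0.9) < nll_at(1.0)



class TestFit:
    def test_site_permutation_invariance(self, tn_dataset):
        perm = mp.Dataset(tn_dataset.variable, tn_dataset.series[::-1])
        m1 = mp.MarkovPOT(tn_dataset, -1.0)
        m2 = mp.MarkovPOT(perm, -1.0)
        p = (0.25, -0.3, 0.7)
        assert m1.nloglik(p) == pytest.approx(m2.nloglik(p), rel=1e-12)
        r1, r2 = m1.fit(compute_cov=False), m2.fit(compute_cov=False)
        np.testing.assert_allclose(r1.params, r2.params, rtol=1e-6)

    def test_stationary_gradient_at_optimum(self, tn_results):
        model = tn_results.model
        g = central_gradient(
            lambda p: model.nloglik(p), tn_results.params,
            steps=np.array([1e-6, 1e-6, 1e-6]),
        )
        # gradient per effective observation is flat at the optimum
        assert np.max(np.abs(g)) < 1e-3 * tn_results.n_effective

    def test_optimum_beats_truth(self, tn_dataset):
        model = mp.MarkovPOT(tn_dataset, -1.0)
        res = model.fit(compute_cov=False)
        assert res.llf >= model.loglike((0.23, -0.27, 0.78)) - 1e-8

    def test_frozen_alpha_matches_independent_pot(self, tn_dataset):
        res = mp.MarkovPOT(tn_dataset, -1.0).fit(fix_alpha=1.0, compute_cov=False)
        pot = mp.fit_pot_independent(tn_dataset, -1.0)
        assert res.sigma == pytest.approx(pot.sigma, abs=1e-4)
        assert res.xi == pytest.approx(pot.xi, abs=1e-4)

    def test_results_surface(self, tn_results):
        assert tn_results.converged
        assert tn_results.n_effective == tn_results.model.n_exceed
        cov = tn_results.cov_params()
        np.testing.assert_allclose(cov, cov.T)
        assert np.all(np.diag(cov)[:3] > 0)
        np.testing.assert_allclose(
            tn_results.bse, np.sqrt(np.diag(cov)), equal_nan=True
        )
        txt = tn_results.summary()
        assert "sigma" in txt and "alpha" in txt and "exceedances" in txt
        d = tn_results.to_dict()
        assert d["n_effective"] == tn_results.n_effective
        assert d["params"]["xi"] == pytest.approx(tn_results.xi)

    def test_recovers_generating_parameters(self, tn_dataset, tn_results):
        # single-replicate sanity: estimates near (0.23, -0.27, 0.78)
        truth = np.array([0.23, -0.27, 0.78])
        assert np.all(np.abs(tn_results.params - truth) < 4 * tn_results.bse)

    def test_independent_data_pushes_alpha_to_boundary(self):
        tail = mp.GPDTail(0.0, 1.0, -0.3, 0.3)
        lrs, ahats = [], []
        for s in range(6):
            ds = mp.simulate_chain(
                mp.SimulationSpec(tail=tail, alpha=1.0, n_sites=4,
                                  chain_length=144, seed=300 + s)
            )
            m = mp.MarkovPOT(ds, 0.0)
            rf = m.fit(compute_cov=False)
            ri = m.fit(fix_alpha=1.0, compute_cov=False)
            ahats.append(rf.alpha)
            lrs.append(2 * (rf.llf - ri.llf))
        assert np.median(ahats) > 0.95
        assert np.median(lrs) < 1.0

    def test_requires_negated_scale(self, tn_dataset):
        with pytest.raises(ValueError, match="negated"):
            mp.MarkovPOT(tn_dataset.negate(), -1.0)

    def test_hessian_helper_agrees_with_statsmodels(self):
        from statsmodels.tools.numdiff import approx_hess2

        f = lambda p: float((p[0] - 1) ** 2 + p[0] * p[1] ** 2 + np.exp(p[1]))
        x = np.array([0.7, 0.3])
        np.testing.assert_allclose(
            central_hessian(f, x), approx_hess2(x, f), atol=1e-3
        )
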