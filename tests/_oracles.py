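"""Independent slow-path oracles used only by the tests.

These deliberately re-derive quantities through a different route than
the vectorized implementation: explicit per-observation loops through the
public censored pair density, and numerical differentiation of the joint
cdf.
"""

import math

import numpy as np

import markovpot as mp


def slow_markov_nll(params, segments, u):
    """Loop-based censored Markov negative log-likelihood."""
    sigma, xi, alpha = params
    values = np.concatenate([np.atleast_1d(s) for s in segments])
    lam = float(np.mean(values > u))
    tail = mp.GPDTail(u=u, sigma=sigma, xi=xi, lambda_u=lam)

    def log_m(x):
        if x > u:
            return math.log(lam) + math.log(mp.gpd_pdf(x, tail))
        return math.log1p(-lam)

    ll = 0.0
    for seg in segments:
        seg = np.atleast_1d(seg)
        ll += log_m(seg[0])
        for t in range(1, len(seg)):
            ll += math.log(
                mp.censored_pair_density(seg[t], seg[t - 1], tail, alpha)
            ) - log_m(seg[t - 1])
    return -ll


def numeric_mixed_partial(z1, z2, alpha, h=1e-4):
    """Central-difference d2 G / dz1 dz2 of the logistic joint cdf."""
    f = mp.logistic_joint_cdf
    return (
        f(z1 + h, z2 + h, alpha)
        - f(z1 + h, z2 - h, alpha)
        - f(z1 - h, z2 + h, alpha)
        + f(z1 - h, z2 - h, alpha)
    ) / (4.0 * h * h)
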