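"""Small central-difference derivative helpers.

Step sizes are chosen per coordinate and can be capped (needed when a
parameter sits near a hard boundary such as alpha -> 1).
"""

from __future__ import annotations

import numpy as np


def central_gradient(f, x, steps=None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = len(x)
    if steps is None:
        steps = np.maximum(1e-6, 1e-5 * np.abs(x))
    g = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * steps[i])
    return g


def central_hessian(f, x, steps=None) -> np.ndarray:
    """Symmetric central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    if steps is None:
        steps = np.maximum(1e-5, 1e-4 * np.abs(x))
    steps = np.asarray(steps, dtype=float)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H
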