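"""Numerical cores for the latent recursion and the Bernoulli likelihood.

The trial recursion is inherently sequential, so the hot loops are compiled
with numba when it is available; a pure-Python fallback keeps the package
functional (just slower) without it.  Both paths are exercised by the tests
via the ``*_py`` aliases.
"""

from __future__ import annotations

import numpy as np

LIK_EPS = 1e-9


def _latents_py(alpha, omega, outcomes, v0, eta0):
    T = outcomes.shape[0]
    v = np.empty(T + 1)
    eta = np.empty(T + 1)
    pe = np.empty(T)
    v[0] = v0
    eta[0] = eta0
    for t in range(T):
        pe[t] = outcomes[t] - v[t]
        v[t + 1] = v[t] + alpha * eta[t] * pe[t]
        eta[t + 1] = omega * abs(pe[t]) + (1.0 - omega) * eta[t]
    return v, eta, pe


def _nll_py(alpha, omega, beta, outcomes, ratings, observed, v0, eta0):
    v = v0
    eta = eta0
    nll = 0.0
    for t in range(outcomes.shape[0]):
        if observed[t]:
            p = 1.0 / (1.0 + np.exp(-v / beta))
            if p < LIK_EPS:
                p = LIK_EPS
            elif p > 1.0 - LIK_EPS:
                p = 1.0 - LIK_EPS
            if ratings[t] >= 0.5:
                nll -= np.log(p)
            else:
                nll -= np.log(1.0 - p)
        pe = outcomes[t] - v
        v = v + alpha * eta * pe
        eta = omega * abs(pe) + (1.0 - omega) * eta
    return nll


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    latents_core = njit(cache=False)(_latents_py)
    nll_core = njit(cache=False)(_nll_py)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    latents_core = _latents_py
    nll_core = _nll_py
    HAVE_NUMBA = False
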