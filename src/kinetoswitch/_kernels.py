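"""Numba kernels for the hidden-state samplers.

The forward-filter/backward-sampling pass and the single-site Gibbs sweep
are the only per-iteration loops that cannot be vectorised; everything else
in the sampler runs through numpy/scipy.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ffbs_draw(logL: np.ndarray, T4: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Exact draw of the hidden pair-state path by forward filtering and
    backward sampling.

    Parameters
    ----------
    logL : (n, 4) per-frame observation log-likelihood of each pair state.
    T4 : (4, 4) state transition matrix.
    u : (n,) uniform(0,1) variates, one per frame.
    """
    n = logL.shape[0]
    alpha = np.empty((n, 4))
    # uniform prior over the initial state
    m = logL[0].max()
    tot = 0.0
    for j in range(4):
        alpha[0, j] = 0.25 * np.exp(logL[0, j] - m)
        tot += alpha[0, j]
    for j in range(4):
        alpha[0, j] /= tot
    for t in range(1, n):
        m = logL[t].max()
        tot = 0.0
        for j in range(4):
            s = 0.0
            for i in range(4):
                s += alpha[t - 1, i] * T4[i, j]
            alpha[t, j] = s * np.exp(logL[t, j] - m)
            tot += alpha[t, j]
        for j in range(4):
            alpha[t, j] /= tot

    path = np.empty(n, dtype=np.int8)
    # sample final state
    c = 0.0
    path[n - 1] = 3
    for j in range(4):
        c += alpha[n - 1, j]
        if u[n - 1] < c:
            path[n - 1] = j
            break
    for t in range(n - 2, -1, -1):
        tot = 0.0
        w = np.empty(4)
        nxt = path[t + 1]
        for j in range(4):
            w[j] = alpha[t, j] * T4[j, nxt]
            tot += w[j]
        c = 0.0
        path[t] = 3
        for j in range(4):
            c += w[j] / tot
            if u[t] < c:
                path[t] = j
                break
    return path


@njit(cache=True)
def single_site_sweep(path: np.ndarray, logL: np.ndarray, T4: np.ndarray,
                      u: np.ndarray) -> None:
    """One in-place single-site Gibbs sweep over the hidden states.

    Each frame's state is redrawn from its full conditional given the
    neighbouring states and that frame's observation likelihood.
    """
    n = logL.shape[0]
    w = np.empty(4)
    for t in range(n):
        m = logL[t].max()
        tot = 0.0
        for j in range(4):
            p = np.exp(logL[t, j] - m)
            if t > 0:
                p *= T4[path[t - 1], j]
            if t < n - 1:
                p *= T4[j, path[t + 1]]
            w[j] = p
            tot += p
        if tot <= 0.0:
            continue  # current state retained (isolated zero-probability corner)
        c = 0.0
        new = path[t]
        for j in range(4):
            c += w[j] / tot
            if u[t] < c:
                new = j
                break
        path[t] = new
    return
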