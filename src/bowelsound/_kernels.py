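"""Compiled inner loops (NLMS weight updates, template-match counting).

Both algorithms are inherently sequential or O(N^2); numba keeps them fast
enough for whole-night recordings without changing their arithmetic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["nlms_kernel", "template_match_counts"]


@njit(cache=False)
def nlms_kernel(primary, reference, order, step, eps):
    """Normalized LMS adaptive filter.

    Weights start at zero; at each sample the FIR output over the most
    recent ``order`` reference samples is the interference estimate, the
    error (primary minus estimate) drives the normalized weight update.
    Returns (error, estimate).
    """
    n = primary.shape[0]
    w = np.zeros(order)
    buf = np.zeros(order)  # buf[0] = newest reference sample
    y = np.zeros(n)
    e = np.zeros(n)
    power = 0.0
    for i in range(n):
        # shift reference history
        for k in range(order - 1, 0, -1):
            buf[k] = buf[k - 1]
        buf[0] = reference[i]
        acc = 0.0
        power = 0.0
        for k in range(order):
            acc += w[k] * buf[k]
            power += buf[k] * buf[k]
        y[i] = acc
        e[i] = primary[i] - acc
        g = step * e[i] / (eps + power)
        for k in range(order):
            w[k] += g * buf[k]
    return e, y


@njit(cache=False)
def template_match_counts(x, m, tau, r, n_templates):
    """Total count of ordered template pairs (i != j) within tolerance.

    Templates are x[i], x[i+tau], ..., x[i+(m-1)tau] for i in
    [0, n_templates); the distance is the Chebyshev (max-abs) norm.
    """
    total = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            dmax = 0.0
            for k in range(m):
                d = abs(x[i + k * tau] - x[j + k * tau])
                if d > dmax:
                    dmax = d
            if dmax <= r:
                total += 2  # ordered pairs: (i, j) and (j, i)
    return total
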