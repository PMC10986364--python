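"""Numba kernels for the O(N^2) template-matching entropies.

One fused pass over template pairs serves both embedding dimensions m and
m+1 and both threshold conventions (<= with self-match for ApEn, strict <
without self-match for SampEn). Fuzzy similarity needs its own pass per
dimension because the mean-removed templates change with m.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def cheb_pair_counts(x, m, r):
    """Counts of Chebyshev template matches at dimensions m and m+1.

    Returns (le_m, le_m1, lt_m, lt_m1): per-template match counts over
    j != i, under d <= r and d < r respectively. Templates at dimension m
    number N-m+1; at m+1, N-m.
    """
    n = x.shape[0]
    tm = n - m + 1
    tm1 = n - m
    le_m = np.zeros(tm)
    le_m1 = np.zeros(tm1)
    lt_m = np.zeros(tm)
    lt_m1 = np.zeros(tm1)
    for i in range(tm):
        for j in range(i + 1, tm):
            d = 0.0
            for k in range(m):
                a = abs(x[i + k] - x[j + k])
                if a > d:
                    d = a
            if d <= r:
                le_m[i] += 1.0
                le_m[j] += 1.0
            if d < r:
                lt_m[i] += 1.0
                lt_m[j] += 1.0
            if i < tm1 and j < tm1:
                a = abs(x[i + m] - x[j + m])
                d1 = a if a > d else d
                if d1 <= r:
                    le_m1[i] += 1.0
                    le_m1[j] += 1.0
                if d1 < r:
                    lt_m1[i] += 1.0
                    lt_m1[j] += 1.0
    return le_m, le_m1, lt_m, lt_m1


@njit(cache=True)
def fuzzy_phi(x, m, r, n_exp):
    """Mean Gaussian similarity Phi^m over mean-removed template pairs."""
    n = x.shape[0]
    t = n - m + 1
    means = np.empty(t)
    for i in range(t):
        s = 0.0
        for k in range(m):
            s += x[i + k]
        means[i] = s / m
    total = 0.0
    for i in range(t):
        for j in range(i + 1, t):
            d = 0.0
            for k in range(m):
                a = abs((x[i + k] - means[i]) - (x[j + k] - means[j]))
                if a > d:
                    d = a
            if n_exp == 2.0:
                dn = d * d
            else:
                dn = d ** n_exp
            total += 2.0 * np.exp(-dn / r)
    return total / (t * (t - 1))
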