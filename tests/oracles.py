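"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the defining formulas with plain
Python loops and stdlib math — deliberately sharing no code or vectorization
strategy with the package implementations they check.
"""

import math


def apen_bruteforce(x, m, r_frac):
    """Approximate entropy by direct template matching (self-match included,
    d <= r)."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = r_frac * sd

    def phi(dim):
        t = n - dim + 1
        logs = []
        for i in range(t):
            count = 0
            for j in range(t):
                d = max(abs(x[i + k] - x[j + k]) for k in range(dim))
                if d <= r:
                    count += 1
            logs.append(math.log(count / t))
        return sum(logs) / t

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r_frac):
    """Sample entropy by direct template matching (no self-match, d < r)."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = r_frac * sd

    def b(dim):
        t = n - dim + 1
        fracs = []
        for i in range(t):
            count = 0
            for j in range(t):
                if j == i:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(dim))
                if d < r:
                    count += 1
            fracs.append(count / (t - 1))
        return sum(fracs) / t

    bm, bm1 = b(m), b(m + 1)
    return -math.log(bm1 / bm)


def fuzzyen_bruteforce(x, m, r_frac, n_exp):
    """Fuzzy entropy with mean-removed templates and exp(-d^n / r) similarity."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = r_frac * sd

    def phi(dim):
        t = n - dim + 1
        tmpl = []
        for i in range(t):
            mu = sum(x[i + k] for k in range(dim)) / dim
            tmpl.append([x[i + k] - mu for k in range(dim)])
        total = 0.0
        for i in range(t):
            inner = 0.0
            for j in range(t):
                if j == i:
                    continue
                d = max(abs(a - b) for a, b in zip(tmpl[i], tmpl[j]))
                inner += math.exp(-(d ** n_exp) / r)
            total += inner / (t - 1)
        return total / t

    return math.log(phi(m)) - math.log(phi(m + 1))


def hfd_bruteforce(x, kmax):
    """Higuchi fractal dimension via explicit subseries curve lengths and a
    hand-rolled least-squares slope of ln L(k) on ln(1/k)."""
    x = list(map(float, x))
    n = len(x)
    ln_inv_k, ln_l = [], []
    for k in range(1, kmax + 1):
        total = 0.0
        for m in range(1, k + 1):
            # subseries x[m-1], x[m-1+k], ... (1-based m)
            idx = list(range(m - 1, n, k))
            length = 0.0
            for a, b in zip(idx[1:], idx[:-1]):
                length += abs(x[a] - x[b])
            norm = (n - 1) / ((len(idx) - 1) * k)
            total += length * norm / k
        ln_inv_k.append(math.log(1.0 / k))
        ln_l.append(math.log(total / k))
    # least squares slope
    kk = len(ln_inv_k)
    sx = sum(ln_inv_k)
    sy = sum(ln_l)
    sxx = sum(v * v for v in ln_inv_k)
    sxy = sum(u * v for u, v in zip(ln_inv_k, ln_l))
    return (kk * sxy - sx * sy) / (kk * sxx - sx * sx)


def scalar_lstm_step(x, h, c, w):
    """Plain scalar LSTM step. ``w`` maps 'wx_i', 'wh_i', 'b_i', ... for gates
    i, f, g, o."""

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    i = sig(w["wx_i"] * x + w["wh_i"] * h + w["b_i"])
    f = sig(w["wx_f"] * x + w["wh_f"] * h + w["b_f"])
    g = math.tanh(w["wx_g"] * x + w["wh_g"] * h + w["b_g"])
    o = sig(w["wx_o"] * x + w["wh_o"] * h + w["b_o"])
    c_new = f * c + i * g
    h_new = o * math.tanh(c_new)
    return h_new, c_new


def mrmr_exhaustive(columns, y, mi_fn):
    """Exhaustive incremental mRMR: at every step recompute the criterion
    for every remaining candidate from scratch; ties broken by name order.

    ``columns`` is a dict name -> 1-D data; returns (ordering, scores).
    """
    relevance = {n: mi_fn(col, y) for n, col in columns.items()}
    selected, scores = [], []
    remaining = sorted(columns)
    while remaining:
        best_name, best_score = None, None
        for name in remaining:
            if selected:
                red = sum(mi_fn(columns[name], columns[s]) for s in selected)
                score = relevance[name] - red / len(selected)
            else:
                score = relevance[name]
            if best_score is None or score > best_score:
                best_name, best_score = name, score
        selected.append(best_name)
        scores.append(best_score)
        remaining.remove(best_name)
    return selected, scores
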