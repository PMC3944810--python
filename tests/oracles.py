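"""Independent reference implementations used only to check the package.

Everything here is coded from first principles with plain Python loops and
exact arithmetic where possible, deliberately avoiding the vectorized code
paths of the package itself.
"""
from __future__ import annotations

import math
from fractions import Fraction


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up by explicit sort and suffix minimum."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        q_sorted[rank_from_top - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = min(q_sorted[rank], 1.0)
    return q


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive enumeration with exact integers.

    Table [[a, b], [c, d]]; all tables with the same margins are weighted by
    C(a+b, k) * C(c+d, r-k) and those no more probable than the observed one
    are summed.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = math.comb(r1 + r2, c1)
    acc = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= obs:
            acc += w
    return float(Fraction(acc, total))


def chi2_stat_oracle(k1, n1, k2, n2):
    """Pearson chi-square on [[k1, n1-k1], [k2, n2-k2]] via the closed form
    (ad - bc)^2 * N / (row and column products)."""
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return (a * d - b * c) ** 2 * n / denom


def _quantile75(values):
    """R type-7 (linear interpolation) 75th percentile."""
    s = sorted(values)
    h = (len(s) - 1) * 0.75
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _tmm_pair_oracle(obs, ref, n_obs, n_ref, logratio_trim, sum_trim):
    log_r, abs_e, weights = [], [], []
    for o, r in zip(obs, ref):
        if o <= 0 or r <= 0:
            continue
        m = math.log2((o / n_obs) / (r / n_ref))
        a = (math.log2(o / n_obs) + math.log2(r / n_ref)) / 2.0
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        log_r.append(m)
        abs_e.append(a)
        weights.append(v)
    if not log_r or max(abs(x) for x in log_r) < 1e-6:
        return 1.0
    n = len(log_r)
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = _average_ranks(log_r)
    rank_a = _average_ranks(abs_e)
    num = den = 0.0
    kept = 0
    for i in range(n):
        if lo_l <= rank_m[i] <= hi_l and lo_s <= rank_a[i] <= hi_s:
            num += log_r[i] / weights[i]
            den += 1.0 / weights[i]
            kept += 1
    if kept == 0 or den == 0:
        return 1.0
    return 2.0 ** (num / den)


def tmm_oracle(columns, logratio_trim=0.3, sum_trim=0.05):
    """TMM factors for ``columns`` (dict name -> list of counts), geometric
    mean 1, reference chosen by upper-quartile fraction closest to the mean."""
    names = list(columns)
    libs = {c: float(sum(columns[c])) for c in names}
    f75 = {c: _quantile75(columns[c]) / libs[c] for c in names}
    mean_q = sum(f75.values()) / len(names)
    ref = min(names, key=lambda c: (abs(f75[c] - mean_q), names.index(c)))
    factors = {
        c: _tmm_pair_oracle(
            columns[c], columns[ref], libs[c], libs[ref], logratio_trim, sum_trim
        )
        for c in names
    }
    log_mean = sum(math.log(f) for f in factors.values()) / len(names)
    return {c: f / math.exp(log_mean) for c, f in factors.items()}
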