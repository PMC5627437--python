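"""Independent brute-force oracles used by the test suite.

Everything here is a deliberately naive, straight-line reimplementation of
a statistic from its definition — loops, no vectorization, no reuse of the
package's code paths — so that agreement with the package is an actual
cross-check.
"""

import itertools
import math

import numpy as np


def brute_threshold(values):
    """median + SD/2 with the n-1 SD, from first principles."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    med = xs[n // 2] if n % 2 else 0.5 * (xs[n // 2 - 1] + xs[n // 2])
    mean = sum(xs) / n
    var = sum((x - mean) ** 2 for x in xs) / (n - 1)
    return med + math.sqrt(var) / 2.0


def brute_favorability(expr, gene_direction=None, sample_class=None):
    """Cell-by-cell favorability scores from the raw definitions.

    ``expr``: dict gene -> dict sample -> value. Exactly one of
    ``gene_direction`` (gene -> 'favorable'/'unfavorable') or
    ``sample_class`` (sample -> +1/-1/0) must be given.
    """
    out = {}
    for gene, row in expr.items():
        thr = brute_threshold(list(row.values()))
        for sample, e in row.items():
            high = e >= thr
            if not high:
                f = 0
            elif gene_direction is not None:
                f = 1 if gene_direction[gene] == "favorable" else -1
            else:
                f = sample_class[sample]
            out[(sample, gene)] = f
    return out


def brute_kendall_tau_b(x, y):
    """Tie-corrected Kendall tau from O(n^2) pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def exact_kendall_p(x, y):
    """Two-sided exact p of Kendall tau by enumerating all orderings of y."""
    obs = abs(brute_kendall_tau_b(x, y))
    n = len(y)
    count = total = 0
    for perm in itertools.permutations(y):
        t = brute_kendall_tau_b(x, list(perm))
        total += 1
        if abs(t) >= obs - 1e-12:
            count += 1
    return count / total


def hypergeom_tail(N, K, M, k):
    """P(X >= k) for overlap of a size-K query and size-M set in universe N."""
    def comb(a, b):
        return math.comb(a, b) if 0 <= b <= a else 0
    denom = comb(N, K)
    return sum(comb(M, i) * comb(N - M, K - i) for i in range(k, min(M, K) + 1)) / denom


def brute_bh(pvalues):
    """Benjamini-Hochberg step-up q-values from the definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def brute_logrank(time1, event1, time2, event2):
    """Two-sample log-rank chi-square statistic from the risk-table sums."""
    times = sorted(set(list(time1[event1 == 1]) + list(time2[event2 == 1])))
    O_minus_E = 0.0
    V = 0.0
    for t in times:
        n1 = np.sum(time1 >= t)
        n2 = np.sum(time2 >= t)
        d1 = np.sum((time1 == t) & (event1 == 1))
        d2 = np.sum((time2 == t) & (event2 == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        O_minus_E += d1 - e1
        V += v
    return (O_minus_E ** 2) / V if V > 0 else 0.0
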