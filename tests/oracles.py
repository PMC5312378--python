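"""Independent brute-force oracles used only by the tests.

Each function here is deliberately written from the textbook definition,
without reusing any code path from the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def partial_loglik_1d(beta, time, event, x):
    """Explicit Cox partial log-likelihood, one covariate, no ties assumed."""
    ll = 0.0
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        denom = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                denom += math.exp(beta * x[j])
        ll += beta * x[i] - math.log(denom)
    return ll


def grid_search_beta(time, event, x, lo=-8.0, hi=8.0, tol=1e-6):
    """Grid-search maximizer of the 1-D partial likelihood, refined by bisection
    on the grid around the best point."""
    grid = np.linspace(lo, hi, 1601)
    vals = [partial_loglik_1d(b, time, event, x) for b in grid]
    k = int(np.argmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    while b - a > tol:
        m1 = a + (b - a) / 3
        m2 = b - (b - a) / 3
        if partial_loglik_1d(m1, time, event, x) < partial_loglik_1d(m2, time, event, x):
            a = m1
        else:
            b = m2
    return 0.5 * (a + b)


def logrank_2group(time, event, group):
    """Two-group log-rank chi-square from per-event-time 2x2 hypergeometric
    moments (mean and variance), allowing tied event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group)
    g1 = group == np.unique(group)[0]
    o_minus_e = 0.0
    var = 0.0
    for tk in np.unique(time[event]):
        at_risk = time >= tk
        nk = at_risk.sum()
        n1k = (at_risk & g1).sum()
        dk = (event & (time == tk)).sum()
        d1k = (event & (time == tk) & g1).sum()
        e1k = dk * n1k / nk
        o_minus_e += d1k - e1k
        if nk > 1:
            var += dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / (nk - 1)
    return o_minus_e**2 / var


def bh_stepup(pvalues):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def quantile_type7(values, q):
    """Linear-interpolation (type 7) quantile by explicit sort-and-index."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])
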