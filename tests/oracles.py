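"""Independent reference implementations used only by the test suite.

Each oracle recomputes a statistic from its definition by direct
enumeration or exact arithmetic, sharing no code with the package.
"""

from __future__ import annotations

import math
from decimal import Decimal, getcontext
from itertools import combinations


def binomial_upper_tail(f: int, n: int, t: int, universe: int) -> float:
    """P(X >= f) for X ~ Bin(n, t/universe) by exact Decimal summation."""
    getcontext().prec = 40
    q = Decimal(t) / Decimal(universe)
    total = Decimal(0)
    for k in range(f, n + 1):
        total += (
            Decimal(math.comb(n, k)) * q**k * (1 - q) ** (n - k)
        )
    return float(min(total, Decimal(1)))


def bh_quadratic(p_values) -> list[float]:
    """Benjamini-Hochberg step-up by the O(m^2) textbook rule.

    adj_(i) = min_{j >= i} m * p_(j) / j, computed per sorted position
    and mapped back to the input order.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    for pos, i in enumerate(order, start=1):
        best = min(
            m * p_values[order[j - 1]] / j for j in range(pos, m + 1)
        )
        adj[i] = min(best, 1.0)
    return adj


def running_sum_es(genes, scores, members, weight=1.0):
    """Brute-force weighted running-sum ES: tabulate every partial sum.

    Returns (es, peak_index_0based, leading_edge).  Uses a stable
    descending sort, hits add |s|^w / sum(|s_hit|^w), misses subtract
    1 / (N - N_hits).
    """
    order = sorted(range(len(genes)), key=lambda i: -scores[i])
    g = [genes[i] for i in order]
    s = [scores[i] for i in order]
    hit = [x in set(members) for x in g]
    n, n_h = len(g), sum(hit)
    assert 0 < n_h < n
    n_r = sum(abs(s[i]) ** weight for i in range(n) if hit[i])
    partial = []
    acc = 0.0
    for i in range(n):
        if hit[i]:
            acc += (abs(s[i]) ** weight / n_r) if n_r > 0 else 1.0 / n_h
        else:
            acc -= 1.0 / (n - n_h)
        partial.append(acc)
    peak = max(range(n), key=lambda i: (abs(partial[i]), -i))
    es = partial[peak]
    if es >= 0:
        le = [g[i] for i in range(peak + 1) if hit[i]]
    else:
        le = [g[i] for i in range(peak, n) if hit[i]]
    return es, peak, le


def exhaustive_two_sided_p(values, n_a, snr_fn) -> float:
    """Exhaustive label-assignment null for a two-group statistic.

    Enumerates every choice of which n_a samples form group A and
    returns the fraction of assignments whose |statistic| reaches the
    observed one (observed = first n_a samples as group A).
    """
    values = list(values)
    n = len(values)
    obs = abs(snr_fn(values[:n_a], values[n_a:]))
    hits = 0
    total = 0
    for idx in combinations(range(n), n_a):
        a = [values[i] for i in idx]
        b = [values[i] for i in range(n) if i not in set(idx)]
        if abs(snr_fn(a, b)) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total
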