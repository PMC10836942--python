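"""Independent reference implementations used to check the package.

These deliberately use a different route than the library code: linear
scans, closed forms, explicit power-set or tail enumeration, and an
O(n^3) agglomeration over explicit cluster lists.
"""

import math

import numpy as np
import pandas as pd


def brute_force_bin(breaks, value):
    """Linear-scan color-key bin: breaks[i] <= v < breaks[i+1], last closed."""
    k = len(breaks) - 1
    if value <= breaks[0]:
        return 0
    if value >= breaks[-1]:
        return k - 1
    for i in range(k):
        if breaks[i] <= value < breaks[i + 1]:
            return i
    raise AssertionError("unreachable")


def welch_oracle(a, b):
    """Closed-form Welch t statistic, Welch-Satterthwaite df and p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df, 2 * tdist.sf(abs(t), df)


def bh_oracle(p):
    """Textbook step-up BH: sort, scale by m/rank, enforce monotonicity."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def hypergeom_tail_oracle(M, n, N, k):
    """P(X >= k) by direct enumeration of the hypergeometric tail sum."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        total += math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
    return total


def naive_agglomerate(D, linkage):
    """O(n^3) reference agglomeration over explicit cluster lists."""
    D = D.astype(float).copy()
    clusters = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ds = [D[a, b] for a in clusters[i] for b in clusters[j]]
                d = {"average": np.mean, "complete": max, "single": min}[linkage](ds)
                key = (d, min(clusters[i] + clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        heights.append(best[0][0])
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for k_, c in enumerate(clusters) if k_ not in (i, j)] + [merged]
    return heights


def powerset_upset_oracle(sets):
    """Exclusive membership-pattern counts by power-set enumeration."""
    from itertools import combinations

    names = list(sets)
    out = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            n = len(inside - outside)
            if n:
                out[combo] = n
    return out


def two_block_matrix(seed=29):
    """Two planted co-expression blocks of 10 genes (within-block r ~ 0.9)."""
    rng = np.random.default_rng(seed)
    t1, t2 = rng.normal(size=8), rng.normal(size=8)
    t1 = (t1 - t1.mean()) / t1.std()
    t2 = (t2 - t2.mean()) / t2.std()
    rows, names = [], []
    for i in range(10):
        rows.append(t1 + rng.normal(0, 0.15, 8))
        names.append(f"m1_{i}")
    for i in range(10):
        rows.append(t2 + rng.normal(0, 0.15, 8))
        names.append(f"m2_{i}")
    return pd.DataFrame(rows, index=names)
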