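"""Independent brute-force oracles used to pin down expected test values.

Every oracle here is deliberately written by a different route than the
implementation it checks (enumeration / textbook recursions / numerical
integration), and stays free of traclon imports.
"""

from __future__ import annotations

import itertools
from math import comb, inf

import numpy as np
from scipy import integrate
from scipy.stats import chi2


def hypergeom_upper_tail(case_present: int, case_total: int,
                         control_present: int, control_total: int) -> float:
    """P(X >= case_present) by direct enumeration of the hypergeometric
    mass for the 2x2 table's margins."""
    K = case_present + control_present
    M = case_total + control_total
    denom = comb(M, K)
    total = 0
    for k in range(case_present, min(K, case_total) + 1):
        if K - k > control_total:
            continue
        total += comb(case_total, k) * comb(control_total, K - k)
    return total / denom


def levenshtein_dp(a: str, b: str) -> int:
    """Full dynamic-programming edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def mann_whitney_exact_two_sided(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled tie-free values to the first group."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)

    def u_stat(group_x):
        gx = set(group_x)
        u = 0
        for xi in group_x:
            for v in pooled:
                if v not in gx and v < xi:
                    u += 1
        return u

    center = n * m / 2
    obs_dev = abs(u_stat(x) - center)
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, n):
        total += 1
        if abs(u_stat(list(combo)) - center) >= obs_dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_two_sided(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign patterns of
    the nonzero, tie-free differences."""
    d = [v for v in diffs if v != 0]
    mags = sorted(abs(v) for v in d)
    assert len(set(mags)) == len(mags), "oracle requires tie-free magnitudes"
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    w_obs = sum(ranks[abs(v)] for v in d if v > 0)
    s = sum(ranks.values())
    center = s / 2
    obs_dev = abs(w_obs - center)
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        total += 1
        w = sum(ranks[abs(v)] for v, sg in zip(d, signs) if sg > 0)
        if abs(w - center) >= obs_dev - 1e-12:
            count += 1
    return count / total


def bh_adjust(ps) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    ps = list(ps)
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def chi2_upper_tail_integrated(stat: float, df: int) -> float:
    """Upper chi-square tail by numerical integration of the density."""
    if stat <= 0:
        return 1.0
    val, _ = integrate.quad(lambda t: chi2.pdf(t, df), stat, np.inf,
                            limit=200)
    return val


def connected_components_bruteforce(nodes, edges):
    """Union-find connected components, independent of networkx."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted((sorted(c) for c in comps.values()),
                  key=lambda c: (-len(c), c[0]))


def pairwise_edges_bruteforce(keys):
    """All same-V/J Hamming-1 pairs by quadratic scan."""
    keys = sorted(keys)
    out = set()
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if a.v_gene != b.v_gene or a.j_gene != b.j_gene:
                continue
            if len(a.cdr3_aa) != len(b.cdr3_aa):
                continue
            d = sum(1 for x, y in zip(a.cdr3_aa, b.cdr3_aa) if x != y)
            if d == 1:
                out.add(frozenset((a, b)))
    return out


def attainable_alpha(n_carriers: int, n_case: int, n_control: int,
                     alpha: float) -> float:
    """Largest achievable one-sided Fisher p strictly below ``alpha`` for a
    clonotype with ``n_carriers`` total carriers, i.e. the exact
    false-positive probability of the discrete test conditional on its
    margins; 0 when no outcome can reach significance."""
    best = 0.0
    for k in range(min(n_carriers, n_case) + 1):
        p = hypergeom_upper_tail(k, n_case, n_carriers - k, n_control)
        if p < alpha:
            best = max(best, p)
    return best
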