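"""Independent brute-force oracles used by the test suite.

These reimplement, by direct enumeration and without any shared helpers,
the quantities the package computes with vectorized or greedy algorithms.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def sync_score_bruteforce(a, b) -> float:
    """SPIKE-synchronization by per-spike enumeration.

    For every spike, find the nearest partner spike by scanning, collect
    the up-to-four adjacent inter-spike intervals, and apply the
    half-minimum coincidence window.
    """
    a, b = list(map(float, a)), list(map(float, b))
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0

    def coincident(x, y):
        total = 0
        for i, t in enumerate(x):
            j = 0
            for k in range(len(y)):
                if abs(y[k] - t) < abs(y[j] - t):
                    j = k
            cands = []
            if i > 0:
                cands.append(x[i] - x[i - 1])
            if i < len(x) - 1:
                cands.append(x[i + 1] - x[i])
            if j > 0:
                cands.append(y[j] - y[j - 1])
            if j < len(y) - 1:
                cands.append(y[j + 1] - y[j])
            tau = 0.5 * min(cands) if cands else float("inf")
            if abs(y[j] - t) < tau:
                total += 1
        return total

    return (coincident(a, b) + coincident(b, a)) / (len(a) + len(b))


def bursts_bruteforce(train, isi_threshold=0.1, min_spikes=3):
    """Burst runs by explicit scan: (start, end, n_spikes) triples."""
    t = list(map(float, train))
    out = []
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] - t[j] <= isi_threshold:
            j += 1
        if j - i + 1 >= min_spikes:
            out.append((t[i], t[j], j - i + 1))
        i = j + 1
    return out


def set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for k in range(len(partition)):
            yield partition[:k] + [[first] + partition[k]] + partition[k + 1:]
        yield [[first]] + partition


def best_partition_exhaustive(graph, resolution=1.0):
    """Maximum-modularity partition of a small graph by full enumeration.

    Modularity is computed with networkx (an implementation independent of
    the package's), so this doubles as a definition cross-check.
    """
    import networkx as nx

    if graph.number_of_edges() == 0:
        return 0.0, [{u} for u in graph.nodes]
    best_q, best = -np.inf, None
    for partition in set_partitions(list(graph.nodes)):
        communities = [set(p) for p in partition]
        q = nx.community.modularity(graph, communities, weight="weight",
                                    resolution=resolution)
        if q > best_q:
            best_q, best = q, communities
    return best_q, best


def ols_slope_ci(x, y, level=0.975):
    """Closed-form OLS slope, intercept and CI from the textbook formulas."""
    from scipy import stats

    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    slope = ((x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - slope * x - intercept
    s2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    tq = stats.t.ppf(level, n - 2)
    return slope, intercept, slope - tq * se, slope + tq * se


def welch_free_ttest(a, b):
    """Pooled-variance two-sample t statistic by hand (equal-variance form)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
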