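"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the mathematical definition, deliberately
avoiding the code paths (and, where possible, the libraries) used by the
package itself.
"""

from __future__ import annotations

import math

import numpy as np


def brute_bh(p_values):
    """Benjamini-Hochberg adjusted p-values straight from the definition:
    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted p-values."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        q[i] = min(1.0, running_min)
    return q


def brute_ssgsea(profile: dict, gene_set, exponent: float) -> float:
    """Plain-Python running-sum enumeration of the ssGSEA integral."""
    order = sorted(profile, key=lambda g: (-profile[g], g))
    n = len(order)
    members = set(gene_set) & set(order)
    m = len(members)
    ranks = {g: n - i for i, g in enumerate(order)}
    norm = sum(abs(ranks[g]) ** exponent for g in members)
    running = 0.0
    total = 0.0
    for g in order:
        if g in members:
            running += (abs(ranks[g]) ** exponent) / norm
        else:
            running -= 1.0 / (n - m)
        total += running
    return total


def brute_spearman(x, y) -> float:
    """Spearman correlation from ranks computed by hand (average ties)."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def brute_two_way_fit(values: np.ndarray) -> np.ndarray:
    """Least-squares fit of mu + row_effect + col_effect on the observed
    cells of a (possibly NaN-holed) matrix, via the minimum-norm solution of
    the overparameterized 0/1 design.  Returns the fitted matrix (NaN where
    unobserved); residuals are what the package's normalization removes."""
    n_r, n_c = values.shape
    mask = ~np.isnan(values)
    rows, cols = np.nonzero(mask)
    y = values[mask]
    X = np.zeros((y.size, 1 + n_r + n_c))
    X[:, 0] = 1.0
    X[np.arange(y.size), 1 + rows] = 1.0
    X[np.arange(y.size), 1 + n_r + cols] = 1.0
    beta = np.linalg.pinv(X) @ y
    fitted = np.full_like(values, np.nan)
    fitted[mask] = X @ beta
    return fitted


def lw_ward_merges(D: np.ndarray):
    """Naive agglomerative Ward clustering by the Lance-Williams recurrence.

    ``D`` is a symmetric dissimilarity matrix.  Returns the merge history as
    a list of (frozenset_of_leaf_indices, height), smallest-distance pair
    first; ties break on the smaller pair of cluster creation indices.
    """
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])
    merges = []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = min(
            ((dist[tuple(sorted((a, b)))], a, b)
             for ai, a in enumerate(active) for b in active[ai + 1:]),
        )
        h, s, t = best
        v_new = clusters[s] | clusters[t]
        merges.append((v_new, h))
        ns, nt = len(clusters[s]), len(clusters[t])
        for v in active:
            if v in (s, t):
                continue
            nv = len(clusters[v])
            dvs = dist[tuple(sorted((v, s)))]
            dvt = dist[tuple(sorted((v, t)))]
            dst = h
            d_new = math.sqrt(
                ((nv + ns) * dvs**2 + (nv + nt) * dvt**2 - nv * dst**2)
                / (nv + ns + nt)
            )
            dist[tuple(sorted((v, next_id)))] = d_new
        clusters[next_id] = v_new
        active = [v for v in active if v not in (s, t)] + [next_id]
        next_id += 1
    return merges


def lw_ward_cut(merges, n: int, k: int):
    """Partition of the n leaves into k clusters by undoing the last k-1
    merges of the Lance-Williams history."""
    parts = {frozenset([i]) for i in range(n)}
    for new_cluster, _ in merges[: n - k]:
        parts = {p for p in parts if not p <= new_cluster}
        parts.add(new_cluster)
    return parts


def cox_newton_binary(times, events, x, iters: int = 50) -> float:
    """Newton-Raphson on the hand-written Cox partial likelihood (single
    covariate, Breslow risk sets; assumes untied event times)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    beta = 0.0
    for _ in range(iters):
        u = 0.0
        info = 0.0
        for i in np.nonzero(events)[0]:
            risk = times >= times[i]
            w = np.exp(beta * x[risk])
            s0 = w.sum()
            s1 = (w * x[risk]).sum()
            s2 = (w * x[risk] ** 2).sum()
            u += x[i] - s1 / s0
            info += s2 / s0 - (s1 / s0) ** 2
        if info == 0:
            break
        step = u / info
        beta += step
        if abs(step) < 1e-12:
            break
    return beta


def km_hand(times, events):
    """Product-limit estimator computed directly from risk sets.

    Returns a list of (event_time, survival_after) pairs.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = []
    for t in sorted(set(times[events == 1])):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out
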