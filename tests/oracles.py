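"""Brute-force reference implementations used only by the tests.

Each oracle recomputes a metric from its printed definition with the
slowest, most literal algorithm available, sharing no code with the
package implementations.
"""

import numpy as np

TIE_TOL = 1e-12


def floyd_warshall(lengths):
    """All-pairs shortest path lengths by the textbook triple loop."""
    n = len(lengths)
    d = np.where(lengths > 0, lengths, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def shortest_path_counts(lengths, d):
    """sigma[s, t]: number of shortest s-t paths, by DP in distance order."""
    n = len(lengths)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(d[s])
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            for u in range(n):
                if lengths[u, t] > 0 and np.isclose(
                        d[s, u] + lengths[u, t], d[s, t],
                        rtol=TIE_TOL, atol=TIE_TOL):
                    sigma[s, t] += sigma[s, u]
    return sigma


def oracle_betweenness(weights):
    """Unnormalised betweenness over unordered pairs, pair-by-pair."""
    n = len(weights)
    lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1),
                       0.0)
    d = floyd_warshall(lengths)
    sigma = shortest_path_counts(lengths, d)
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if v in (s, t) or s == t or not np.isfinite(d[s, t]):
                    continue
                if sigma[s, t] > 0 and np.isclose(
                        d[s, v] + d[v, t], d[s, t],
                        rtol=TIE_TOL, atol=TIE_TOL):
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc / 2.0  # ordered -> unordered pairs


def oracle_local_efficiency(weights):
    """Eq.-4 weighted local efficiency, neighbourhood subgraph paths."""
    n = len(weights)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(weights[i] > 0)
        deg = len(nbrs)
        if deg < 2:
            continue
        sub_w = weights[np.ix_(nbrs, nbrs)]
        sub_len = np.where(sub_w > 0, 1.0 / np.where(sub_w > 0, sub_w, 1),
                           0.0)
        d = floyd_warshall(sub_len)
        total = 0.0
        for a in range(deg):
            for b in range(deg):
                if a == b or not np.isfinite(d[a, b]) or d[a, b] == 0:
                    continue
                total += (weights[i, nbrs[a]] * weights[i, nbrs[b]]
                          / d[a, b]) ** (1.0 / 3.0)
        out[i] = total / (deg * (deg - 1))
    return out


def oracle_clustering(weights):
    """Eq.-5 Onnela clustering with max-scaled weights, triple loop."""
    n = len(weights)
    w_max = weights.max()
    scaled = weights / w_max
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(weights[i] > 0)
        deg = len(nbrs)
        if deg < 2:
            continue
        total = 0.0
        for j in nbrs:
            for h in nbrs:
                if j == h:
                    continue
                total += (scaled[i, j] * scaled[j, h]
                          * scaled[i, h]) ** (1.0 / 3.0)
        out[i] = total / (deg * (deg - 1))
    return out


def oracle_participation(weights, module_id):
    """Eq.-6 participation from binary counts, node by node."""
    n = len(weights)
    adj = weights > 0
    out = np.zeros(n)
    for i in range(n):
        d = int(adj[i].sum())
        if d == 0:
            continue
        acc = 0.0
        for m in np.unique(module_id):
            d_im = int(adj[i][module_id == m].sum())
            acc += (d_im / d) ** 2
        out[i] = 1.0 - acc
    return out


def oracle_s_core_survivors(weights, s):
    """Node-strength fixpoint by repeated full recomputation on sets."""
    alive = set(range(len(weights)))
    changed = True
    while changed:
        changed = False
        for i in sorted(alive):
            strength = sum(weights[i, j] for j in alive if j != i)
            if strength < s:
                alive.discard(i)
                changed = True
                break
    return alive
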