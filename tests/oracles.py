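"""Independent brute-force reference implementations used by the tests.

These deliberately follow the definitions step by step (explicit loops,
plain formulas) and share no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def naive_sl_pair(x: np.ndarray, y: np.ndarray, params) -> float:
    """Double-loop synchronization likelihood.

    Per reference time i: collect candidate times j with w1 < |i-j| < w2,
    pick the critical distance as the ceil(p_ref*n)-th smallest embedding
    distance separately in each signal, count recurrences of x and hits
    where y also recurs, average hits/recurrences over i, and symmetrize.
    """

    def zscore(s):
        s = np.asarray(s, dtype=float)
        return (s - s.mean()) / s.std()

    def embed_naive(s, m, l):
        return np.array([[s[t + k * l] for k in range(m)]
                         for t in range(len(s) - (m - 1) * l)])

    vx = embed_naive(zscore(x), params.m, params.l)
    vy = embed_naive(zscore(y), params.m, params.l)
    n = len(vx)

    def recurrences(v, i):
        js = [j for j in range(n)
              if params.w1 < abs(i - j) < params.w2]
        d = np.array([np.linalg.norm(v[i] - v[j]) for j in js])
        k = max(1, math.ceil(params.p_ref * len(js)))
        eps = np.sort(d)[k - 1]
        return {j for j, dj in zip(js, d) if dj <= eps}

    totals = []
    for first, second in ((vx, vy), (vy, vx)):
        s_i = []
        for i in range(n):
            rec1 = recurrences(first, i)
            rec2 = recurrences(second, i)
            s_i.append(len(rec1 & rec2) / len(rec1))
        totals.append(np.mean(s_i))
    return 0.5 * (totals[0] + totals[1])


def brute_force_clustering(adj: np.ndarray) -> float:
    """Mean over vertices of closed/(closed+open) neighbour triples."""
    n = adj.shape[0]
    c = []
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            c.append(0.0)
            continue
        closed = open_ = 0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                if adj[nbrs[a], nbrs[b]]:
                    closed += 1
                else:
                    open_ += 1
        c.append(closed / (closed + open_))
    return float(np.mean(c))


def bfs_distances(adj: np.ndarray, start: int) -> list[float]:
    """Hop counts from ``start`` to every vertex (inf when unreachable)."""
    n = adj.shape[0]
    dist = [math.inf] * n
    dist[start] = 0
    queue = [start]
    while queue:
        v = queue.pop(0)
        for u in range(n):
            if adj[v, u] and dist[u] == math.inf:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def brute_force_path_length(adj: np.ndarray) -> float:
    """Harmonic path length via explicit breadth-first search.

    L_i aggregates the distances from i harmonically ((N-1)/sum of inverse
    distances, unreachable contributing zero); L is the harmonic mean of the
    L_i over vertices.
    """
    n = adj.shape[0]
    inv_li = []
    for v in range(n):
        d = bfs_distances(adj, v)
        inv_sum = sum(1.0 / d[u] for u in range(n) if u != v and d[u] != math.inf)
        inv_li.append(inv_sum / (n - 1))
    total = sum(inv_li)
    return n / total if total > 0 else math.inf
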