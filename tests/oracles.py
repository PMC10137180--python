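"""Independent reference implementations used only as test oracles.

Deliberately naive: Floyd-Warshall distances, explicit enumeration of
all shortest paths for betweenness, and triple loops for clustering.
They share no code path with the package's metric implementations.
"""

from __future__ import annotations

import numpy as np


def fw_distances(A: np.ndarray) -> np.ndarray:
    n = len(A)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[np.asarray(A, dtype=bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_degree(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=bool)
    return np.array([sum(A[i]) for i in range(len(A))], dtype=float)


def brute_clustering(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=bool)
    n = len(A)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        e = sum(
            1 for a in range(k) for b in range(a + 1, k) if A[nbrs[a], nbrs[b]]
        )
        out[i] = 2.0 * e / (k * (k - 1))
    return out


def brute_nodal_efficiency(A: np.ndarray) -> np.ndarray:
    d = fw_distances(A)
    n = len(d)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
        out[i] = acc / (n - 1)
    return out


def brute_local_efficiency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=bool)
    n = len(A)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        d = fw_distances(sub)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]):
                    acc += 1.0 / d[a, b]
        out[i] = acc / (k * (k - 1))
    return out


def _all_shortest_paths(A: np.ndarray, d: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Enumerate every shortest s-t path (as node lists) recursively."""
    if s == t:
        return [[t]]
    paths = []
    for u in range(len(A)):
        if A[s, u] and d[u, t] == d[s, t] - 1:
            for tail in _all_shortest_paths(A, d, u, t):
                paths.append([s] + tail)
    return paths


def brute_betweenness(A: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Betweenness by explicit enumeration of all shortest paths."""
    A = np.asarray(A, dtype=bool)
    n = len(A)
    d = fw_distances(A)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]):
                continue
            paths = _all_shortest_paths(A, d, s, t)
            sigma = len(paths)
            through = np.zeros(n)
            for p in paths:
                for v in p[1:-1]:
                    through[v] += 1
            bc += through / sigma
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def two_pass_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return float(num / den)


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    A = rng.random((n, n)) < p
    A = np.triu(A, 1)
    return A | A.T
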