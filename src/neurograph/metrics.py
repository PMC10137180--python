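"""Nodal topological metrics on binary undirected graphs, plus AUC.

Five node-level properties are computed natively on the adjacency
matrix:

* **degree centrality** — number of neighbours, k_i;
* **clustering coefficient** — C_i = 2 e_i / (k_i (k_i - 1)), where e_i
  is the number of edges among the neighbours of i (0 when k_i < 2);
* **nodal efficiency** — E_nod(i) = (1/(N-1)) * sum_{j != i} 1/d_ij,
  with 1/inf = 0 for unreachable pairs;
* **nodal local efficiency** — the global efficiency of the subgraph
  induced by i's neighbours, distances measured *within* that subgraph
  (Latora-Marchiori convention; 0 when k_i < 2);
* **betweenness centrality** — Brandes' accumulation of the fraction of
  all-pairs shortest paths passing through the node, reported normalized
  by (N-1)(N-2)/2 so values lie in [0, 1].

Disconnected graphs are handled by 1/inf = 0 throughout; no restriction
to the largest component is applied, because sparsely thresholded
networks are routinely disconnected.

A metric profile measured across the sparsity sweep is collapsed into a
single threshold-independent scalar per node by the trapezoidal area
under the curve over the grid.
"""

from __future__ import annotations

import numpy as np

from .connectivity import BinaryNetwork, SparsityGrid

METRIC_NAMES = (
    "local_efficiency",
    "nodal_efficiency",
    "clustering",
    "degree",
    "betweenness",
)


def _as_adjacency(g) -> np.ndarray:
    A = g.adjacency if isinstance(g, BinaryNetwork) else np.asarray(g)
    return A.astype(bool)


def degree_centrality(g) -> np.ndarray:
    A = _as_adjacency(g)
    return A.sum(axis=1).astype(float)


def clustering_coefficient(g) -> np.ndarray:
    A = _as_adjacency(g).astype(np.int64)
    k = A.sum(axis=1)
    # (A@A * A).sum(1) counts ordered neighbour pairs that are connected = 2*e_i
    two_e = ((A @ A) * A).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, two_e / denom, 0.0)
    return c.astype(float)


def shortest_path_lengths(g) -> np.ndarray:
    """All-pairs hop distances via level-synchronous BFS (matrix form).

    Unreachable pairs get +inf; the diagonal is 0.
    """
    A = _as_adjacency(g).astype(np.uint8)
    n = A.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=np.uint8)
    d = 0
    while frontier.any():
        d += 1
        nxt = ((frontier @ A) > 0) & ~reached
        if not nxt.any():
            break
        dist[nxt] = d
        reached |= nxt
        frontier = nxt.astype(np.uint8)
    return dist


def _efficiency_from_dist(dist: np.ndarray) -> float:
    """Mean inverse distance over ordered pairs (global efficiency)."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(g) -> np.ndarray:
    A = _as_adjacency(g)
    n = A.shape[0]
    dist = shortest_path_lengths(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def nodal_local_efficiency(g) -> np.ndarray:
    A = _as_adjacency(g)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        out[i] = _efficiency_from_dist(shortest_path_lengths(sub))
    return out


def betweenness_centrality(g, *, normalized: bool = True) -> np.ndarray:
    """Brandes betweenness over unordered pairs s != i != t.

    With ``normalized=True`` (default) values are divided by
    (N-1)(N-2)/2, the number of pairs a node could lie between.
    """
    A = _as_adjacency(g)
    n = A.shape[0]
    Af = A.astype(float)
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, -1, dtype=np.int64)
        sigma = np.zeros(n)
        dist[s] = 0
        sigma[s] = 1.0
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        d = 0
        levels = [frontier]
        while True:
            contrib = Af[:, frontier] @ sigma[frontier]
            nxt = (contrib > 0) & (dist < 0)
            if not nxt.any():
                break
            d += 1
            dist[nxt] = d
            sigma[nxt] = contrib[nxt]
            frontier = nxt
            levels.append(frontier)
        delta = np.zeros(n)
        for lev in range(len(levels) - 1, 0, -1):
            mask = levels[lev]
            w = (1.0 + delta[mask]) / sigma[mask]
            back = Af[:, mask] @ w
            prev = levels[lev - 1]
            delta[prev] += sigma[prev] * back[prev]
        delta[s] = 0.0
        bc += delta
    bc /= 2.0  # each unordered pair visited from both endpoints
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


_METRIC_FUNCS = {
    "degree": degree_centrality,
    "clustering": clustering_coefficient,
    "nodal_efficiency": nodal_efficiency,
    "local_efficiency": nodal_local_efficiency,
    "betweenness": betweenness_centrality,
}


def compute_metric(name: str, g) -> np.ndarray:
    try:
        fn = _METRIC_FUNCS[name]
    except KeyError:
        raise KeyError(f"unknown metric {name!r}; choose from {METRIC_NAMES}") from None
    return fn(g)


def metric_cube(networks: list[BinaryNetwork], metrics=METRIC_NAMES) -> dict[str, np.ndarray]:
    """Per-metric N x K value matrices over a subject's threshold sweep."""
    out: dict[str, np.ndarray] = {}
    for name in metrics:
        out[name] = np.column_stack([compute_metric(name, g) for g in networks])
    return out


def auc_over_grid(values: np.ndarray, grid: SparsityGrid) -> np.ndarray:
    """Trapezoidal area under the metric-vs-sparsity curve.

    ``values`` is (..., K) over the K grid thresholds; requires K >= 2.
    """
    v = np.asarray(values, dtype=float)
    s = grid.values
    if v.shape[-1] != len(s):
        raise ValueError(f"values last axis {v.shape[-1]} != grid size {len(s)}")
    if len(s) < 2:
        raise ValueError("AUC needs at least 2 grid points")
    return np.trapezoid(v, s, axis=-1)


def compute_all_metrics(networks: list[BinaryNetwork], grid: SparsityGrid,
                        metrics=METRIC_NAMES):
    """All requested metrics at all thresholds plus nodal AUCs.

    Returns ``(cube, auc)`` where cube maps metric -> N x K matrix and
    auc maps metric -> length-N vector.
    """
    if len(networks) != len(grid):
        raise ValueError("one network per grid threshold required")
    cube = metric_cube(networks, metrics)
    auc = {name: auc_over_grid(vals, grid) for name, vals in cube.items()}
    return cube, auc
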