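"""Independent brute-force oracles for graph metrics.

Deliberately naive: Floyd-Warshall by triple loop, clustering by iterating
node triples, betweenness by enumerating every shortest path.  Tractable
only for tiny graphs; used to validate the production implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_oracle(adj: np.ndarray) -> tuple[float, float]:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(i + 1, n)]
    finite = [v for v in vals if np.isfinite(v)]
    frac = len(finite) / len(vals) if vals else 0.0
    return (float(np.mean(finite)) if finite else float("nan")), frac


def global_efficiency_oracle(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [
        1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals)) if vals else 0.0


def clustering_oracle(adj: np.ndarray) -> tuple[float, np.ndarray]:
    n = adj.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        c[i] = 2 * links / (k * (k - 1))
    return float(c.mean()), c


def _all_shortest_paths(adj: np.ndarray, dist: np.ndarray, s: int, t: int):
    """Every shortest s-t path, by DFS along distance-decreasing neighbors."""
    if not np.isfinite(dist[s, t]):
        return []
    if s == t:
        return [[s]]
    paths = []
    for u in np.flatnonzero(adj[s]):
        if dist[u, t] == dist[s, t] - 1:
            for rest in _all_shortest_paths(adj, dist, int(u), t):
                paths.append([s] + rest)
    return paths


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness, each unordered pair counted once."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    u = rng.random((n, n))
    adj = np.triu(u < p, 1).astype(int)
    return adj + adj.T
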