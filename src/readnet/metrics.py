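"""Topological metrics on binary undirected networks.

Global: clustering coefficient Cp, characteristic path length Lp, global
and local efficiency, plus gamma/lambda/sigma normalized against
degree-preserving (Maslov-Sneppen) rewired null networks.  Nodal: degree
and Brandes betweenness.

Conventions (declared, since disconnected graphs arise at sparse
thresholds): Lp averages over reachable pairs only, and every metric table
carries the reachable fraction so that convention is visible in the
output; nodes of degree < 2 contribute 0 to Cp and local efficiency, and
the means run over all N nodes.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import BinaryNetwork

__all__ = [
    "GLOBAL_METRICS",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "degree_centrality",
    "betweenness_centrality",
    "rewire_degree_preserving",
    "normalized_metrics",
    "compute_global_metrics",
    "compute_nodal_metrics",
]

#: Global metric names in canonical output order.
GLOBAL_METRICS = ("Cp", "Lp", "gamma", "lambda", "sigma", "E_glob", "E_loc")


def _as_adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return np.asarray(net.adjacency, dtype=np.int64)
    return np.asarray(net, dtype=np.int64)


def _pairwise_distances(adj: np.ndarray) -> np.ndarray:
    """Unweighted shortest-path matrix (inf where unreachable)."""
    n = adj.shape[0]
    if n <= 1 or adj.sum() == 0:
        d = np.full(adj.shape, np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    if n <= 128:
        return _bfs_distances_bool(adj > 0)
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def _bfs_distances_bool(a: np.ndarray) -> np.ndarray:
    """Level-synchronous BFS from all sources at once via boolean matmul;
    much cheaper than sparse-graph machinery for graphs this size."""
    n = a.shape[0]
    dist = np.where(a, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = a | np.eye(n, dtype=bool)
    d = 1
    while d < n:
        new = (reach @ a) & ~reach
        if not new.any():
            break
        d += 1
        dist[new] = d
        reach |= new
    return dist


def clustering_coefficient(
    net: BinaryNetwork | np.ndarray,
) -> tuple[float, np.ndarray]:
    """(Cp, nodal values): C_i = 2 T_i / (k_i (k_i - 1)), 0 when k_i < 2.

    T_i counts edges among i's neighbors (= triangles through i); Cp is the
    mean over all N nodes.
    """
    a = _as_adjacency(net)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2 * triangles / np.where(denom, denom, 1), 0.0)
    return float(c.mean()), c


def characteristic_path_length(
    net: BinaryNetwork | np.ndarray,
) -> tuple[float, float]:
    """(Lp, reachable_fraction).

    Lp is the mean shortest-path distance over unordered pairs with a
    finite distance; a graph with no finite pairs yields (nan, 0.0).
    """
    d = _pairwise_distances(_as_adjacency(net))
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    vals = d[iu]
    finite = np.isfinite(vals)
    frac = float(finite.mean()) if vals.size else 0.0
    if not finite.any():
        return float("nan"), frac
    return float(vals[finite].mean()), frac


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean of 1/d over all unordered pairs, with 1/inf = 0."""
    d = _pairwise_distances(_as_adjacency(net))
    n = d.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    return float(np.where(np.isfinite(inv), inv, 0.0).mean())


def local_efficiency(net: BinaryNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """(E_loc, nodal values): mean over nodes of the global efficiency of
    the subgraph induced by each node's neighbors (0 when degree < 2)."""
    a = _as_adjacency(net) > 0
    n = a.shape[0]
    nodal = np.zeros(n)
    with np.errstate(divide="ignore"):
        for i in range(n):
            nbrs = np.flatnonzero(a[i])
            k = nbrs.size
            if k < 2:
                continue
            dist = _bfs_distances_bool(a[np.ix_(nbrs, nbrs)])
            inv = 1.0 / dist  # diagonal and unreachable -> inf -> dropped
            # full-matrix sum counts ordered pairs, matching k(k-1)
            nodal[i] = inv[np.isfinite(inv)].sum() / (k * (k - 1))
    return float(nodal.mean()), nodal


def degree_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    return _as_adjacency(net).sum(axis=1).astype(int)


def betweenness_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Brandes betweenness, unnormalized, each unordered pair counted once."""
    a = _as_adjacency(net)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(a.shape[0])])


def rewire_degree_preserving(
    net: BinaryNetwork, n_swaps: int | None = None, seed: int | None = None
) -> BinaryNetwork:
    """Maslov-Sneppen rewiring: repeated double-edge swap attempts
    (a-b, c-d -> a-d, c-b), rejecting any that would create a self-loop or
    a multi-edge.  The degree sequence is preserved exactly.

    `n_swaps` counts attempts (default 10 * |E|).  A complete graph admits
    no legal swap and is returned unchanged with a warning.
    """
    m = net.n_edges
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    n = net.n_nodes
    if m == n * (n - 1) // 2:
        warnings.warn("complete graph has no legal swap; returning input unchanged")
        return net
    if n_swaps is None:
        n_swaps = 10 * m
    rng = np.random.default_rng(seed)
    edges = net.edge_list()
    eset = set(edges)
    ei = rng.integers(0, m, size=n_swaps)
    ej = rng.integers(0, m, size=n_swaps)
    flip = rng.integers(0, 2, size=n_swaps)
    for t in range(n_swaps):
        ia, ib = int(ei[t]), int(ej[t])
        if ia == ib:
            continue
        a, b = edges[ia]
        c, d = edges[ib]
        if flip[t]:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in eset or new2 in eset:
            continue
        eset.discard(edges[ia])
        eset.discard(edges[ib])
        eset.add(new1)
        eset.add(new2)
        edges[ia] = new1
        edges[ib] = new2
    adj = np.zeros((n, n), dtype=np.int8)
    idx = np.array(sorted(eset))
    adj[idx[:, 0], idx[:, 1]] = 1
    adj |= adj.T
    return BinaryNetwork(
        adjacency=adj,
        sparsity=net.sparsity,
        node_labels=net.node_labels,
        subject_id=net.subject_id,
        group=net.group,
        session=net.session,
    )


def normalized_metrics(
    net: BinaryNetwork, n_null: int = 100, seed: int | None = None
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against degree-preserving rewired nulls.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null> (same reachable-pairs
    convention for the nulls), sigma = gamma / lambda.  A zero null mean
    clustering flags gamma (and sigma) as nan with a warning.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    cp, _ = clustering_coefficient(net)
    lp, _ = characteristic_path_length(net)
    ss = np.random.SeedSequence(seed)
    null_seeds = ss.generate_state(n_null, dtype=np.uint32)
    null_cp = np.empty(n_null)
    null_lp = np.empty(n_null)
    for k in range(n_null):
        null = rewire_degree_preserving(net, seed=int(null_seeds[k]))
        null_cp[k], _ = clustering_coefficient(null)
        null_lp[k], _ = characteristic_path_length(null)
    mean_cp = null_cp.mean()
    mean_lp = np.nanmean(null_lp) if np.isfinite(null_lp).any() else float("nan")
    if mean_cp == 0:
        warnings.warn("null networks have zero mean clustering; gamma undefined")
        gamma = float("nan")
    else:
        gamma = cp / mean_cp
    lam = lp / mean_lp if mean_lp and np.isfinite(mean_lp) else float("nan")
    sigma = gamma / lam
    return float(gamma), float(lam), float(sigma)


def compute_global_metrics(
    net: BinaryNetwork,
    n_null: int = 0,
    seed: int | None = None,
    metrics: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """All requested global metrics for one network, as a flat dict.

    Normalized metrics (gamma/lambda/sigma) are computed only when
    requested and ``n_null > 0``; reachable_fraction always accompanies Lp.
    """
    wanted = GLOBAL_METRICS if metrics is None else tuple(metrics)
    unknown = set(wanted) - set(GLOBAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    out: dict[str, float] = {}
    if "Cp" in wanted:
        out["Cp"], _ = clustering_coefficient(net)
    if "Lp" in wanted:
        out["Lp"], out["reachable_fraction"] = characteristic_path_length(net)
    if "E_glob" in wanted:
        out["E_glob"] = global_efficiency(net)
    if "E_loc" in wanted:
        out["E_loc"], _ = local_efficiency(net)
    if any(m in wanted for m in ("gamma", "lambda", "sigma")):
        if n_null > 0:
            gamma, lam, sigma = normalized_metrics(net, n_null=n_null, seed=seed)
        else:
            gamma = lam = sigma = float("nan")
        for name, val in (("gamma", gamma), ("lambda", lam), ("sigma", sigma)):
            if name in wanted:
                out[name] = val
    return out


def compute_nodal_metrics(net: BinaryNetwork) -> dict[str, np.ndarray]:
    """Per-node degree and betweenness for one network."""
    return {
        "degree": degree_centrality(net),
        "betweenness": betweenness_centrality(net),
    }
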