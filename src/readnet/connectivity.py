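"""Functional connectivity matrices and sparsity-thresholded binary graphs.

Pearson correlation over ROI pairs, Fisher z = atanh(r) for normality, and
binarization by sparsity: keep the strongest positive edges until the graph
holds floor(s * N(N-1)/2) of the possible edges.  Negative correlations are
never turned into edges (their physiological meaning is ambiguous), so very
sparse positive structure can leave the achieved sparsity below the target,
which is then recorded and warned about rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import RoiTimeSeriesSet

__all__ = [
    "ZConnectivityMatrix",
    "BinaryNetwork",
    "roi_correlation_matrix",
    "edge_count_for_sparsity",
    "threshold_by_sparsity",
    "sparsity_ladder",
    "default_sparsities",
]

Z_CLIP = 1 - 1e-12


@dataclass(frozen=True)
class ZConnectivityMatrix:
    """Symmetric Fisher-z connectivity with its underlying correlations.

    The diagonal is masked (z and r set to 0 and 1 respectively and
    excluded from all edge operations).
    """

    z: np.ndarray
    r: np.ndarray
    roi_labels: tuple[str, ...]
    subject_id: str = ""
    group: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if z.shape != r.shape or z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z and r must be matching square matrices")
        if z.shape[0] != len(self.roi_labels):
            raise ValueError("matrix size does not match roi_labels")
        if not np.allclose(z, z.T, atol=0, rtol=0):
            raise ValueError("z matrix must be exactly symmetric")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "r", r)

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


def roi_correlation_matrix(
    ts: RoiTimeSeriesSet, volumes: np.ndarray | None = None
) -> ZConnectivityMatrix:
    """Pearson correlations between all ROI pairs, Fisher transformed.

    `volumes` optionally restricts the computation to a boolean mask or
    index array over analyzed volumes (e.g. task blocks only).  Constant
    ROIs get zero correlation with everything, with a warning; r is clipped
    away from +/-1 before atanh so z stays finite.
    """
    data = ts.data if volumes is None else ts.data[:, volumes]
    if data.shape[1] < 3:
        raise ValueError("need at least 3 volumes to correlate")
    const = np.ptp(data, axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant ROI(s); their correlations are set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[const, :] = 0.0
    r[:, const] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    np.fill_diagonal(z, 0.0)
    return ZConnectivityMatrix(
        z=z,
        r=r,
        roi_labels=ts.roi_labels,
        subject_id=ts.subject_id,
        group=ts.group,
        session=ts.session,
    )


def edge_count_for_sparsity(n_nodes: int, s: float) -> int:
    """floor(s * N(N-1)/2): the number of edges a sparsity-s graph holds."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 < s <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    return int(np.floor(s * n_nodes * (n_nodes - 1) / 2 + 1e-9))


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted graph at a given target sparsity."""

    adjacency: np.ndarray  # [N, N] of 0/1, zero diagonal
    sparsity: float  # requested
    node_labels: tuple[str, ...]
    subject_id: str = ""
    group: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.node_labels):
            raise ValueError("adjacency size does not match node_labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def achieved_sparsity(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(i.tolist(), j.tolist()))


def threshold_by_sparsity(zc: ZConnectivityMatrix, s: float) -> BinaryNetwork:
    """Keep the strongest positive-z edges up to the sparsity's edge budget.

    Edges are ranked by z descending; ties at the cutoff break
    lexicographically by (row, column) index so the result is
    deterministic.  If fewer positive entries exist than the budget, all
    of them are kept and a warning records the achieved sparsity.
    """
    n = zc.n_nodes
    target = edge_count_for_sparsity(n, s)
    iu, ju = np.triu_indices(n, 1)
    vals = zc.z[iu, ju]
    pos = vals > 0
    iu, ju, vals = iu[pos], ju[pos], vals[pos]
    order = np.lexsort((ju, iu, -vals))
    keep = order[:target]
    if keep.size < target:
        achieved = keep.size / (n * (n - 1) / 2)
        warnings.warn(
            f"only {keep.size} positive edges available for a target of "
            f"{target}; achieved sparsity {achieved:.4f}"
        )
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryNetwork(
        adjacency=adj,
        sparsity=s,
        node_labels=zc.roi_labels,
        subject_id=zc.subject_id,
        group=zc.group,
        session=zc.session,
    )


def default_sparsities(
    s_min: float = 0.05, s_max: float = 0.50, step: float = 0.05
) -> list[float]:
    """The sparsity ladder {s_min, s_min+step, ..., s_max} (inclusive)."""
    if not 0 < s_min <= s_max <= 1:
        raise ValueError("need 0 < s_min <= s_max <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((s_max - s_min) / step + 1e-9)) + 1
    return [round(s_min + k * step, 10) for k in range(n)]


def sparsity_ladder(
    zc: ZConnectivityMatrix,
    s_min: float = 0.05,
    s_max: float = 0.50,
    step: float = 0.05,
) -> list[BinaryNetwork]:
    """One BinaryNetwork per ladder sparsity; defaults give 10 networks."""
    return [threshold_by_sparsity(zc, s) for s in default_sparsities(s_min, s_max, step)]
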