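"""Binary graph construction and metrics for functional connectomes.

A subject's region-by-region correlation matrix is reduced to an undirected
binary graph by proportional (sparsity) thresholding: keep the strongest
``s`` fraction of the possible edges, discard the rest.  Comparing topology
at a fixed edge density, rather than at a fixed correlation cutoff, is what
makes graph metrics comparable across subjects whose overall correlation
level differs.

Four measures are computed on each binary graph:

* per-region clustering coefficient and its graph-wide mean,
* per-region eigenvector centrality (principal eigenvector of the adjacency
  matrix, L2-normalised, non-negative),
* assortativity (Pearson correlation of degrees across edge endpoints).

All metrics are implemented directly on the adjacency matrix with numpy;
no graph library is used at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix

__all__ = [
    "SparsityGrid",
    "BinaryGraph",
    "sparsity_threshold",
    "clustering_coefficient",
    "eigenvector_centrality",
    "assortativity",
    "metric_sweep",
    "LOCAL_METRICS",
    "GLOBAL_METRICS",
]

#: names used in metric tables
LOCAL_METRICS = ("clustering", "eigenvector_centrality")
GLOBAL_METRICS = ("mean_clustering", "assortativity")


def _default_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered set of edge-density proportions, default 0.10 ... 0.50 step 0.05."""

    values: tuple[float, ...] = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError("sparsity grid is empty")
        if any(not (0.0 < v < 1.0) for v in vals):
            raise ValueError(f"sparsity values must lie in (0, 1): {vals}")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"sparsity grid must be strictly increasing: {vals}")
        object.__setattr__(self, "values", vals)

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BinaryGraph:
    """Undirected 0/1 adjacency at one sparsity level."""

    adjacency: np.ndarray
    region_labels: tuple[str, ...]
    sparsity: float

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = A.astype(np.int8)
        self.region_labels = tuple(str(r) for r in self.region_labels)
        if len(self.region_labels) != A.shape[0]:
            raise ValueError("region_labels length does not match adjacency")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def edge_list(self) -> list[tuple[int, int]]:
        """Undirected edges as (i, j) index pairs with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (self.region_labels[i], self.region_labels[j])
            for i, j in self.edge_list()
        ]
        return pd.DataFrame(rows, columns=["source", "target"])


def edge_count_for_sparsity(n_regions: int, sparsity: float) -> int:
    """Number of edges retained at a proportional threshold.

    Round-half-away-from-zero of ``s * R(R-1)/2`` so that e.g. R=116 at
    s=0.10 yields exactly 667 edges.
    """
    n_pairs = n_regions * (n_regions - 1) // 2
    x = sparsity * n_pairs
    return int(np.floor(x + 0.5))


def sparsity_threshold(
    C: ConnectivityMatrix,
    sparsity: float,
    *,
    absolute: bool = False,
) -> BinaryGraph:
    """Binarize a connectivity matrix keeping the strongest ``sparsity`` fraction of edges.

    Edges are ranked by signed correlation (largest positive first) by
    default; ``absolute=True`` ranks by magnitude instead.  Ties at the cut
    value are broken by lexicographic (row, column) order so the result is
    deterministic.
    """
    s = float(sparsity)
    if not (0.0 < s < 1.0):
        raise ValueError(f"sparsity must lie in (0, 1), got {s}")
    R = C.n_regions
    vals = C.values
    iu, ju = np.triu_indices(R, k=1)
    w = np.abs(vals[iu, ju]) if absolute else vals[iu, ju]
    m = edge_count_for_sparsity(R, s)
    # stable sort on (-weight) keeps lexicographic (i, j) order among ties
    order = np.argsort(-w, kind="stable")[:m]
    A = np.zeros((R, R), dtype=np.int8)
    A[iu[order], ju[order]] = 1
    A += A.T
    return BinaryGraph(adjacency=A, region_labels=C.region_labels, sparsity=s)


def clustering_coefficient(G: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its mean.

    For node i with degree k_i and t_i triangles through it the coefficient
    is 2 t_i / (k_i (k_i - 1)); nodes with degree < 2 score 0 and are kept
    in the mean.
    """
    A = G.adjacency.astype(np.float64)
    k = A.sum(axis=0)
    # diag(A^3) counts closed walks of length 3 = 2 * triangles per node
    tri2 = np.einsum("ij,jk,ki->i", A, A, A)  # = 2 * t_i
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c, float(c.mean())


def eigenvector_centrality(
    G: BinaryGraph,
    *,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Principal eigenvector of the adjacency matrix, non-negative, unit L2 norm.

    Power iteration on A + I (the shift leaves eigenvectors unchanged and
    avoids the sign oscillation of bipartite spectra); falls back to a dense
    symmetric eigensolver if the iteration has not converged.  An edgeless
    graph yields the all-zero vector.
    """
    A = G.adjacency.astype(np.float64)
    n = A.shape[0]
    if A.sum() == 0:
        return np.zeros(n)
    M = A + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = M @ x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:  # dense fallback on non-convergence (e.g. tied dominant eigenvalues)
        w, V = np.linalg.eigh(A)
        x = V[:, -1]
    x = np.abs(x)
    x /= np.linalg.norm(x)
    return x


def assortativity(G: BinaryGraph) -> float:
    """Degree assortativity: Pearson correlation of degrees over edge endpoints.

    Each undirected edge contributes both orientations.  Returns NaN (the
    undefined marker) when endpoint degrees have zero variance, e.g. any
    regular graph.  Raises on an edgeless graph.
    """
    edges = G.edge_list()
    if not edges:
        raise ValueError("assortativity is undefined for an edgeless graph")
    k = G.degrees().astype(np.float64)
    i, j = np.array(edges).T
    # both orientations of every edge
    x = np.concatenate([k[i], k[j]])
    y = np.concatenate([k[j], k[i]])
    sx = x.std()
    if sx == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def metric_sweep(
    C: ConnectivityMatrix,
    grid: SparsityGrid | Sequence[float] | None = None,
    *,
    subject_id: str = "",
    session: str = "",
    absolute: bool = False,
) -> pd.DataFrame:
    """Compute all four measures across the sparsity grid.

    Returns a tidy table with one row per (threshold, scope, metric):
    per-region clustering and eigenvector centrality plus global mean
    clustering and assortativity, keyed by subject and session.
    """
    if grid is None:
        grid = SparsityGrid()
    elif not isinstance(grid, SparsityGrid):
        grid = SparsityGrid(tuple(grid))
    rows: list[tuple] = []
    for s in grid:
        G = sparsity_threshold(C, s, absolute=absolute)
        clust, mean_clust = clustering_coefficient(G)
        cent = eigenvector_centrality(G)
        try:
            assort = assortativity(G)
        except ValueError:
            assort = float("nan")
        for r, label in enumerate(G.region_labels):
            rows.append((subject_id, session, s, label, "clustering", clust[r]))
            rows.append(
                (subject_id, session, s, label, "eigenvector_centrality", cent[r])
            )
        rows.append((subject_id, session, s, "global", "mean_clustering", mean_clust))
        rows.append((subject_id, session, s, "global", "assortativity", assort))
    return pd.DataFrame(
        rows, columns=["subject", "session", "threshold", "scope", "metric", "value"]
    )
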