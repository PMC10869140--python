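"""Exact k-nearest-neighbor graphs with deterministic tie-breaking.

Neighbor lists underlie the doublet-neighborhood score (pDNN), the LISI
diagnostic, and label/coordinate transfer. Search is exact (all pairwise
Euclidean distances, computed in row blocks) and distance ties are broken
by ascending row index, so results are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class NeighborGraph:
    """Ordered k-nearest-neighbor lists for a set of cells.

    Attributes
    ----------
    k : neighborhood size.
    indices : (n_cells, k) neighbor row indices, sorted by nondecreasing
        distance; a cell is never its own neighbor.
    distances : (n_cells, k) corresponding Euclidean distances.
    """

    k: int
    indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices and distances must have the same shape")
        if self.indices.shape[1] != self.k:
            raise ValueError("neighbor lists must have exactly k entries per row")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


def _block_knn(query: np.ndarray, reference: np.ndarray, k: int,
               exclude_self: bool, block: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Exact kNN of ``query`` rows among ``reference`` rows.

    Stable argsort on distances breaks ties by ascending reference index.
    When ``exclude_self`` the two matrices must be the same object/shape and
    row i of the query is barred from matching row i of the reference.
    """
    nq = query.shape[0]
    idx = np.empty((nq, k), dtype=np.int64)
    dist = np.empty((nq, k), dtype=float)
    for start in range(0, nq, block):
        stop = min(start + block, nq)
        d = cdist(query[start:stop], reference)
        if exclude_self:
            d[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        idx[start:stop] = order
        dist[start:stop] = np.take_along_axis(d, order, axis=1)
    return idx, dist


def knn_graph(embedding: np.ndarray, k: int = 75) -> NeighborGraph:
    """Exact k-nearest-neighbor graph under Euclidean distance, self excluded.

    Parameters
    ----------
    embedding
        (n_cells, d) coordinates; the documented upstream default is the
        top 30 batch-corrected principal components.
    k
        Neighborhood size (default 75, the size used for pDNN).
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ValueError("embedding must be a 2-D matrix (cells x components)")
    if not np.all(np.isfinite(X)):
        raise ValueError("embedding contains non-finite entries")
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if k < 1:
        raise ValueError("k must be a positive integer")
    idx, dist = _block_knn(X, X, k, exclude_self=True)
    return NeighborGraph(k=k, indices=idx, distances=dist)


def cross_knn(query: np.ndarray, reference: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest *reference* rows for each query row (query rows never match
    each other). Returns (indices, distances)."""
    Q = np.asarray(query, dtype=float)
    R = np.asarray(reference, dtype=float)
    if R.shape[0] == 0:
        raise ValueError("reference is empty")
    if k > R.shape[0]:
        raise ValueError(f"k={k} exceeds reference size ({R.shape[0]})")
    if Q.ndim != 2 or R.ndim != 2 or Q.shape[1] != R.shape[1]:
        raise ValueError("query and reference must be 2-D with matching dimensionality")
    return _block_knn(Q, R, k, exclude_self=False)
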