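"""Doublet-neighborhood density (pDNN).

pDNN combines per-library doublet annotations (cell hashing and a
computational scorer run per library) into one dataset-wide statistic: the
fraction of a cell's k nearest neighbors (default k=75, on the top 30
batch-corrected principal components) flagged as doublets by a chosen
source. Neighborhoods dense in flagged doublets mark clusters of
undetected doublets, e.g. cells co-expressing markers of two lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .neighbors import NeighborGraph, knn_graph

SOURCES = ("hashing", "computational", "union")


@dataclass(frozen=True)
class DoubletFlags:
    """Per-cell doublet annotations from hashing, a computational scorer,
    and their elementwise union."""

    hashing: np.ndarray
    computational: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.hashing, dtype=bool)
        c = np.asarray(self.computational, dtype=bool)
        if h.shape != c.shape or h.ndim != 1:
            raise ValueError("hashing and computational flags must be 1-D and of equal length")
        object.__setattr__(self, "hashing", h)
        object.__setattr__(self, "computational", c)

    @property
    def union(self) -> np.ndarray:
        return self.hashing | self.computational

    def get(self, source: str) -> np.ndarray:
        if source not in SOURCES:
            raise ValueError(f"unknown doublet source {source!r}; expected one of {SOURCES}")
        return getattr(self, source) if source != "union" else self.union

    def __len__(self) -> int:
        return self.hashing.shape[0]


def union_flags(hashing: np.ndarray, computational: np.ndarray) -> np.ndarray:
    """Elementwise OR of two boolean flag vectors of equal length."""
    h = np.asarray(hashing, dtype=bool)
    c = np.asarray(computational, dtype=bool)
    if h.shape != c.shape:
        raise ValueError("flag vectors must have equal length")
    return h | c


def pdnn(graph: NeighborGraph, flags: DoubletFlags | np.ndarray, source: str = "union") -> np.ndarray:
    """Proportion of doublet nearest neighbors per cell.

    For each cell, the number of its k neighbors flagged by ``source``
    divided by k; every score is a multiple of 1/k in [0, 1].
    """
    if isinstance(flags, DoubletFlags):
        flagged = flags.get(source)
    else:
        if source not in SOURCES:
            raise ValueError(f"unknown doublet source {source!r}; expected one of {SOURCES}")
        flagged = np.asarray(flags, dtype=bool)
    if flagged.shape[0] != graph.n_cells:
        raise ValueError("flags must cover every cell in the graph")
    return flagged[graph.indices].mean(axis=1)


class DoubletNeighborhoodScorer(BaseEstimator):
    """Score doublet-neighborhood density on an embedding.

    Parameters
    ----------
    k
        Neighborhood size (default 75).

    Attributes
    ----------
    graph_ : NeighborGraph
        Exact kNN graph built by :meth:`fit`.
    """

    def __init__(self, k: int = 75):
        self.k = k

    def fit(self, embedding: np.ndarray) -> "DoubletNeighborhoodScorer":
        self.graph_ = knn_graph(embedding, k=self.k)
        return self

    def score_flags(self, flags: DoubletFlags) -> pd.DataFrame:
        """pDNN for all three sources, as a table with one column per source."""
        if not hasattr(self, "graph_"):
            raise RuntimeError("fit the scorer before scoring flags")
        return pd.DataFrame({f"pdnn_{s}": pdnn(self.graph_, flags, s) for s in SOURCES})
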