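"""Integration and annotation diagnostics: LISI, region specificity, QC.

LISI (local inverse Simpson's index) measures, per cell, the effective
number of distinct labels (batches, assays, ...) in its kernel-weighted
neighborhood: 1 means the neighborhood is pure (no mixing), N (the number
of labels) means perfect mixing. The region-specificity score ranks
differentially accessible chromatin regions by how concentrated their
accessibility is in one group. QC filtering applies the per-cell UMI /
detected-gene / mitochondrial-fraction thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neighbors import knn_graph

LISI_BISECT_TOL = 1e-5
LISI_MAX_ITER = 100


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cutoffs. Exclusion is strict (<min_umi, <min_genes,
    >max_mito_pct), so boundary values pass. Hashed libraries use a higher
    detected-gene cutoff (400 instead of 250) because their library-size
    distribution is shifted upward."""

    min_umi: float = 1000.0
    min_genes: float = 250.0
    max_mito_pct: float = 20.0

    def __post_init__(self) -> None:
        if self.min_umi < 0 or self.min_genes < 0 or self.max_mito_pct < 0:
            raise ValueError("QC thresholds must be nonnegative")

    @classmethod
    def for_library(cls, hashed: bool = False) -> "QCThresholds":
        return cls(min_genes=400.0) if hashed else cls()


def lisi(embedding: np.ndarray, labels, perplexity: float = 30.0) -> np.ndarray:
    """Per-cell local inverse Simpson's index of ``labels`` on ``embedding``.

    For each cell, Gaussian-kernel weights over its 3 x perplexity nearest
    neighbors are calibrated by bisection (tolerance 1e-5) so that the
    weight entropy equals log(perplexity); the score is ``1 / sum_l p_l**2``
    with ``p_l`` the kernel-weighted frequency of label ``l``. Scores lie in
    [1, N] where N is the number of distinct labels.
    """
    X = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("embedding must be 2-D with at least 2 cells")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one label per cell required")
    if perplexity < 1:
        raise ValueError("perplexity must be >= 1")
    n = X.shape[0]
    k = int(3 * perplexity)
    if k >= n:
        raise ValueError(
            f"perplexity {perplexity} needs {k} neighbors but only {n - 1} cells are available"
        )
    graph = knn_graph(X, k=k)
    codes = pd.Categorical(labels).codes
    n_labels = codes.max() + 1
    log_u = np.log(perplexity)

    scores = np.empty(n)
    for i in range(n):
        d = graph.distances[i]
        beta, beta_min, beta_max = 1.0, -np.inf, np.inf
        p = np.exp(-d * beta)
        for _ in range(LISI_MAX_ITER):
            sum_p = p.sum()
            if sum_p == 0:
                h = 0.0
            else:
                h = np.log(sum_p) + beta * (d * p).sum() / sum_p
            diff = h - log_u
            if abs(diff) < LISI_BISECT_TOL:
                break
            if diff > 0:
                beta_min = beta
                beta = beta * 2 if np.isinf(beta_max) else (beta + beta_max) / 2
            else:
                beta_max = beta
                beta = beta / 2 if np.isinf(beta_min) else (beta + beta_min) / 2
            p = np.exp(-d * beta)
        sum_p = p.sum()
        if sum_p == 0:
            # degenerate neighborhood (all mass collapsed): pure by convention
            scores[i] = 1.0
            continue
        w = p / sum_p
        freq = np.bincount(codes[graph.indices[i]], weights=w, minlength=n_labels)
        scores[i] = 1.0 / np.sum(freq**2)
    # guard against float round-off leaving the theoretical range
    return np.clip(scores, 1.0, float(n_labels))


def dar_specificity(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Region-specificity score: max accessibility across groups over the
    summed accessibility, per region.

    Scores lie in [1/T, 1] for a T-group matrix; all-zero regions are
    undefined and returned as NaN with their mask. The score is invariant
    to rescaling a region by any positive constant.
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2:
        raise ValueError("values must be a regions x groups matrix")
    if np.any(V < 0):
        raise ValueError("accessibility values must be nonnegative")
    totals = V.sum(axis=1)
    undefined = totals == 0
    scores = np.full(V.shape[0], np.nan)
    ok = ~undefined
    scores[ok] = V[ok].max(axis=1) / totals[ok]
    return scores, undefined


def qc_filter(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Boolean keep-mask for a per-cell QC table with columns
    ``umi``, ``genes``, ``mito_pct``, plus a summary of per-rule failures.

    A cell is kept iff umi >= min_umi AND genes >= min_genes AND
    mito_pct <= max_mito_pct (boundary values pass).
    """
    thresholds = thresholds or QCThresholds()
    missing = [c for c in ("umi", "genes", "mito_pct") if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing required column(s): {missing}")
    fail_umi = metrics["umi"].to_numpy() < thresholds.min_umi
    fail_genes = metrics["genes"].to_numpy() < thresholds.min_genes
    fail_mito = metrics["mito_pct"].to_numpy() > thresholds.max_mito_pct
    keep = ~(fail_umi | fail_genes | fail_mito)
    summary = pd.DataFrame(
        {
            "rule": ["umi", "genes", "mito_pct", "kept", "dropped"],
            "count": [
                int(fail_umi.sum()),
                int(fail_genes.sum()),
                int(fail_mito.sum()),
                int(keep.sum()),
                int((~keep).sum()),
            ],
        }
    )
    return keep, summary
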