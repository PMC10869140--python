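"""KNN label and 2-D layout transfer from reference to query cells.

Once reference and query cells share a corrected joint embedding, each
query cell receives (a) the plurality label of its k nearest reference
cells (default k=5), with annotation confidence defined as the winning
vote fraction, and (b) 2-D layout coordinates as the unweighted mean of
those neighbors' layouts. Query cells are never used as neighbors for
other query cells. k can be tuned with a stratified 70/30 hold-out on the
reference. A three-fold validation accompanies the transfer: neighborhood
preservation (label stability when the neighborhood grows from k to 3k),
conservation of marker-gene pseudo-profiles, and per-cluster confidence
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import train_test_split

from .neighbors import cross_knn


@dataclass(frozen=True)
class TransferResult:
    """Per-query-cell prediction: label, confidence (a multiple of 1/k),
    and transferred 2-D layout coordinates."""

    cell_ids: list[str]
    labels: np.ndarray
    confidence: np.ndarray
    layout: np.ndarray | None = None
    k: int = 5

    def __post_init__(self) -> None:
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValueError("confidence must lie in [0, 1]")
        quantized = np.round(self.confidence * self.k) / self.k
        if not np.allclose(quantized, self.confidence, atol=1e-12):
            raise ValueError("confidence must be a multiple of 1/k")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "predicted_label": self.labels,
                "confidence": self.confidence,
            }
        )
        if self.layout is not None:
            df["layout_1"] = self.layout[:, 0]
            df["layout_2"] = self.layout[:, 1]
        return df


@dataclass(frozen=True)
class KSelectionReport:
    candidates: tuple[int, ...]
    accuracies: tuple[float, ...]
    chosen_k: int
    train_fraction: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.candidates,
                "holdout_accuracy": self.accuracies,
                "chosen": [k == self.chosen_k for k in self.candidates],
            }
        )


def _vote(labels_k: np.ndarray, dist_k: np.ndarray) -> tuple[object, float]:
    """Plurality vote over one neighbor list.

    Ties on vote count are broken by the smaller summed distance of the tied
    labels' voters, then lexicographically by label.
    """
    uniq, counts = np.unique(labels_k, return_counts=True)
    top = counts.max()
    tied = uniq[counts == top]
    if len(tied) == 1:
        winner = tied[0]
    else:
        sums = {lab: dist_k[labels_k == lab].sum() for lab in tied}
        winner = min(sorted(sums), key=lambda lab: (sums[lab], str(lab)))
    return winner, top / labels_k.size


class KNNLabelTransfer(BaseEstimator):
    """k-nearest-neighbor classifier with vote-fraction confidence.

    Parameters
    ----------
    k
        Neighborhood size (default 5).

    Attributes
    ----------
    X_ : reference embedding coordinates.
    y_ : reference labels.
    classes_ : sorted unique reference labels.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X: np.ndarray, y) -> "KNNLabelTransfer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("reference is empty")
        if X.shape[0] != y.shape[0]:
            raise ValueError("one label per reference cell required")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds reference size ({X.shape[0]})")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def predict_with_confidence(self, X_query: np.ndarray, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        k = k or self.k
        idx, dist = cross_knn(np.asarray(X_query, dtype=float), self.X_, k)
        labels = np.empty(idx.shape[0], dtype=self.y_.dtype)
        conf = np.empty(idx.shape[0])
        for i in range(idx.shape[0]):
            labels[i], conf[i] = _vote(self.y_[idx[i]], dist[i])
        return labels, conf

    def predict(self, X_query: np.ndarray) -> np.ndarray:
        return self.predict_with_confidence(X_query)[0]

    def score(self, X_query: np.ndarray, y_true) -> float:
        return float(np.mean(self.predict(X_query) == np.asarray(y_true)))


class KNNCoordinateTransfer(BaseEstimator):
    """k-nearest-neighbor regression of 2-D layout coordinates: the
    unweighted arithmetic mean of the k nearest reference cells' layouts."""

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X: np.ndarray, layout: np.ndarray) -> "KNNCoordinateTransfer":
        X = np.asarray(X, dtype=float)
        layout = np.asarray(layout, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("reference is empty")
        if layout.ndim != 2 or layout.shape[1] != 2:
            raise ValueError("layout must have exactly 2 components")
        if layout.shape[0] != X.shape[0]:
            raise ValueError("one layout row per reference cell required")
        self.X_ = X
        self.layout_ = layout
        return self

    def predict(self, X_query: np.ndarray) -> np.ndarray:
        idx, _ = cross_knn(np.asarray(X_query, dtype=float), self.X_, self.k)
        return self.layout_[idx].mean(axis=1)


def transfer_labels(
    X_ref: np.ndarray, y_ref, X_query: np.ndarray, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Thin wrapper: predicted labels and confidences for the query rows."""
    return KNNLabelTransfer(k=k).fit(X_ref, y_ref).predict_with_confidence(X_query)


def transfer_coordinates(
    X_ref: np.ndarray, layout_ref: np.ndarray, X_query: np.ndarray, k: int = 5
) -> np.ndarray:
    """Thin wrapper: neighbor-mean 2-D layout for the query rows."""
    return KNNCoordinateTransfer(k=k).fit(X_ref, layout_ref).predict(X_query)


def tune_k(
    X_ref: np.ndarray,
    y_ref,
    candidates: list[int],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> KSelectionReport:
    """Choose k by stratified hold-out accuracy on the reference.

    A random stratified split keeps ``train_fraction`` (default 70%) of the
    cells for training and classifies the remainder with each candidate k;
    the chosen k is the smallest candidate attaining the maximum accuracy.
    Labels with fewer than 2 cells cannot be stratified and are excluded
    with a warning.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    X = np.asarray(X_ref, dtype=float)
    y = np.asarray(y_ref)
    uniq, counts = np.unique(y, return_counts=True)
    rare = uniq[counts < 2]
    if rare.size:
        warnings.warn(f"labels with <2 cells excluded from stratification: {list(rare)}")
        keep = ~np.isin(y, rare)
        X, y = X[keep], y[keep]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    accs = []
    for k in candidates:
        if k > X_tr.shape[0]:
            raise ValueError(f"candidate k={k} exceeds training-set size {X_tr.shape[0]}")
        accs.append(KNNLabelTransfer(k=k).fit(X_tr, y_tr).score(X_te, y_te))
    best = max(accs)
    chosen = min(k for k, a in zip(candidates, accs) if a == best)
    return KSelectionReport(
        candidates=tuple(candidates),
        accuracies=tuple(accs),
        chosen_k=chosen,
        train_fraction=train_fraction,
        seed=seed,
    )


def validate_transfer(
    X_ref: np.ndarray,
    y_ref,
    expr_ref: np.ndarray,
    X_query: np.ndarray,
    expr_query: np.ndarray,
    gene_ids: list[str],
    result: TransferResult,
    markers: dict[str, list[str]],
    k: int = 5,
) -> pd.DataFrame:
    """Three-fold validation of a label transfer.

    Per predicted cluster: (1) neighborhood preservation — the fraction of
    its query cells whose plurality label recomputed with 3k reference
    neighbors equals the transferred label; (2) marker conservation — the
    Pearson correlation between the mean normalized expression of the
    cluster's marker genes in its query cells and in the reference cells of
    that label; (3) confidence summaries (mean and quartiles) plus query
    cell counts. Clusters without query cells are reported with null
    metrics.
    """
    y_ref = np.asarray(y_ref)
    expr_ref = np.asarray(expr_ref, dtype=float)
    expr_query = np.asarray(expr_query, dtype=float)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    clf = KNNLabelTransfer(k=k).fit(np.asarray(X_ref, float), y_ref)
    enlarged, _ = clf.predict_with_confidence(
        np.asarray(X_query, float), k=min(3 * k, clf.X_.shape[0])
    )
    predicted = np.asarray(result.labels)

    rows = []
    for label in np.unique(y_ref):
        in_cluster = predicted == label
        n_query = int(in_cluster.sum())
        genes = [g for g in markers.get(str(label), markers.get(label, [])) if g in gene_index]
        row: dict[str, object] = {"cluster": label, "n_query_cells": n_query}
        if n_query == 0:
            row.update(
                neighborhood_preservation=np.nan, marker_conservation=np.nan,
                confidence_mean=np.nan, confidence_q25=np.nan, confidence_q75=np.nan,
            )
            rows.append(row)
            continue
        row["neighborhood_preservation"] = float(np.mean(enlarged[in_cluster] == label))
        if len(genes) >= 2:
            cols = [gene_index[g] for g in genes]
            prof_q = expr_query[np.ix_(in_cluster, cols)].mean(axis=0)
            prof_r = expr_ref[np.ix_(y_ref == label, cols)].mean(axis=0)
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(prof_q, prof_r)[0, 1]
            row["marker_conservation"] = float(corr)
        else:
            row["marker_conservation"] = np.nan
        conf = result.confidence[in_cluster]
        row["confidence_mean"] = float(conf.mean())
        row["confidence_q25"] = float(np.quantile(conf, 0.25))
        row["confidence_q75"] = float(np.quantile(conf, 0.75))
        rows.append(row)
    return pd.DataFrame(rows)
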