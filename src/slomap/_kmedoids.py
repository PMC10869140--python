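"""Partitioning Around Medoids (PAM) with deterministic BUILD initialization.

Small-scale, exact implementation used by the hashtag demultiplexer.
Deterministic: BUILD picks the greedy cost-minimizing point at each step
(ties broken by lowest index) and SWAP applies the single best improving
swap until none remains, so repeated runs are bit-identical.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def pam(X: np.ndarray, n_clusters: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Cluster rows of ``X`` into ``n_clusters`` groups around medoids.

    Parameters
    ----------
    X
        Data matrix (observations x features).
    n_clusters
        Number of clusters; must not exceed the number of observations.

    Returns
    -------
    labels : ndarray of shape (n,)
        Cluster index per observation.
    medoids : ndarray of shape (n_clusters,)
        Row indices of the medoid of each cluster.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds number of observations ({n})")
    D = cdist(X, X)

    # BUILD: first medoid minimizes total distance; each next greedily
    # minimizes the assignment cost given the medoids chosen so far.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < n_clusters:
        # gain of adding candidate j: sum of max(nearest - D[:, j], 0)
        gain = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        j = int(np.argmax(gain))
        medoids.append(j)
        nearest = np.minimum(nearest, D[:, j])

    medoids = np.array(medoids, dtype=int)
    cost = D[:, medoids].min(axis=1).sum()

    # SWAP: steepest-descent over all (medoid, non-medoid) exchanges.
    for _ in range(max_iter):
        best = (0.0, None)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        for mi in range(n_clusters):
            trial = medoids.copy()
            for h in np.flatnonzero(~is_medoid):
                trial[mi] = h
                c = D[:, trial].min(axis=1).sum()
                if cost - c > best[0] + 1e-12:
                    best = (cost - c, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        cost -= best[0]

    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids
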