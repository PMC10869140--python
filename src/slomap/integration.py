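"""Assay-aware joint embedding of reference and query cells.

The reference-mapping workflow embeds reference and query datasets (possibly
from different assays: scRNA-seq, Multiome gene expression, CITE-seq RNA,
scATAC-seq gene activities) into one corrected low-dimensional space:

1. log-normalize counts per cell (counts / cell total x 10,000, then log1p),
2. rank highly variable genes (HVG) separately for every cohort x technology
   group and intersect the per-group top lists, so that only genes variable
   in *every* assay drive the embedding,
3. z-score the shared HVG on the concatenated matrix and run PCA (default
   30 components),
4. correct the scores for batch (assay tag by default, optionally also the
   GEM well) — either by delegating to an external implementation of the
   iterative soft-clustering correction ("plugin") or by per-batch mean
   centering ("centering").

Reference and query are re-scaled and re-embedded *together* (joint
re-embedding, not projection): reference coordinates are not frozen, which
differs from projection-style reference mappers.

Datasets are AnnData objects: raw counts in ``layers["counts"]``, the
normalized layer in ``X``, per-cell metadata (``assay``, ``batch``,
``cohort``, optional ``label``/``layout_1``/``layout_2``) in ``obs``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

DEFAULT_SCALE_FACTOR = 10_000.0
DEFAULT_CLIP = 10.0
DEFAULT_N_COMPONENTS = 30
HVG_SPAN = 0.3


@dataclass(frozen=True)
class NormalizationParams:
    scale_factor: float = DEFAULT_SCALE_FACTOR

    def __post_init__(self) -> None:
        if not self.scale_factor > 0:
            raise ValueError("scale_factor must be positive")


@dataclass(frozen=True)
class HVGSelection:
    """Per-group ranked HVG lists and their mean-rank-ordered intersection."""

    groups: dict[str, list[str]]
    n_per_group: int
    intersection: list[str]

    def report(self) -> pd.DataFrame:
        genes = sorted({g for lst in self.groups.values() for g in lst})
        rows = []
        for g in genes:
            row: dict[str, object] = {"gene": g}
            for tag, lst in self.groups.items():
                row[f"rank_{tag}"] = lst.index(g) + 1 if g in lst else np.nan
            row["in_intersection"] = g in self.intersection
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PCAModel:
    """Fitted scaling + PCA: per-gene center/scale, clip value, orthonormal
    loadings with the sign fixed so each component's largest-magnitude
    loading is positive."""

    genes: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    clip: float
    loadings: np.ndarray
    explained_variance: np.ndarray


@dataclass(frozen=True)
class JointEmbedding:
    """Batch-corrected joint coordinates for reference and query cells."""

    cell_ids: list[str]
    coords: np.ndarray
    origin: np.ndarray
    assay: np.ndarray
    batch: np.ndarray
    hvg: HVGSelection | None = None
    pca: PCAModel | None = None

    def __post_init__(self) -> None:
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("one coordinate row per cell required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("joint embedding contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        d = self.coords.shape[1]
        df = pd.DataFrame(self.coords, columns=[f"comp_{i + 1}" for i in range(d)])
        df.insert(0, "cell_id", self.cell_ids)
        df.insert(1, "origin", self.origin)
        df.insert(2, "assay", self.assay)
        df.insert(3, "batch", self.batch)
        return df

    def subset(self, mask: np.ndarray) -> "JointEmbedding":
        return JointEmbedding(
            cell_ids=[c for c, m in zip(self.cell_ids, mask) if m],
            coords=self.coords[mask],
            origin=self.origin[mask],
            assay=self.assay[mask],
            batch=self.batch[mask],
            hvg=self.hvg,
            pca=self.pca,
        )


def _dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def lognormalize(counts, params: NormalizationParams | None = None) -> np.ndarray:
    """Per-cell log-normalization: ``log1p(count / cell_total * scale_factor)``.

    The identity ``sum_g expm1(y[c, g]) == scale_factor`` holds exactly for
    every cell with a positive total. Cells with zero total are returned as
    all-zero rows with a warning; dropping them is a separate, explicit QC
    step.
    """
    params = params or NormalizationParams()
    X = _dense(counts)
    if np.any(X < 0):
        raise ValueError("counts must be nonnegative")
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) with zero total counts kept as all-zero rows")
    safe = np.where(zero, 1.0, totals)
    return np.log1p(X / safe[:, None] * params.scale_factor)


def lognormalize_adata(adata: ad.AnnData, scale_factor: float = DEFAULT_SCALE_FACTOR) -> ad.AnnData:
    """Store raw counts in ``layers['counts']`` and the normalized layer in ``X``."""
    if "counts" not in adata.layers:
        adata.layers["counts"] = adata.X.copy()
    adata.X = lognormalize(adata.layers["counts"], NormalizationParams(scale_factor))
    return adata


def standardized_variance(X: np.ndarray) -> np.ndarray:
    """Per-gene standardized variance (vst-style HVG statistic).

    The expected standard deviation of each gene given its mean comes from
    a LOWESS fit (span 0.3) of log10(variance) on log10(mean) over genes
    with positive variance; values standardized with that expectation are
    clipped at sqrt(n_cells) before the variance is recomputed. Constant
    genes score 0 and therefore rank last.
    """
    X = _dense(X)
    n = X.shape[0]
    if n < 2:
        raise ValueError("standardized variance needs at least 2 cells")
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    out = np.zeros(X.shape[1])
    usable = (var > 0) & (mean > 0)
    if not usable.any():
        return out
    lx = np.log10(mean[usable])
    ly = np.log10(var[usable])
    if np.unique(lx).size < 3:
        expected_var = np.full(usable.sum(), 10 ** ly.mean())
    else:
        fit = lowess(ly, lx, frac=HVG_SPAN, return_sorted=True)
        expected_var = 10 ** np.interp(lx, fit[:, 0], fit[:, 1])
    sd = np.sqrt(expected_var)
    clip = np.sqrt(n)
    z = (X[:, usable] - mean[usable]) / sd
    np.clip(z, -clip, clip, out=z)
    out[usable] = (z**2).sum(axis=0) / (n - 1)
    return out


def find_hvg(data, n: int, gene_ids: list[str] | None = None) -> list[str]:
    """Rank genes by standardized variance and return the top ``n``.

    ``data`` may be a matrix (cells x genes, with ``gene_ids``) or an
    AnnData whose ``X`` holds the normalized layer. Ties and ranking are
    deterministic (stable sort); if ``n`` exceeds the gene count the full
    ranking is returned with a warning.
    """
    if isinstance(data, ad.AnnData):
        X = _dense(data.X)
        gene_ids = list(data.var_names)
    else:
        X = _dense(data)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(X.shape[1])]
    sv = standardized_variance(X)
    if n > len(gene_ids):
        warnings.warn(f"requested {n} HVG but only {len(gene_ids)} genes; truncating")
        n = len(gene_ids)
    order = np.argsort(-sv, kind="stable")[:n]
    return [gene_ids[i] for i in order]


def shared_hvg(groups: list[tuple[str, list[str]]], n_per_group: int | None = None) -> HVGSelection:
    """Intersect the per-group top-``n_per_group`` gene lists.

    The intersection is ordered by mean rank across groups (1-based ranks;
    stable tie-break by order in the first group). An empty intersection is
    an error asking for a larger ``n_per_group``.
    """
    if len(groups) < 2:
        raise ValueError("shared_hvg needs at least two groups")
    if n_per_group is None:
        n_per_group = 5000 if len(groups) >= 3 else 3000
    tops = {tag: lst[:n_per_group] for tag, lst in groups}
    ranks = {tag: {g: i + 1 for i, g in enumerate(lst)} for tag, lst in tops.items()}
    first_tag = groups[0][0]
    inter = [g for g in tops[first_tag] if all(g in ranks[t] for t in tops)]
    if not inter:
        raise ValueError(
            "the per-group HVG lists share no genes; raise n_per_group or check that "
            "datasets are on a comparable feature space"
        )
    mean_rank = {g: np.mean([ranks[t][g] for t in tops]) for g in inter}
    inter.sort(key=lambda g: mean_rank[g])  # stable: preserves first-group order on ties
    return HVGSelection(groups={t: list(lst) for t, lst in tops.items()},
                        n_per_group=n_per_group, intersection=inter)


def scale_features(
    normalized: np.ndarray,
    gene_ids: list[str],
    genes: list[str] | HVGSelection,
    clip: float = DEFAULT_CLIP,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score the selected genes, clipping at ``+/-clip`` standard deviations.

    Constant genes become all-zero columns. Returns the scaled matrix and
    the (center, scale) vectors for the selected genes.
    """
    if isinstance(genes, HVGSelection):
        genes = genes.intersection
    index = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise ValueError(f"genes not present in the matrix: {missing[:5]}")
    cols = [index[g] for g in genes]
    X = _dense(normalized)[:, cols]
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    safe = np.where(sd == 0, 1.0, sd)
    Z = (X - center) / safe
    Z[:, sd == 0] = 0.0
    np.clip(Z, -clip, clip, out=Z)
    return Z, (center, sd)


def fit_pca(
    scaled: np.ndarray,
    d: int = DEFAULT_N_COMPONENTS,
    genes: list[str] | None = None,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    clip: float = DEFAULT_CLIP,
    random_state: int = 0,
) -> tuple[np.ndarray, PCAModel]:
    """PCA of the scaled matrix; component signs fixed so the
    largest-magnitude loading of each component is positive."""
    X = np.asarray(scaled, dtype=float)
    max_d = min(X.shape)
    if d > max_d:
        raise ValueError(f"d={d} exceeds min(cells, genes)={max_d}")
    solver = "full" if max_d <= 2000 else "randomized"
    pca = PCA(n_components=d, svd_solver=solver, random_state=random_state)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # genes x d
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    loadings *= flip[None, :]
    scores = scores * flip[None, :]
    n_genes = X.shape[1]
    model = PCAModel(
        genes=tuple(genes) if genes is not None else tuple(str(i) for i in range(n_genes)),
        center=center if center is not None else np.zeros(n_genes),
        scale=scale if scale is not None else np.ones(n_genes),
        clip=clip,
        loadings=loadings,
        explained_variance=pca.explained_variance_,
    )
    return scores, model


def correct_batches(scores: np.ndarray, batches, method: str = "centering", **plugin_options) -> np.ndarray:
    """Remove batch structure from PCA scores.

    ``method="plugin"`` delegates to an external implementation of the
    published iterative soft-clustering correction through a matrix-in /
    matrix-out contract (extra keyword arguments are passed through
    opaquely); ``method="centering"`` subtracts each batch's component-wise
    mean and adds back the global mean. Both preserve shape and row order.
    """
    X = np.asarray(scores, dtype=float)
    batches = np.asarray(batches)
    if batches.shape[0] != X.shape[0]:
        raise ValueError("one batch label per row required")
    if method == "centering":
        out = X.copy()
        global_mean = X.mean(axis=0)
        for b in np.unique(batches):
            mask = batches == b
            out[mask] += global_mean - X[mask].mean(axis=0)
        return out
    if method == "plugin":
        try:
            import harmonypy  # type: ignore
        except ImportError as err:
            raise RuntimeError(
                "the iterative batch-correction plugin requires the 'harmonypy' package, "
                "which is not installed; use method='centering' as a fallback"
            ) from err
        meta = pd.DataFrame({"batch": batches})
        res = harmonypy.run_harmony(X, meta, "batch", **plugin_options)
        return np.asarray(res.Z_corr.T, dtype=float)
    raise ValueError(f"unknown correction method {method!r}; expected 'plugin' or 'centering'")


def _validate_dataset(adata: ad.AnnData, origin: str) -> None:
    for key in ("assay", "batch", "cohort"):
        if key not in adata.obs:
            raise ValueError(f"{origin} dataset missing obs column {key!r}")
        if adata.obs[key].astype(str).str.len().eq(0).any():
            raise ValueError(f"{origin} dataset has empty {key!r} values")
    if adata.obs_names.duplicated().any():
        raise ValueError(f"{origin} dataset has duplicate cell ids")


class JointIntegrator(BaseEstimator):
    """Fit the joint normalization -> HVG -> PCA -> batch-correction pipeline.

    Parameters
    ----------
    n_per_group
        Top HVG per cohort x technology group; default 5,000 when three or
        more groups are present, 3,000 otherwise.
    n_components
        Embedding dimensionality (default 30).
    batch_key
        obs column(s) defining batches for correction; default ``"assay"``
        (optionally ``["assay", "batch"]`` to also treat GEM wells as
        batches).
    method
        ``"centering"`` (default) or ``"plugin"``.

    Attributes
    ----------
    embedding_ : JointEmbedding
    hvg_ : HVGSelection
    pca_ : PCAModel
    """

    def __init__(
        self,
        n_per_group: int | None = None,
        n_components: int = DEFAULT_N_COMPONENTS,
        batch_key: str | list[str] = "assay",
        method: str = "centering",
        scale_factor: float = DEFAULT_SCALE_FACTOR,
        clip: float = DEFAULT_CLIP,
        random_state: int = 0,
    ):
        self.n_per_group = n_per_group
        self.n_components = n_components
        self.batch_key = batch_key
        self.method = method
        self.scale_factor = scale_factor
        self.clip = clip
        self.random_state = random_state

    def fit(self, reference: list[ad.AnnData], query: list[ad.AnnData] = ()) -> "JointIntegrator":
        reference = list(reference)
        query = list(query)
        if not reference:
            raise ValueError("at least one reference dataset is required")
        for a in reference:
            _validate_dataset(a, "reference")
        for a in query:
            _validate_dataset(a, "query")

        shared = list(reference[0].var_names)
        for a in reference[1:] + query:
            present = set(a.var_names)
            shared = [g for g in shared if g in present]
        if not shared:
            raise ValueError(
                "no genes are shared across the input datasets; the per-group HVG "
                "intersection would be empty"
            )

        parts, origins = [], []
        for a in reference:
            parts.append(a[:, shared].copy())
            origins.extend(["reference"] * a.n_obs)
        for a in query:
            parts.append(a[:, shared].copy())
            origins.extend(["query"] * a.n_obs)
        joint = ad.concat(parts, join="inner", merge="same") if len(parts) > 1 else parts[0]
        joint.obs["origin"] = origins
        counts = _dense(joint.layers["counts"] if "counts" in joint.layers else joint.X)
        normalized = lognormalize(counts, NormalizationParams(self.scale_factor))
        logger.info("joint matrix: %d cells x %d shared genes", *normalized.shape)

        group_tags = (
            joint.obs["cohort"].astype(str) + ":" + joint.obs["assay"].astype(str)
        ).to_numpy()
        unique_groups = list(dict.fromkeys(group_tags))
        n_per_group = self.n_per_group or (5000 if len(unique_groups) >= 3 else 3000)
        if len(unique_groups) == 1:
            ranked = find_hvg(normalized, min(n_per_group, len(shared)), shared)
            self.hvg_ = HVGSelection(
                groups={unique_groups[0]: ranked}, n_per_group=n_per_group, intersection=ranked
            )
        else:
            per_group = [
                (tag, find_hvg(normalized[group_tags == tag], len(shared), shared))
                for tag in unique_groups
            ]
            self.hvg_ = shared_hvg(per_group, n_per_group)
        logger.info(
            "HVG: %d groups, top %d each, intersection of %d genes",
            len(unique_groups), n_per_group, len(self.hvg_.intersection),
        )

        scaled, (center, scale) = scale_features(normalized, shared, self.hvg_, clip=self.clip)
        d = min(self.n_components, min(scaled.shape))
        scores, self.pca_ = fit_pca(
            scaled, d=d, genes=self.hvg_.intersection, center=center, scale=scale,
            clip=self.clip, random_state=self.random_state,
        )

        keys = [self.batch_key] if isinstance(self.batch_key, str) else list(self.batch_key)
        batch_labels = joint.obs[keys[0]].astype(str)
        for key in keys[1:]:
            batch_labels = batch_labels + "|" + joint.obs[key].astype(str)
        corrected = correct_batches(scores, batch_labels.to_numpy(), method=self.method)

        self.embedding_ = JointEmbedding(
            cell_ids=list(joint.obs_names),
            coords=corrected,
            origin=np.array(origins),
            assay=joint.obs["assay"].astype(str).to_numpy(),
            batch=batch_labels.to_numpy(),
            hvg=self.hvg_,
            pca=self.pca_,
        )
        return self

    def fit_transform(self, reference: list[ad.AnnData], query: list[ad.AnnData] = ()) -> JointEmbedding:
        return self.fit(reference, query).embedding_


def integrate_joint(
    reference: list[ad.AnnData],
    query: list[ad.AnnData] = (),
    **params,
) -> JointEmbedding:
    """Thin functional wrapper around :class:`JointIntegrator`."""
    return JointIntegrator(**params).fit_transform(reference, query)
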