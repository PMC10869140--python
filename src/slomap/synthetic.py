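"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators, both pure functions of their configuration and seed:

``simulate_multimodal`` emulates the statistical structure the
reference-mapping workflow assumes — the same cell types observed under
assay- and batch-specific distortions. Cluster means sit on a scaled
simplex in a latent space (separation expressed in units of the
within-cluster standard deviation); per-cell latent positions are Gaussian
around their cluster mean; gene means are the exponential of a linear map
of the latent position; counts are negative binomial with gene-wise
multiplicative assay and batch factors (log-normal) and Bernoulli dropout.
The true 2-D layout is a fixed linear projection of the latent space, so
coordinate-transfer error has an exact oracle.

``simulate_hto`` emulates a cell-hashing library: each singlet carries one
hashtag with negative-binomial signal counts and background counts
elsewhere; planted doublets are sums of two independent singlet profiles
with distinct hashtags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad

from .hashing import HashtagCounts

REFERENCE_ASSAY = "scRNA-seq"
QUERY_ASSAY = "Multiome"


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a multimodal simulation.

    separation is the pairwise distance between latent cluster means in
    units of the within-cluster standard deviation (which is 1);
    assay_shift / batch_shift are the standard deviations of gene-wise
    multiplicative log-normal factors; dispersion is the negative-binomial
    size parameter (smaller = noisier); dropout is the probability of
    zeroing any observed count.
    """

    seed: int = 0
    n_cell_types: int = 3
    cells_per_type: int = 100
    n_genes: int = 500
    latent_dim: int = 10
    separation: float = 3.0
    assay_shift: float = 0.5
    batch_shift: float = 0.3
    dispersion: float = 2.0
    dropout: float = 0.1
    n_batches_per_assay: int = 2

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.cells_per_type < 1 or self.n_genes < 1:
            raise ValueError("cell types, cells per type, and genes must all be positive")
        if self.n_cell_types > self.latent_dim:
            raise ValueError("latent_dim must be at least n_cell_types")
        if min(self.separation, self.assay_shift, self.batch_shift, self.dropout) < 0:
            raise ValueError("magnitudes must be nonnegative")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth: one row per cell (label, origin, batch, layout,
    doublet flag / hashtag where applicable) plus latent positions."""

    table: pd.DataFrame
    latent: np.ndarray | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with the (mean, size) parameterization."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def _assay_block(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    means_latent: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    layout_proj: np.ndarray,
    assay: str,
    cohort: str,
    assay_factor: np.ndarray,
    prefix: str,
) -> tuple[ad.AnnData, pd.DataFrame, np.ndarray]:
    n_cells = cfg.n_cell_types * cfg.cells_per_type
    labels = np.repeat([f"type_{t}" for t in range(cfg.n_cell_types)], cfg.cells_per_type)
    latent = means_latent[np.repeat(np.arange(cfg.n_cell_types), cfg.cells_per_type)]
    latent = latent + rng.standard_normal((n_cells, cfg.latent_dim))
    log_mean = b[None, :] + latent @ W.T
    mean = np.exp(np.clip(log_mean, -12.0, 9.0))

    batches = np.array(
        [f"{prefix}_gem{i % cfg.n_batches_per_assay}" for i in range(n_cells)]
    )
    batch_factors = {
        bt: np.exp(cfg.batch_shift * rng.standard_normal(cfg.n_genes))
        for bt in sorted(set(batches))
    }
    for bt, f in batch_factors.items():
        mean[batches == bt] *= f[None, :]
    mean *= assay_factor[None, :]

    counts = _nb_draw(rng, mean, cfg.dispersion)
    if cfg.dropout > 0:
        counts[rng.random(counts.shape) < cfg.dropout] = 0

    layout = latent @ layout_proj.T
    cell_ids = [f"{prefix}_cell{i}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "assay": assay,
            "batch": batches,
            "cohort": cohort,
            "label": labels,
            "layout_1": layout[:, 0],
            "layout_2": layout[:, 1],
        },
        index=cell_ids,
    )
    adata = ad.AnnData(
        X=counts.astype(float),
        obs=obs,
        var=pd.DataFrame(index=[f"gene_{g}" for g in range(cfg.n_genes)]),
        layers={"counts": counts},
    )
    truth = obs.reset_index(names="cell_id")
    truth.insert(1, "origin", "reference" if cohort == "reference" else "query")
    truth["doublet"] = False
    return adata, truth, latent


def simulate_multimodal(
    config: SimulationConfig,
) -> tuple[list[ad.AnnData], list[ad.AnnData], GroundTruth]:
    """Simulate a labeled reference assay and an unlabeled-at-transfer query
    assay sharing the same cell types. Bit-reproducible for a fixed config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # shared generative model: cluster means are simplex vertices scaled by
    # the separation parameter (within-cluster sd is 1 in every direction)
    means_latent = np.zeros((cfg.n_cell_types, cfg.latent_dim))
    for t in range(cfg.n_cell_types):
        means_latent[t, t] = cfg.separation
    # gene loadings sized so between-type marker log-fold changes are ~1-2,
    # the scale seen for discriminative markers in droplet scRNA-seq
    W = 0.5 * rng.standard_normal((cfg.n_genes, cfg.latent_dim))
    b = rng.uniform(np.log(0.2), np.log(3.0), size=cfg.n_genes)
    layout_proj = rng.standard_normal((2, cfg.latent_dim)) / np.sqrt(cfg.latent_dim)

    ref_factor = np.ones(cfg.n_genes)
    query_factor = np.exp(cfg.assay_shift * rng.standard_normal(cfg.n_genes))

    ref, truth_ref, latent_ref = _assay_block(
        rng, cfg, means_latent, W, b, layout_proj,
        REFERENCE_ASSAY, "reference", ref_factor, "ref",
    )
    query, truth_query, latent_query = _assay_block(
        rng, cfg, means_latent, W, b, layout_proj,
        QUERY_ASSAY, "query", query_factor, "query",
    )
    truth = GroundTruth(
        table=pd.concat([truth_ref, truth_query], ignore_index=True),
        latent=np.vstack([latent_ref, latent_query]),
    )
    return [ref], [query], truth


def simulate_hto(
    n_cells: int = 300,
    n_hashtags: int = 3,
    doublet_rate: float = 0.0,
    mu_signal: float = 1000.0,
    mu_background: float = 5.0,
    dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[HashtagCounts, GroundTruth]:
    """Simulate a cell-hashing count matrix with planted doublets.

    Each singlet is assigned one hashtag uniformly and draws
    NB(mu_signal) counts on it and NB(mu_background) elsewhere; each cell
    is independently a doublet with probability ``doublet_rate``, in which
    case its profile is the sum of two independent singlet profiles with
    distinct hashtags.
    """
    if not 0 <= doublet_rate <= 1:
        raise ValueError("doublet_rate must lie in [0, 1]")
    if not mu_signal > mu_background >= 0:
        raise ValueError("mu_signal must exceed mu_background, and mu_background be nonnegative")
    if n_cells < 1 or n_hashtags < 1:
        raise ValueError("n_cells and n_hashtags must be positive")
    rng = np.random.default_rng(seed)

    def singlet_profile(ht: int) -> np.ndarray:
        mean = np.full(n_hashtags, mu_background)
        mean[ht] = mu_signal
        return _nb_draw(rng, mean, dispersion)

    counts = np.zeros((n_cells, n_hashtags), dtype=np.int64)
    is_doublet = rng.random(n_cells) < doublet_rate
    first = rng.integers(0, n_hashtags, size=n_cells)
    hashtags: list[str] = []
    ht_ids = [f"HTO_{h}" for h in range(n_hashtags)]
    for i in range(n_cells):
        if is_doublet[i] and n_hashtags >= 2:
            second = int(rng.choice([h for h in range(n_hashtags) if h != first[i]]))
            counts[i] = singlet_profile(int(first[i])) + singlet_profile(second)
            hashtags.append(";".join(sorted([ht_ids[first[i]], ht_ids[second]])))
        else:
            is_doublet[i] = False
            counts[i] = singlet_profile(int(first[i]))
            hashtags.append(ht_ids[first[i]])

    hto = HashtagCounts(
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
        hashtag_ids=ht_ids,
        counts=counts,
    )
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "cell_id": hto.cell_ids,
                "true_hashtag": hashtags,
                "doublet": is_doublet,
            }
        )
    )
    return hto, truth
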