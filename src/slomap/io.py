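"""Reading and writing datasets and result tables.

Count matrices travel as Matrix-Market triplets with barcode and feature
sidecars (the droplet-sequencing convention: the .mtx is features x
barcodes, 1-based indices; in memory everything is cells x genes and
0-based — this module is the boundary) or as dense delimited tables with
cells as rows. Result tables are written with a deterministic column
order, together with a run manifest recording the package version, a
configuration hash, and every seed used, so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import io as spio
from scipy import sparse

from . import __version__
from .hashing import HashtagCounts

MATRIX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
FEATURES_FILE = "features.tsv"
METADATA_FILE = "metadata.csv"
METADATA_COLUMNS = ("assay", "batch", "cohort")


def _read_sidecar(path: Path) -> list[str]:
    values = pd.read_csv(path, header=None, sep="\t")[0].astype(str).tolist()
    if len(set(values)) != len(values):
        raise ValueError(f"duplicate identifiers in {path.name}")
    return values


def _read_mtx_dir(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    matrix = spio.mmread(path / MATRIX_FILE)
    barcodes = _read_sidecar(path / BARCODES_FILE)
    features = _read_sidecar(path / FEATURES_FILE)
    if matrix.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix dimensions {matrix.shape} do not match sidecars "
            f"({len(features)} features x {len(barcodes)} barcodes)"
        )
    dense = np.asarray(sparse.coo_matrix(matrix).todense()).T  # cells x genes
    return dense, barcodes, features


def _read_dense_table(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate cell ids in dense table")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"non-numeric entry at row {row!r}, column {col!r}")
        df[col] = coerced
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def read_counts(path: str | Path, kind: str = "modality") -> ad.AnnData | HashtagCounts:
    """Read a counts input (Matrix-Market triplet directory or dense
    delimited table, cells as rows).

    ``kind="modality"`` returns an AnnData (with ``layers['counts']`` and
    any ``metadata.csv`` sidecar merged into obs); ``kind="hashtag"``
    returns a :class:`HashtagCounts`.
    """
    path = Path(path)
    if path.is_dir():
        counts, cells, features = _read_mtx_dir(path)
    else:
        counts, cells, features = _read_dense_table(path)
    if kind == "hashtag":
        return HashtagCounts(cell_ids=cells, hashtag_ids=features,
                             counts=counts.astype(np.int64))
    if kind != "modality":
        raise ValueError(f"unknown kind {kind!r}; expected 'modality' or 'hashtag'")
    obs = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta_path = path / METADATA_FILE if path.is_dir() else None
    if meta_path is not None and meta_path.exists():
        meta = pd.read_csv(meta_path, index_col="cell_id")
        obs = obs.join(meta.astype({c: str for c in meta.columns if meta[c].dtype == object}))
    adata = ad.AnnData(
        X=counts,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
        layers={"counts": counts.copy()},
    )
    return adata


def write_counts(dataset: ad.AnnData | HashtagCounts, out_dir: str | Path) -> Path:
    """Write a dataset as a Matrix-Market triplet directory (plus a
    metadata sidecar for AnnData obs columns)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(dataset, HashtagCounts):
        counts, cells, features, obs = dataset.counts, dataset.cell_ids, dataset.hashtag_ids, None
    else:
        counts = np.asarray(
            dataset.layers["counts"] if "counts" in dataset.layers else dataset.X
        )
        cells, features = list(dataset.obs_names), list(dataset.var_names)
        obs = dataset.obs
    spio.mmwrite(out / MATRIX_FILE, sparse.coo_matrix(np.asarray(counts).T))
    pd.Series(cells).to_csv(out / BARCODES_FILE, index=False, header=False)
    pd.Series(features).to_csv(out / FEATURES_FILE, index=False, header=False)
    if obs is not None and len(obs.columns):
        obs.rename_axis("cell_id").to_csv(out / METADATA_FILE)
    return out


def config_hash(config: dict) -> str:
    """Order-independent SHA-256 of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seeds: dict[str, int] | None = None,
) -> Path:
    """Write result tables as CSV (deterministic column order) plus a
    ``manifest.json`` recording version, config hash, and all seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        target = out / f"{name}.csv"
        df.to_csv(target, index=False)
        written.append(target.name)
    manifest = {
        "package": "slomap",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "config": config or {},
        "seeds": seeds or {},
        "tables": sorted(written),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, **kwargs)


def read_embedding(path: str | Path) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """Read a delimited embedding table with a ``cell_id`` column; returns
    (cell_ids, coordinate matrix, non-numeric annotation columns)."""
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise ValueError("embedding table must have a 'cell_id' column")
    comp_cols = [c for c in df.columns if c.startswith("comp_")]
    if not comp_cols:
        comp_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c]) and c != "cell_id"]
    if not comp_cols:
        raise ValueError("embedding table has no numeric coordinate columns")
    meta = df[[c for c in df.columns if c not in comp_cols]]
    return df["cell_id"].astype(str).tolist(), df[comp_cols].to_numpy(dtype=float), meta
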