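"""Readers and writers for the pipeline's plain-text exchange formats.

Variants and copy-number segments travel as TSV (positions 1-based for
variants, 0-based half-open for segments), single-cell matrices as
MatrixMarket MTX plus features/barcodes TSV, ATAC fragments and AIRR-style
contigs as TSV, ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

__all__ = [
    "write_variants_tsv",
    "read_variants_tsv",
    "write_segments_tsv",
    "read_segments_tsv",
    "write_matrix_dir",
    "read_matrix_dir",
    "write_fragments_tsv",
    "read_fragments_tsv",
    "write_contigs_tsv",
    "read_contigs_tsv",
    "write_truth_json",
    "read_truth_json",
]


def write_variants_tsv(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    if (df["POS"] < 1).any():
        raise ValueError("variant POS must be 1-based (>= 1)")
    return df


def write_segments_tsv(segments: pd.DataFrame, path: str | Path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_segments_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    if (df["START"] >= df["END"]).any():
        raise ValueError("segments must satisfy START < END (0-based half-open)")
    return df


def write_matrix_dir(adata, out_dir: str | Path) -> Path:
    """Write an AnnData as matrix.mtx + features.tsv + barcodes.tsv + obs.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scio.mmwrite(str(out / "matrix.mtx"), X.T.tocoo())  # features x cells
    feat = adata.var.reset_index()
    feat.rename(columns={feat.columns[0]: "feature_id"}, inplace=True)
    feat.to_csv(out / "features.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        out / "barcodes.tsv", sep="\t", index=False
    )
    adata.obs.reset_index().to_csv(out / "obs.tsv", sep="\t", index=False)
    return out


def read_matrix_dir(in_dir: str | Path):
    import anndata as ad

    src = Path(in_dir)
    X = sparse.csr_matrix(scio.mmread(str(src / "matrix.mtx")).T)
    feat = pd.read_csv(src / "features.tsv", sep="\t", dtype={"chrom": str})
    obs = pd.read_csv(src / "obs.tsv", sep="\t")
    obs = obs.set_index(obs.columns[0])
    var = feat.set_index("feature_id")
    return ad.AnnData(X=X, obs=obs, var=var)


def write_fragments_tsv(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments.to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_contigs_tsv(contigs: pd.DataFrame, path: str | Path) -> None:
    contigs.to_csv(path, sep="\t", index=False)


def read_contigs_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=2, sort_keys=True) + "\n")


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
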