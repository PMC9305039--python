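"""Readers and writers for the pipeline's on-disk formats.

All tables are tab-separated UTF-8 with '.' decimals. Units and conventions:
cell counts are integers, expression in TPM (tissue tables) or normalized
log units (cell matrices), image coordinates 0-based (row, col) pixels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import anndata as ad
import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_airr_tsv",
    "write_airr_tsv",
    "read_tissue_expression",
    "write_gct",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_image",
    "write_image",
    "write_json",
    "read_json",
    "sha256_of",
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Cell-count table: columns individual, site, then cluster counts."""
    df = pd.read_csv(path, sep="\t")
    for col in ("individual", "site"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


_AIRR_COLS = ["sequence_id", "v_call", "j_call", "junction_aa", "duplicate_count"]


def read_airr_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _AIRR_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing AIRR column(s) {missing}")
    return df


def write_airr_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tissue_expression(path: str | Path) -> pd.DataFrame:
    """Genes x tissues mean-TPM matrix from GCT 1.2 or plain TSV."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first == "#1.2":
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns="Description")
        return df
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gct(df: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x tissues matrix in GCT 1.2."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in df.iterrows():
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{gene}\t{gene}\t{vals}\n")


def read_mtx_bundle(prefix: str | Path) -> ad.AnnData:
    """Cells x genes matrix from ``<prefix>.mtx`` + genes/barcodes/labels TSVs."""
    prefix = Path(prefix)
    X = spio.mmread(f"{prefix}.mtx").tocsr()
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(f"{prefix}.barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.DataFrame(index=barcodes.to_list())
    labels_path = Path(f"{prefix}.labels.tsv")
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t", header=None)[0].astype(str)
        obs["cluster"] = pd.Categorical(labels.to_list())
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes.to_list()))


def write_mtx_bundle(adata: ad.AnnData, prefix: str | Path) -> None:
    prefix = Path(prefix)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(f"{prefix}.mtx", X)
    pd.Series(adata.var_names).to_csv(f"{prefix}.genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(f"{prefix}.barcodes.tsv", sep="\t",
                                      index=False, header=False)
    if "cluster" in adata.obs:
        pd.Series(adata.obs["cluster"].astype(str).to_numpy()).to_csv(
            f"{prefix}.labels.tsv", sep="\t", index=False, header=False
        )


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return img


def write_image(img: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
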