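"""Reading and writing the toolkit's on-disk formats.

10x-style MTX triplets (matrix.mtx + features.tsv + barcodes.tsv, genes as
matrix rows), a gene-annotation TSV (gene_id, chromosome, start), a
Visium-style tissue_positions CSV, and plain TSV ground-truth tables.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy.sparse import csr_matrix


def write_mtx(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write counts as a 10x MTX triplet (genes x cells in matrix.mtx)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    X = csr_matrix(X) if not hasattr(X, "tocsr") else X.tocsr()
    spio.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(np.int64))
    feats = pd.DataFrame({"gene_id": adata.var_names, "gene_name": adata.var_names})
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    if {"chromosome", "start"} <= set(adata.var.columns):
        annot = adata.var[["chromosome", "start"]].copy()
        annot.insert(0, "gene_id", adata.var_names)
        annot.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    return outdir


def read_mtx(indir: str | Path) -> ad.AnnData:
    """Read an MTX triplet written by :func:`write_mtx`."""
    indir = Path(indir)
    X = spio.mmread(str(indir / "matrix.mtx")).tocsr().T.tocsr()
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    var = pd.DataFrame(index=pd.Index(feats[0], name=None))
    annot_path = indir / "genes.tsv"
    if annot_path.exists():
        annot = pd.read_csv(annot_path, sep="\t").set_index("gene_id")
        var = var.join(annot)
    return ad.AnnData(X=X, obs=pd.DataFrame(index=pd.Index(barcodes.astype(str))), var=var)


def write_tissue_positions(adata: ad.AnnData, path: str | Path) -> Path:
    """Visium-style tissue_positions CSV: barcode, in_tissue, array/pixel coords."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    xy = adata.obsm["spatial"]
    pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "in_tissue": 1,
            "array_row": adata.obs["array_row"].to_numpy(),
            "array_col": adata.obs["array_col"].to_numpy(),
            "pxl_row_in_fullres": xy[:, 1],
            "pxl_col_in_fullres": xy[:, 0],
        }
    ).to_csv(path, index=False)
    return path


def read_tissue_positions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index("barcode")


def write_ground_truth(adata: ad.AnnData, path: str | Path) -> Path:
    """Per-observation ground-truth columns (those present) as a TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [
        c
        for c in (
            "true_depth", "malignant", "region", "immune_region",
            "csc_loading", "macro_loading", "malignant_truth",
        )
        if c in adata.obs.columns
    ]
    adata.obs[cols].to_csv(path, sep="\t")
    return path
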