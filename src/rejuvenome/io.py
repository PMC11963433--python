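"""Plain-text readers and writers for the pipeline's tables and models.

Feature/ASV/phenotype tables travel as TSV (a ``values``/``counts`` file
plus a ``meta`` file sharing the sample index), metabolic models as JSON,
and cell matrices as MatrixMarket ``matrix.mtx`` with ``barcodes.tsv`` and
``features.tsv`` companions.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from rejuvenome.community_profile import ASVCountTable
from rejuvenome.eco_fba import MetabolicModel
from rejuvenome.feature_prep import LongitudinalFeatureTable

__all__ = [
    "write_feature_table",
    "read_feature_table",
    "write_asv_table",
    "read_asv_table",
    "write_model",
    "read_model",
    "write_cell_matrix",
    "read_cell_matrix",
]


def write_feature_table(table: LongitudinalFeatureTable, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table.values.to_csv(f"{prefix}_values.tsv", sep="\t")
    meta = table.meta.copy()
    meta["scale"] = table.scale
    meta.to_csv(f"{prefix}_meta.tsv", sep="\t")


def read_feature_table(prefix) -> LongitudinalFeatureTable:
    values = pd.read_csv(f"{prefix}_values.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(f"{prefix}_meta.tsv", sep="\t", index_col=0)
    scale = meta.pop("scale").iloc[0]
    return LongitudinalFeatureTable(values=values, meta=meta, scale=scale)


def write_asv_table(table: ASVCountTable, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(f"{prefix}_counts.tsv", sep="\t")
    table.meta.to_csv(f"{prefix}_meta.tsv", sep="\t")


def read_asv_table(prefix) -> ASVCountTable:
    counts = pd.read_csv(f"{prefix}_counts.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(f"{prefix}_meta.tsv", sep="\t", index_col=0)
    return ASVCountTable(counts=counts, meta=meta)


def write_model(model: MetabolicModel, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(model.to_json())


def read_model(path) -> MetabolicModel:
    return MetabolicModel.from_json(Path(path).read_text())


def write_cell_matrix(adata: ad.AnnData, outdir) -> None:
    """MTX + barcodes/features TSV, plus obs/var label tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    # genes x cells, the conventional feature-barcode orientation
    spio.mmwrite(outdir / "matrix.mtx", X.T.tocoo(), field="integer")
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.var.to_csv(outdir / "features.tsv", sep="\t", header=True)
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t", header=True)


def read_cell_matrix(indir) -> ad.AnnData:
    indir = Path(indir)
    X = spio.mmread(indir / "matrix.mtx").T.tocsr()
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(indir / "features.tsv", sep="\t", index_col=0)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    return adata
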