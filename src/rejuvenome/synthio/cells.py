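"""Negative-binomial cell x gene count matrices with planted effects.

Gene base means are log-normal; counts are negative-binomial with a fixed
per-gene dispersion and a log-normal per-cell depth factor — the simplest
overdispersed model under which rank-based differential expression is
calibrated.  Two kinds of effects can be planted, both as multiplicative
shifts of gene means in yMB cells:

- a *signature shift* ``score_shift[cell_type]`` (natural-log units) applied
  to a named gene set in the targeted cell types, to be recovered by the
  module score;
- ``n_de_genes`` background genes shifted by ``lfc`` (natural-log units) in
  all yMB cells, to be recovered by the per-cell-type DE test.

The matrix includes mitochondrial (``mt-`` prefix) and housekeeping genes so
the QC filter is exercised realistically.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from rejuvenome._seeds import child_rng

__all__ = ["gen_cell_matrix", "DEFAULT_DISPERSION"]

#: Fixed per-gene NB dispersion phi (var = mu + phi * mu^2).
DEFAULT_DISPERSION = 0.4

_N_MITO = 10
_N_HOUSEKEEPING = 20


def gen_cell_matrix(
    n_cells_per_type: int = 150,
    cell_types=("enterocyte", "TA", "goblet", "macrophage"),
    signature=None,
    score_shift=None,
    n_de_genes: int = 0,
    lfc: float = 0.0,
    n_genes: int = 1000,
    n_mice_per_group: int = 3,
    dispersion: float = DEFAULT_DISPERSION,
    mean_scale: float = 0.3,
    seed: int = 0,
) -> ad.AnnData:
    """Generate a labeled single-cell count matrix as an AnnData.

    ``signature`` is a gene-name list planted into the matrix; ``score_shift``
    maps cell types to the natural-log shift of those genes in yMB cells of
    that type.  Ground truth is recorded in ``uns["ground_truth"]``.
    """
    signature = list(signature or [])
    score_shift = dict(score_shift or {})
    unknown = set(score_shift) - set(cell_types)
    if unknown:
        raise ValueError(f"score_shift targets unknown cell types {sorted(unknown)}")
    rng = child_rng(seed, "cells")

    mito = [f"mt-Gene{i}" for i in range(_N_MITO)]
    housekeeping = [f"Hk{i}" for i in range(_N_HOUSEKEEPING)]
    n_bg = n_genes - len(signature) - len(mito) - len(housekeeping)
    if n_bg < n_de_genes:
        raise ValueError("n_genes too small for the requested gene sets")
    background = [f"Gene{i:04d}" for i in range(n_bg)]
    genes = signature + mito + housekeeping + background
    de_genes = background[:n_de_genes]

    # base means: log-normal across genes; housekeeping and mito boosted so
    # their count fractions sit in a realistic range for the QC thresholds
    mu = mean_scale * rng.lognormal(0.0, 1.0, size=len(genes))
    gidx = pd.Index(genes)
    mu[gidx.get_indexer(housekeeping)] *= 12.0
    mu[gidx.get_indexer(mito)] *= 4.0

    obs_rows = []
    counts = []
    sig_idx = gidx.get_indexer(signature)
    de_idx = gidx.get_indexer(de_genes)
    for trt, prefix in (("yMB", "Y"), ("iMB", "I")):
        mice = [f"{prefix}{i}" for i in range(n_mice_per_group)]
        for ct in cell_types:
            for j in range(n_cells_per_type):
                cell_mu = mu.copy()
                if trt == "yMB":
                    if ct in score_shift and len(sig_idx):
                        cell_mu[sig_idx] *= np.exp(score_shift[ct])
                    if len(de_idx):
                        cell_mu[de_idx] *= np.exp(lfc)
                cell_mu = cell_mu * rng.lognormal(0.0, 0.25)
                n_param = 1.0 / dispersion
                p_param = n_param / (n_param + cell_mu)
                counts.append(rng.negative_binomial(n_param, p_param))
                obs_rows.append((ct, mice[j % n_mice_per_group], trt))
    X = np.vstack(counts).astype(np.int64)
    obs = pd.DataFrame(obs_rows, columns=["cell_type", "mouse_id", "treatment"])
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    var = pd.DataFrame(
        {
            "mito": [g.startswith("mt-") for g in genes],
            "housekeeping": [g in set(housekeeping) for g in genes],
        },
        index=genes,
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["ground_truth"] = {
        "signature": signature,
        "score_shift": score_shift,
        "de_genes": de_genes,
        "lfc": lfc,
        "dispersion": dispersion,
    }
    return adata
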