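"""Single-cell mucosa analysis: QC, normalization, signature scores, DE.

Works on an :class:`anndata.AnnData` of raw counts (cells x genes) with
``obs`` columns ``cell_type``, ``mouse_id`` and ``treatment`` and boolean
``var`` columns ``mito`` and ``housekeeping``.

QC keeps cells with 200..5000 total counts, at most 25% mitochondrial
counts and at least 10% housekeeping counts (criteria are conjunctive, so
order is immaterial).  Expression is depth-normalized to a fixed scale and
natural-log transformed.  A composite module score per signature (e.g. the
mesenchymal set Vim/Ctnnb1/Fn1/... or the inflammaging set Tnf/Ifng/Il1b/...)
is the mean normalized expression of the signature genes minus that of
expression-matched control genes drawn from average-expression bins —
so a score above zero means the signature is expressed above its
expression-matched background in that cell.  Scores and per-mouse cell-type
proportions are compared between treatments with Mann-Whitney tests; genes
are tested per cell type with a Wilcoxon rank-sum test, a natural-log fold
threshold, and Bonferroni correction over all genes in the dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from rejuvenome._seeds import child_rng

__all__ = [
    "GeneSignature",
    "MESENCHYMAL",
    "INFLAMMATORY",
    "qc_filter",
    "lognorm",
    "module_score",
    "score_compare",
    "de_per_celltype",
    "proportion_compare",
]


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError("empty gene signature")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")


#: Mesenchymal (EMT-propensity) signature scored in epithelial cells.
MESENCHYMAL = GeneSignature(
    "mesenchymal",
    ("Vim", "Ctnnb1", "Fn1", "Aifm2", "Tgfb1", "Tgfbr1", "Smad2", "Smad3", "Smad4"),
)

#: Inflammaging signature scored in immune cells.
INFLAMMATORY = GeneSignature(
    "inflammatory",
    ("Tnf", "Ifng", "Il1b", "Il2", "Il6", "Cxcl15", "Ccl20", "Ccl9", "Ccr1",
     "Nfkb1", "Myd88", "Tlr6"),
)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)


def qc_filter(
    adata,
    min_counts: int = 200,
    max_counts: int = 5000,
    max_mito: float = 0.25,
    min_housekeeping: float = 0.10,
):
    """Remove damaged or doublet-like cells; returns ``(adata, report)``.

    Keeps cells with ``min_counts <= total <= max_counts`` (cells with *more
    than* ``max_counts`` or *fewer than* ``min_counts`` are removed, so both
    stated bounds are themselves kept), mitochondrial fraction at most
    ``max_mito`` and housekeeping fraction at least ``min_housekeeping``.
    The report counts removals per criterion (a cell may fail several).
    """
    for col in ("mito", "housekeeping"):
        if col not in adata.var.columns:
            raise ValueError(f"gene flag column {col!r} missing")
    X = _dense(adata.X)
    total = X.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = X[:, adata.var["mito"].to_numpy(bool)].sum(axis=1) / total
        hk_frac = X[:, adata.var["housekeeping"].to_numpy(bool)].sum(axis=1) / total
    fail_low = total < min_counts
    fail_high = total > max_counts
    fail_mito = mito_frac > max_mito
    fail_hk = hk_frac < min_housekeeping
    keep = ~(fail_low | fail_high | fail_mito | fail_hk)
    if not keep.any():
        raise ValueError("no cells survive QC")
    report = {
        "n_input": adata.n_obs,
        "n_kept": int(keep.sum()),
        "removed_low_counts": int(fail_low.sum()),
        "removed_high_counts": int(fail_high.sum()),
        "removed_mito": int(fail_mito.sum()),
        "removed_housekeeping": int(fail_hk.sum()),
    }
    return adata[keep].copy(), report


def lognorm(adata, scale: float = 1e4):
    """Depth-normalize to ``scale`` counts per cell, then ``ln(1 + x)``.

    Raw counts are preserved in ``layers["counts"]``; the result is depth
    invariant (doubling every count of a cell leaves it unchanged).
    """
    X = _dense(adata.X)
    total = X.sum(axis=1, keepdims=True)
    if (total == 0).any():
        raise ValueError("cell with zero total counts; run QC first")
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    out.X = np.log1p(X / total * scale)
    out.uns["lognorm_scale"] = scale
    return out


def module_score(
    adata,
    signature: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_pool=None,
) -> np.ndarray:
    """Per-cell composite score of a gene signature.

    All genes are ranked by their average normalized expression and split
    into ``n_bins`` equal-size bins; for every signature gene, ``n_ctrl``
    control genes are drawn (seeded, without replacement where possible)
    from its bin.  The score is the mean expression of the signature genes
    minus the mean expression of the pooled control genes.  ``control_pool``
    overrides the drawn controls (passing the signature itself yields an
    identically zero score, a useful self-check).

    Signature genes absent from the matrix are dropped with a warning; an
    entirely absent signature raises.
    """
    genes = pd.Index(adata.var_names)
    present = [g for g in signature.genes if g in genes]
    missing = sorted(set(signature.genes) - set(present))
    if not present:
        raise ValueError(f"signature {signature.name!r} entirely absent from matrix")
    if missing:
        warnings.warn(f"signature genes absent and dropped: {missing}", stacklevel=2)
    X = _dense(adata.X)
    sig_idx = genes.get_indexer(present)
    if control_pool is not None:
        ctrl_idx = genes.get_indexer([g for g in control_pool if g in genes])
        if len(ctrl_idx) == 0:
            raise ValueError("control pool absent from matrix")
    else:
        rng = child_rng(seed, "module_score")
        mean_expr = X.mean(axis=0)
        order = pd.Series(mean_expr, index=genes).rank(method="first")
        bins = np.floor(order.to_numpy() / (len(genes) / n_bins + 1e-9)).astype(int)
        ctrl = []
        for gi in sig_idx:
            pool = np.flatnonzero(bins == bins[gi])
            pool = pool[pool != gi]
            take = min(n_ctrl, len(pool))
            ctrl.append(rng.choice(pool, size=take, replace=False))
        ctrl_idx = np.unique(np.concatenate(ctrl))
    return X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def score_compare(adata, scores, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell-type Mann-Whitney comparison of cell scores between treatments.

    BH correction is applied across cell types.
    """
    from rejuvenome.phenotype_stats import mann_whitney

    df = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "cell_type": adata.obs["cell_type"].to_numpy(),
            "treatment": adata.obs["treatment"].to_numpy(),
        }
    )
    rows = []
    for ct, sub in df.groupby("cell_type", observed=True):
        x = sub.loc[sub["treatment"] == "yMB", "score"]
        y = sub.loc[sub["treatment"] == "iMB", "score"]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"cell type {ct!r} missing a treatment; skipped", stacklevel=2)
            continue
        u, p = mann_whitney(x.to_numpy(), y.to_numpy(), mode="asymptotic")
        rows.append((ct, len(x), len(y), float(x.mean() - y.mean()), u, p))
    out = pd.DataFrame(
        rows, columns=["cell_type", "n_yMB", "n_iMB", "delta_mean", "U", "p"]
    )
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] <= alpha
    return out.set_index("cell_type")


def de_per_celltype(
    adata,
    cell_type: str,
    min_lfc: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between treatments within one cell type.

    Expression must be log-normalized.  The log fold is the difference of
    group means on the natural-log normalized scale; reported genes satisfy
    ``|log_fold| >= min_lfc`` and a Bonferroni-adjusted p below ``alpha``
    with the correction factor equal to *all* genes in the dataset.
    Returns the full per-gene table with a ``significant`` column.
    """
    sub = adata[adata.obs["cell_type"] == cell_type]
    X = _dense(sub.X)
    is_y = (sub.obs["treatment"] == "yMB").to_numpy()
    if not is_y.any() or is_y.all():
        warnings.warn(f"cell type {cell_type!r} absent in one treatment; skipped",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["log_fold", "U", "p", "p_bonf", "direction", "significant"]
        )
    xg, yg = X[is_y], X[~is_y]
    res = stats.mannwhitneyu(xg, yg, alternative="two-sided", axis=0)
    lfc = xg.mean(axis=0) - yg.mean(axis=0)
    m = adata.n_vars  # Bonferroni over all genes in the dataset
    p_bonf = np.minimum(res.pvalue * m, 1.0)
    out = pd.DataFrame(
        {
            "log_fold": lfc,
            "U": res.statistic,
            "p": res.pvalue,
            "p_bonf": p_bonf,
            "direction": np.where(lfc > 0, "up", "down"),
        },
        index=sub.var_names,
    )
    out["significant"] = (np.abs(out["log_fold"]) >= min_lfc) & (out["p_bonf"] < alpha)
    return out


def proportion_compare(adata) -> tuple:
    """Per-mouse cell-type proportions and their between-treatment tests.

    Returns ``(proportions, tests)``: proportions is mice x cell types
    (rows sum to one); tests holds one Mann-Whitney comparison per cell
    type across mice.
    """
    from rejuvenome.phenotype_stats import mann_whitney

    obs = adata.obs[["mouse_id", "treatment", "cell_type"]].copy()
    counts = (
        obs.groupby(["mouse_id", "cell_type"], observed=True).size().unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    trt = obs.drop_duplicates("mouse_id").set_index("mouse_id")["treatment"]
    rows = []
    for ct in props.columns:
        x = props.loc[trt[props.index] == "yMB", ct]
        y = props.loc[trt[props.index] == "iMB", ct]
        if len(x) < 2 or len(y) < 2:
            continue
        u, p = mann_whitney(x.to_numpy(), y.to_numpy())
        rows.append((ct, float(x.mean()), float(y.mean()), u, p))
    tests = pd.DataFrame(
        rows, columns=["cell_type", "mean_yMB", "mean_iMB", "U", "p"]
    ).set_index("cell_type")
    return props, tests
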