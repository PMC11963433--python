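"""ASV-level community diversity: rarefaction, Bray-Curtis, drift, PCoA.

16S amplicon count tables are rarefied (seeded subsampling without
replacement) to a common depth to remove sequencing-depth differences,
converted to relative abundances, and compared with the Bray-Curtis
dissimilarity.  The central trajectory statistic is the distance of each
sample to the week-8 "young baseline" configuration of its own mouse (or to
the baseline centroid when the mouse has no baseline sample), compared
between treatment arms per timepoint with a Mann-Whitney test.  Classical
(unconstrained) principal-coordinates analysis is provided for ordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ASVCountTable",
    "rarefy",
    "relative_abundance",
    "bray_curtis",
    "distance_to_baseline",
    "pcoa",
]


@dataclass
class ASVCountTable:
    """Integer count matrix (samples x ASVs) with per-sample metadata."""

    counts: pd.DataFrame
    meta: pd.DataFrame  # mouse_id, age_weeks, treatment

    def __post_init__(self):
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the same sample index")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(int)


def rarefy(table: ASVCountTable, depth: int | None = None, seed: int = 0) -> ASVCountTable:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum sample sum (the "minimum shared read
    count").  Sampling is multivariate hypergeometric per sample, seeded.
    """
    sums = table.counts.sum(axis=1)
    if depth is None:
        depth = int(sums.min())
    too_small = sums[sums < depth]
    if len(too_small):
        raise ValueError(
            f"depth {depth} exceeds total reads of sample(s) {list(too_small.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.vstack(
        [
            rng.multivariate_hypergeometric(row, depth)
            for row in table.counts.to_numpy().astype(np.int64)
        ]
    )
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return replace(table, counts=counts)


def relative_abundance(table) -> pd.DataFrame:
    """Per-sample proportions (rows sum to one)."""
    counts = table.counts if isinstance(table, ASVCountTable) else table
    sums = counts.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("zero-sum sample in relative abundance")
    return counts.div(sums, axis=0)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity ``sum|u - v| / sum(u + v)``, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("negative abundances")
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


def distance_to_baseline(
    table: ASVCountTable,
    baseline_week: float = 8,
    mode: str = "own",
):
    """Bray-Curtis distance of every sample to the baseline configuration.

    ``mode="own"`` uses each mouse's own baseline-week sample, falling back
    to the baseline centroid (mean relative abundance over baseline samples)
    for mice without one; ``mode="centroid"`` always uses the centroid.
    Returns ``(per_sample, tests)``: a frame with the distance per sample and
    a frame of per-timepoint Mann-Whitney yMB-vs-iMB comparisons.
    """
    from rejuvenome.phenotype_stats import mann_whitney

    if mode not in ("own", "centroid"):
        raise ValueError(f"unknown mode {mode!r}")
    rel = relative_abundance(table)
    is_base = table.meta["age_weeks"] == baseline_week
    if not is_base.any():
        raise ValueError(f"no samples at baseline week {baseline_week}")
    centroid = rel[is_base].mean().to_numpy()
    base_by_mouse = {
        table.meta.loc[s, "mouse_id"]: rel.loc[s].to_numpy()
        for s in rel.index[is_base]
    }
    dist = {}
    for s in rel.index:
        mouse = table.meta.loc[s, "mouse_id"]
        if mode == "own" and mouse in base_by_mouse:
            ref = base_by_mouse[mouse]
        else:
            ref = centroid
        dist[s] = bray_curtis(rel.loc[s].to_numpy(), ref)
    per_sample = table.meta.copy()
    per_sample["distance"] = pd.Series(dist)
    tests = []
    for week, sub in per_sample.groupby("age_weeks"):
        x = sub.loc[sub["treatment"] == "yMB", "distance"]
        y = sub.loc[sub["treatment"] == "iMB", "distance"]
        if len(x) < 2 or len(y) < 2:
            continue
        u, p = mann_whitney(x.to_numpy(), y.to_numpy())
        tests.append((week, len(x), len(y), u, p))
    tests = pd.DataFrame(tests, columns=["age_weeks", "n_yMB", "n_iMB", "U", "p"])
    return per_sample, tests


def pcoa(distances, k: int = 2):
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centers the squared distances and eigendecomposes; coordinates
    are returned for the top ``k`` positive eigenvalues (fewer, with a
    warning, if the matrix has fewer positive eigenvalues).  All eigenvalues,
    including negative ones, are reported.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals)) * 1e-12 if eigvals.size else 0.0
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes", stacklevel=2
        )
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    if isinstance(distances, pd.DataFrame):
        coords = pd.DataFrame(
            coords, index=distances.index, columns=[f"PCo{i+1}" for i in range(k)]
        )
    return coords, eigvals
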