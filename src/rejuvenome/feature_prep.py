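"""Filtering, normalization and transformation of longitudinal feature tables.

Metagenomic feature abundances (e.g. KEGG-ortholog counts per sample) pass
through a fixed pipeline before the mixed-model screen:

1. prevalence filter — keep features with non-zero abundance in at least a
   fraction of samples (default 10%);
2. total-sum scaling (TSS) — per-sample division by the sample total;
3. transform — ``log10(x + 0.01) + 2`` for sparse KO relative abundances
   (zero maps exactly to zero) or a plain ``log10`` for strictly positive
   abundances such as ecological-relationship frequencies.

Each table carries a ``scale`` tag (raw → relative → transformed) and every
operation checks it, so the pipeline can only be run in the intended order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

TREATMENTS = ("yMB", "iMB")
_SCALES = ("raw", "relative", "transformed")

__all__ = [
    "LongitudinalFeatureTable",
    "prevalence_filter",
    "tss_normalize",
    "transform_ko",
    "transform_eco",
]


@dataclass
class LongitudinalFeatureTable:
    """Samples x features abundance matrix joined to per-sample metadata.

    ``values`` rows are samples, columns features; ``meta`` is indexed by the
    same sample ids and carries ``mouse_id``, ``age_weeks`` and ``treatment``
    (one of ``yMB``/``iMB``).  ``scale`` tags the current pipeline stage.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same sample index")
        for col in ("mouse_id", "age_weeks", "treatment"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata column {col!r} missing")
        bad = set(self.meta["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatment labels {sorted(bad)}")
        if self.scale != "transformed" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundances on a non-transformed scale")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def prevalence_filter(
    table: LongitudinalFeatureTable, min_prevalence: float = 0.10
) -> LongitudinalFeatureTable:
    """Keep features non-zero in at least ``min_prevalence`` of samples.

    The boundary is inclusive ("at least"): with 10 samples and a threshold
    of 0.10, a feature present in exactly one sample is retained.  The
    comparison is done on exact rationals so that thresholds like 0.10 behave
    as written rather than as their nearest binary float.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    if table.scale not in ("raw", "relative"):
        raise ValueError("prevalence filter expects a raw or relative table")
    n = table.n_samples
    thresh = Fraction(min_prevalence).limit_denominator(10**6)
    nonzero = (table.values.to_numpy() > 0).sum(axis=0)
    keep = np.array([Fraction(int(k), n) >= thresh for k in nonzero])
    if not keep.any():
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return replace(table, values=table.values.loc[:, keep])


def tss_normalize(table: LongitudinalFeatureTable) -> LongitudinalFeatureTable:
    """Total-sum scaling: divide each sample row by its total.

    Requires a raw table; the result is tagged ``relative`` and every row
    sums to one.
    """
    if table.scale != "raw":
        raise ValueError(f"TSS expects a raw table, got scale {table.scale!r}")
    sums = table.values.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    return replace(table, values=table.values.div(sums, axis=0), scale="relative")


def _transform_values(x, fn, name):
    arr = np.asarray(x, dtype=float)
    out = fn(arr)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    if np.isscalar(x):
        return float(out)
    return out


def transform_ko(x):
    """Sparse-abundance transform ``log10(x + 0.01) + 2``.

    Maps zero relative abundance to exactly zero while shifting non-zero
    values only minimally; strictly increasing on ``x >= 0``.  Accepts a
    scalar, array, DataFrame, or a relative-scale
    :class:`LongitudinalFeatureTable` (returned tagged ``transformed``).
    """
    if isinstance(x, LongitudinalFeatureTable):
        if x.scale != "relative":
            raise ValueError("transform_ko expects a relative-scale table")
        return replace(x, values=transform_ko(x.values), scale="transformed")
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundance passed to transform_ko")
    return _transform_values(x, lambda a: np.log10(a + 0.01) + 2.0, "ko")


def transform_eco(x):
    """Plain ``log10`` for strictly positive abundances.

    Used for ecological-relationship frequencies, which are never zero; a
    zero or negative input violates that premise and raises.
    """
    if isinstance(x, LongitudinalFeatureTable):
        if x.scale != "relative":
            raise ValueError("transform_eco expects a relative-scale table")
        return replace(x, values=transform_eco(x.values), scale="transformed")
    arr = np.asarray(x, dtype=float)
    if (arr <= 0).any():
        raise ValueError("transform_eco requires strictly positive abundances")
    return _transform_values(x, np.log10, "eco")
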