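"""Dirichlet-multinomial ASV tables drifting from a week-8 baseline.

Every mouse starts from its own baseline composition (a Dirichlet draw
around a shared community profile).  With age, the expected composition
moves linearly toward a mouse-specific "aged" attractor at a per-week rate
that depends on treatment, so the expected Bray-Curtis distance to the
mouse's own baseline grows with age at the configured rate.  Counts are
Dirichlet-multinomial: the realized composition of each sample is itself a
Dirichlet draw around the expectation, which produces the overdispersion
that rarefaction has to absorb.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rejuvenome._seeds import child_rng
from rejuvenome.community_profile import ASVCountTable

__all__ = ["gen_asv_table"]


def gen_asv_table(
    n_mice_per_group: int = 8,
    timepoints=(8, 40, 72, 120),
    drift_per_week=None,
    depth_range=(8000, 12000),
    n_asvs: int = 150,
    concentration: float = 300.0,
    seed: int = 0,
) -> ASVCountTable:
    """Generate a seeded longitudinal ASV count table.

    ``drift_per_week`` maps treatment to the per-week mixing rate toward the
    aged composition (default yMB 0.002, iMB 0.006 — the young-donor arm
    drifts more slowly); the mixing weight is capped at 1.  ``concentration``
    controls the Dirichlet overdispersion of each realized sample (larger =
    closer to the expected composition).
    """
    if drift_per_week is None:
        drift_per_week = {"yMB": 0.002, "iMB": 0.006}
    timepoints = tuple(timepoints)
    if len(timepoints) < 1 or any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise ValueError("timepoints must be strictly increasing")
    baseline_week = timepoints[0]
    lo, hi = depth_range
    if lo > hi or lo <= 0:
        raise ValueError("invalid depth_range")
    rng = child_rng(seed, "asv")

    # shared community profile with a realistic abundance skew
    base_profile = rng.dirichlet(np.full(n_asvs, 0.3))
    asv_ids = [f"ASV{i:04d}" for i in range(n_asvs)]
    rows, meta = [], []
    for g, trt in (("Y", "yMB"), ("I", "iMB")):
        rate = drift_per_week[trt]
        for i in range(n_mice_per_group):
            mouse = f"{g}{i:03d}"
            p_base = rng.dirichlet(base_profile * 2000 + 1e-9)
            p_aged = rng.dirichlet(base_profile * 50 + 1e-9)
            for t in timepoints:
                w = min(1.0, rate * (t - baseline_week))
                p_t = (1 - w) * p_base + w * p_aged
                theta = rng.dirichlet(p_t * concentration + 1e-12)
                depth = int(rng.integers(lo, hi + 1))
                rows.append(rng.multinomial(depth, theta))
                meta.append((f"{mouse}_w{t}", mouse, float(t), trt))
    meta = pd.DataFrame(
        meta, columns=["sample_id", "mouse_id", "age_weeks", "treatment"]
    ).set_index("sample_id")
    counts = pd.DataFrame(np.vstack(rows), index=meta.index, columns=asv_ids)
    return ASVCountTable(counts=counts, meta=meta)
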