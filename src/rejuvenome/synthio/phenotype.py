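"""Host-phenotype curves: weights, ipGTT glucose, right-censored survival.

- Weight trajectories follow a saturating growth curve (grams) sampled every
  4 weeks from week 8 to week 120, with subject-level offsets and
  measurement noise; ``auc_offset`` adds a late-life advantage to the yMB
  arm, ramped linearly over weeks 80-120 so that the planted between-group
  difference of the weeks-80-120 AUC equals ``auc_offset`` in expectation.
- ipGTT curves (mmol/L) are sampled at 0/15/30/60/90/120 minutes with a
  peak near 15-30 min; ``gtt_offset`` (default 0, matching a null glucose
  effect) shifts the yMB curve additively.
- Survival times are exponential beyond a shared minimum lifespan, with the
  iMB hazard equal to ``survival_hazard_ratio`` times the yMB hazard, and
  administrative right-censoring at week 122.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rejuvenome._seeds import child_rng

__all__ = ["PhenotypeTables", "gen_phenotype"]

_WEIGHT_WEEKS = np.arange(8, 121, 4, dtype=float)
_GTT_MINUTES = np.array([0.0, 15.0, 30.0, 60.0, 90.0, 120.0])
_CENSOR_WEEK = 122.0
_MIN_LIFESPAN = 60.0
_BASE_HAZARD = 0.012  # deaths per week beyond the minimum lifespan (yMB)


@dataclass
class PhenotypeTables:
    """Long-format phenotype tables for one simulated cohort."""

    weights: pd.DataFrame  # subject, group, week, value
    gtt: pd.DataFrame  # subject, group, minute, value
    survival: pd.DataFrame  # subject, group, time, event


def gen_phenotype(
    n_per_group: int = 20,
    auc_offset: float = 0.0,
    survival_hazard_ratio: float = 1.0,
    gtt_offset: float = 0.0,
    seed: int = 0,
) -> PhenotypeTables:
    """Simulate one cohort; deterministic per seed."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be positive")
    if survival_hazard_ratio <= 0:
        raise ValueError("survival_hazard_ratio must be positive")
    rng = child_rng(seed, "phenotype")
    weights, gtt, surv = [], [], []
    window = 120.0 - 80.0
    for group in ("yMB", "iMB"):
        for i in range(n_per_group):
            subject = f"{group}_{i:03d}"
            # weights: saturating growth + subject offset + noise
            subj_offset = rng.normal(0.0, 1.5)
            base = 20.0 + 15.0 * _WEIGHT_WEEKS / (_WEIGHT_WEEKS + 25.0)
            vals = base + subj_offset + rng.normal(0.0, 0.5, size=base.size)
            if group == "yMB" and auc_offset != 0.0:
                ramp = np.clip((_WEIGHT_WEEKS - 80.0) / window, 0.0, 1.0)
                # triangle of height h over the window has area h*window/2
                vals = vals + ramp * (2.0 * auc_offset / window)
            weights.extend(
                (subject, group, w, v) for w, v in zip(_WEIGHT_WEEKS, vals)
            )
            # ipGTT: fasting level, glucose bolus peak, decay
            peak = 10.0 + rng.normal(0.0, 1.0)
            curve = 5.0 + peak * (_GTT_MINUTES / 30.0) * np.exp(1.0 - _GTT_MINUTES / 30.0)
            curve = curve + rng.normal(0.0, 0.4, size=curve.size)
            if group == "yMB":
                curve = curve + gtt_offset
            gtt.extend((subject, group, m, v) for m, v in zip(_GTT_MINUTES, curve))
            # survival: exponential beyond a shared minimum lifespan
            hazard = _BASE_HAZARD * (survival_hazard_ratio if group == "iMB" else 1.0)
            t = _MIN_LIFESPAN + rng.exponential(1.0 / hazard)
            event = int(t <= _CENSOR_WEEK)
            surv.append((subject, group, min(t, _CENSOR_WEEK), event))
    return PhenotypeTables(
        weights=pd.DataFrame(weights, columns=["subject", "group", "week", "value"]),
        gtt=pd.DataFrame(gtt, columns=["subject", "group", "minute", "value"]),
        survival=pd.DataFrame(surv, columns=["subject", "group", "time", "event"]),
    )
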