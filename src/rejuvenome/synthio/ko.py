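"""Longitudinal KO-style feature tables with planted age dependencies.

The generator produces data directly on the transformed scale under the
exact model the screen fits:

    y = intercept_f + slope_f(treatment) * age + u(mouse, feature) + noise

so the additive model holds exactly in expectation and parameter recovery is
exact in the noise-free limit.  Four feature classes are planted:

- ``null`` — no age effect in either arm;
- ``inverted`` — age slopes of strictly opposite sign in yMB vs iMB
  (the rejuvenation signature);
- ``concordant_up`` / ``concordant_down`` — same-sign slopes in both arms,
  with the iMB slope attenuated so the interaction is still non-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rejuvenome._seeds import child_rng
from rejuvenome.feature_prep import LongitudinalFeatureTable

__all__ = ["ScreenSimConfig", "GroundTruth", "gen_ko_table"]

_CLASSES = ("null", "inverted", "concordant_up", "concordant_down")

#: iMB slope = this factor times the yMB slope for concordant features, so
#: concordant features still carry a true interaction while sharing the sign.
_CONCORDANT_ATTENUATION = 0.4


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class ScreenSimConfig:
    """Design of one synthetic longitudinal feature table."""

    n_mice_per_group: int = 10
    timepoints: tuple = (8, 40, 72, 120)
    n_null: int = 200
    n_inverted: int = 50
    n_concordant_up: int = 0
    n_concordant_down: int = 0
    slope_magnitude: float = 0.005  # transformed units per week
    mouse_sd: float = 0.1
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for f in ("n_mice_per_group", "n_null", "n_inverted",
                  "n_concordant_up", "n_concordant_down"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be non-negative")
        if self.n_mice_per_group == 0:
            raise ConfigError("n_mice_per_group must be positive")
        tp = tuple(self.timepoints)
        if len(tp) < 2:
            raise ConfigError("timepoints: at least 2 required for a random intercept")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("timepoints must be strictly increasing")
        if self.mouse_sd < 0:
            raise ConfigError("mouse_sd must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.n_features == 0:
            raise ConfigError("n_null + class counts: at least one feature required")
        self.timepoints = tp

    @property
    def n_features(self) -> int:
        return (self.n_null + self.n_inverted
                + self.n_concordant_up + self.n_concordant_down)


@dataclass
class GroundTruth:
    """True class and per-treatment slopes for every generated feature."""

    classes: pd.Series  # feature_id -> class
    slopes: pd.DataFrame  # feature_id x {slope_yMB, slope_iMB}

    def features_of(self, cls: str) -> list:
        if cls not in _CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        return list(self.classes.index[self.classes == cls])

    @property
    def has_interaction(self) -> pd.Series:
        """True where the two arms' slopes genuinely differ."""
        return self.slopes["slope_yMB"] != self.slopes["slope_iMB"]


def gen_ko_table(cfg: ScreenSimConfig):
    """Generate one table plus its ground truth; same seed, same bytes."""
    rng = child_rng(cfg.seed, "ko")
    n_mice = 2 * cfg.n_mice_per_group
    mice = [f"M{i:03d}" for i in range(n_mice)]
    treatment = ["yMB"] * cfg.n_mice_per_group + ["iMB"] * cfg.n_mice_per_group
    meta = pd.DataFrame(
        [
            (f"{m}_w{t}", m, float(t), trt)
            for m, trt in zip(mice, treatment)
            for t in cfg.timepoints
        ],
        columns=["sample_id", "mouse_id", "age_weeks", "treatment"],
    ).set_index("sample_id")

    labels = (
        ["null"] * cfg.n_null
        + ["inverted"] * cfg.n_inverted
        + ["concordant_up"] * cfg.n_concordant_up
        + ["concordant_down"] * cfg.n_concordant_down
    )
    fids = [f"K{i:05d}" for i in range(len(labels))]
    mag = cfg.slope_magnitude
    slopes = np.zeros((len(labels), 2))  # yMB, iMB
    for i, lab in enumerate(labels):
        if lab == "inverted":
            s = mag if rng.random() < 0.5 else -mag
            slopes[i] = (s, -s)
        elif lab == "concordant_up":
            slopes[i] = (mag, mag * _CONCORDANT_ATTENUATION)
        elif lab == "concordant_down":
            slopes[i] = (-mag, -mag * _CONCORDANT_ATTENUATION)
    intercepts = rng.uniform(0.5, 1.5, size=len(labels))

    age = meta["age_weeks"].to_numpy()
    is_y = (meta["treatment"] == "yMB").to_numpy()
    mouse_codes = pd.factorize(meta["mouse_id"])[0]
    # one random intercept per (mouse, feature), drawn once and reused at
    # every timepoint of that mouse
    u = rng.normal(0.0, cfg.mouse_sd, size=(n_mice, len(labels)))
    eps = rng.normal(0.0, cfg.noise_sd, size=(len(meta), len(labels)))
    slope_per_sample = np.where(is_y[:, None], slopes[None, :, 0], slopes[None, :, 1])
    values = (
        intercepts[None, :]
        + slope_per_sample * age[:, None]
        + u[mouse_codes, :]
        + eps
    )
    table = LongitudinalFeatureTable(
        values=pd.DataFrame(values, index=meta.index, columns=fids),
        meta=meta,
        scale="transformed",
    )
    truth = GroundTruth(
        classes=pd.Series(labels, index=fids, name="class"),
        slopes=pd.DataFrame(slopes, index=fids, columns=["slope_yMB", "slope_iMB"]),
    )
    return table, truth
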