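"""Deterministic seed fan-out.

One user-facing integer seed is split into independent per-component child
streams via :class:`numpy.random.SeedSequence` spawn keys.  Each generator in
the package owns a fixed component index, so adding a new generator (a new
index) never perturbs the streams of existing ones.
"""

from __future__ import annotations

import numpy as np

# Fixed component indices; append only, never renumber.
_COMPONENTS = {
    "ko": 0,
    "models": 1,
    "asv": 2,
    "cells": 3,
    "phenotype": 4,
    "rarefaction": 5,
    "module_score": 6,
}


def child_rng(seed: int, component: str) -> np.random.Generator:
    """Return the child random generator for ``component`` under ``seed``."""
    try:
        key = _COMPONENTS[component]
    except KeyError:
        raise ValueError(f"unknown seed component {component!r}") from None
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
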