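import numpy as np
import pandas as pd
import pytest

from rejuvenome.feature_prep import LongitudinalFeatureTable


def make_table(values, ages=None, treatments=None, mice=None, scale="raw"):
    """Small LongitudinalFeatureTable from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ages = list(ages) if ages is not None else [8.0] * n
    treatments = list(treatments) if treatments is not None else ["yMB"] * (n // 2) + ["iMB"] * (n - n // 2)
    mice = list(mice) if mice is not None else [f"M{i}" for i in range(n)]
    idx = [f"s{i}" for i in range(n)]
    vals = pd.DataFrame(values, index=idx, columns=[f"K{j:05d}" for j in range(values.shape[1])])
    meta = pd.DataFrame(
        {"mouse_id": mice, "age_weeks": ages, "treatment": treatments}, index=idx
    )
    return LongitudinalFeatureTable(values=vals, meta=meta, scale=scale)


@pytest.fixture
def raw_table():
    rng = np.random.default_rng(0)
    return make_table(rng.integers(0, 50, size=(10, 6)))
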