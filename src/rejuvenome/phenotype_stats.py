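"""Host-phenotype statistics: windowed trapezoidal AUC, Mann-Whitney, log-rank.

These are the cross-cutting tests of the study design: body-weight
trajectories are summarized by the trapezoidal area under the curve over a
late-life window (weeks 80-120) and compared between treatment arms with a
two-sided Mann-Whitney test; glucose-tolerance (ipGTT) curves are summarized
the same way over minutes; survival is compared with the Mantel-Cox log-rank
test.

The Mann-Whitney p-value is exact (full enumeration of the U distribution)
when both groups have at most 8 observations and there are no ties, and
otherwise uses the normal approximation with tie and continuity corrections.
The log-rank statistic is the classical Mantel-Cox form: at each pooled
event time the observed events in group 1 are compared with the
hypergeometric expectation given the risk sets, and the squared standardized
sum is referred to a 1-df chi-square.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["auc_trapezoid", "mann_whitney", "logrank"]


def auc_trapezoid(times, values, window_start: float, window_end: float) -> float:
    """Trapezoidal AUC of one subject's series over ``[window_start, window_end]``.

    Window edges that fall between observations are linearly interpolated.
    Times must be strictly increasing and the window must lie inside the
    observed range.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    if window_start >= window_end:
        raise ValueError("window_start must be below window_end")
    if window_start < t[0] or window_end > t[-1]:
        raise ValueError("window outside the observed time range")
    inside = (t > window_start) & (t < window_end)
    tt = np.concatenate([[window_start], t[inside], [window_end]])
    vv = np.concatenate(
        [[np.interp(window_start, t, v)], v[inside], [np.interp(window_end, t, v)]]
    )
    if len(tt) < 2:
        raise ValueError("fewer than 2 points in window")
    return float(np.trapezoid(vv, tt))


def mann_whitney(x, y, mode: str = "auto"):
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    ``mode="exact"`` enumerates the null distribution of U (ties not
    allowed); ``"asymptotic"`` uses the normal approximation with tie and
    continuity corrections; ``"auto"`` picks exact when both samples have at
    most 8 observations and no ties occur.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical in both groups", stacklevel=2)
        u = x.size * y.size / 2
        return float(u), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if method == "exact" and has_ties:
        raise ValueError("exact Mann-Whitney p is undefined with ties")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def logrank(records: pd.DataFrame):
    """Mantel-Cox log-rank test of two survival curves; returns ``(chi2, p)``.

    ``records`` needs columns ``group``, ``time`` and ``event`` (1 = death,
    0 = censored).  Censored subjects contribute to the risk sets up to their
    censoring time but never to the event counts; a subject censored at time
    zero therefore leaves the statistic unchanged.
    """
    for col in ("group", "time", "event"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise ValueError("log-rank requires exactly 2 groups")
    if not records["event"].astype(bool).any():
        raise ValueError("no events observed")
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy(bool)
    g1 = (records["group"] == groups[0]).to_numpy()
    obs_minus_exp = 0.0
    var = 0.0
    for tau in np.unique(t[e]):
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (e & (t == tau)).sum()
        d1 = (e & (t == tau) & g1).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
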