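"""Per-feature mixed-model screen for age-by-treatment interaction.

Each transformed feature is modeled as

    y = b0 + b_age * age + b_trt * 1[yMB] + b_int * age * 1[yMB] + u_mouse + e

with a random intercept per mouse.  With iMB as the reference level, the age
slope in iMB is ``b_age`` and in yMB is ``b_age + b_int``; the Wald p-value
of ``b_int`` tests whether the two treatment arms age differently.  After
Benjamini-Hochberg correction across features, significant features are
classified by the signs of their two slopes: strictly opposite signs mean
the treatment *inverted* the feature's age trajectory, equal signs mean a
concordant (merely attenuated or amplified) trajectory.

Estimation is restricted maximum likelihood.  Because the model has a single
random intercept, REML profiles down to a one-dimensional search over the
variance ratio ``lambda = var(mouse) / var(residual)``; for a given lambda
the fixed effects are generalized least squares with a per-mouse Woodbury
inverse.  This specialized fitter is exact for this model family and is
validated against a general mixed-model implementation in the test suite.

Downstream, significant features are condensed into pathways with a
one-sided hypergeometric enrichment test (pathway sizes 3..500, BH across
tested pathways, reported at raw p <= 0.05 with overlap >= 3) and summarized
as per-treatment mean log2 fold changes between an old and a young timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from rejuvenome.feature_prep import LongitudinalFeatureTable

__all__ = [
    "FeatureScreenResult",
    "fit_feature_lmm",
    "screen",
    "classify_direction",
    "pathway_enrichment",
    "pathway_log2fc",
    "false_discovery_calibration",
]

DIRECTIONS = (
    "inverted",
    "concordant_up",
    "concordant_down",
    "indeterminate",
    "not_significant",
    "fit_failed",
)


@dataclass
class FeatureScreenResult:
    feature_id: str
    beta_age_iMB: float
    beta_age_yMB: float
    p_interaction: float
    fdr_interaction: float
    direction: str


# ---------------------------------------------------------------------------
# Profiled REML for the random-intercept model
# ---------------------------------------------------------------------------


def _group_sums(X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-mouse sufficient statistics for the Woodbury GLS."""
    p = X.shape[1]
    sx = np.zeros((n_groups, p))
    sy = np.zeros(n_groups)
    np.add.at(sx, codes, X)
    np.add.at(sy, codes, y)
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    return sx, sy, sizes


def _gls_pieces(lam, XtX, Xty, yty, sx, sy, sizes):
    # V_i^{-1} = I - c_i J with c_i = lam / (1 + lam * m_i) per mouse block
    c = lam / (1.0 + lam * sizes)
    xtvx = XtX - (sx * c[:, None]).T @ sx
    xtvy = Xty - sx.T @ (c * sy)
    ytvy = yty - np.sum(c * sy**2)
    return xtvx, xtvy, ytvy, c


def _reml_neglog(lam, XtX, Xty, yty, sx, sy, sizes, n, p):
    xtvx, xtvy, ytvy, _ = _gls_pieces(lam, XtX, Xty, yty, sx, sy, sizes)
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return np.inf
    rss = ytvy - beta @ xtvy
    if rss <= 0:
        rss = np.finfo(float).tiny
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    logdet_v = np.sum(np.log1p(lam * sizes))
    return (n - p) * np.log(rss / (n - p)) + logdet_v + logdet_x


def _fit_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """REML fit of ``y = X beta + u_group + e``; returns (beta, se, sigma2_u, sigma2_e)."""
    codes, _ = pd.factorize(groups)
    n_groups = codes.max() + 1
    n, p = X.shape
    XtX, Xty, yty = X.T @ X, X.T @ y, y @ y
    sx, sy, sizes = _group_sums(X, y, codes, n_groups)
    args = (XtX, Xty, yty, sx, sy, sizes, n, p)

    # profile over log-lambda; include the boundary lambda -> 0
    obj = lambda t: _reml_neglog(np.exp(t), *args)
    res = optimize.minimize_scalar(obj, bounds=(-25.0, 25.0), method="bounded")
    lam = float(np.exp(res.x))
    if _reml_neglog(0.0, *args) <= res.fun:
        lam = 0.0

    xtvx, xtvy, ytvy, _ = _gls_pieces(lam, *args[:-2])
    beta = np.linalg.solve(xtvx, xtvy)
    rss = max(ytvy - beta @ xtvy, 0.0)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se, lam * sigma2, sigma2


def _design(table: LongitudinalFeatureTable):
    age = table.meta["age_weeks"].to_numpy(float)
    trt = (table.meta["treatment"] == "yMB").to_numpy(float)  # iMB is reference
    X = np.column_stack([np.ones_like(age), age, trt, age * trt])
    return X, table.meta["mouse_id"].to_numpy()


def fit_feature_lmm(table: LongitudinalFeatureTable, feature_id: str) -> dict:
    """Fit the random-intercept interaction model for one feature.

    Returns a dict with the fixed-effect coefficients, per-treatment age
    slopes, the Wald p-value of the interaction term, the variance
    components, and a convergence flag.
    """
    if table.scale != "transformed":
        raise ValueError("the screen expects a transformed-scale table")
    treatments = set(table.meta["treatment"])
    if len(treatments) < 2:
        raise ValueError("both treatment groups must be present")
    y = table.values[feature_id].to_numpy(float)
    X, groups = _design(table)
    try:
        beta, se, s2_mouse, s2_resid = _fit_random_intercept(y, X, groups)
        ok = bool(np.isfinite(beta).all() and np.isfinite(se).all())
    except np.linalg.LinAlgError:
        beta = se = np.full(4, np.nan)
        s2_mouse = s2_resid = np.nan
        ok = False
    if ok:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
        p_int = float(2 * stats.norm.sf(abs(z[3])))
    else:
        p_int = np.nan
    return {
        "coefficients": dict(
            zip(("intercept", "age", "treatment", "age_treatment"), beta)
        ),
        "slope_iMB": float(beta[1]),
        "slope_yMB": float(beta[1] + beta[3]),
        "p_interaction": p_int,
        "sigma2_mouse": s2_mouse,
        "sigma2_resid": s2_resid,
        "converged": ok,
    }


def classify_direction(slope_yMB: float, slope_iMB: float) -> str:
    """Sign-pattern class of the two per-treatment age slopes."""
    if not (np.isfinite(slope_yMB) and np.isfinite(slope_iMB)):
        raise ValueError("slopes must be finite")
    if slope_yMB == 0 or slope_iMB == 0:
        return "indeterminate"
    if slope_yMB > 0 and slope_iMB > 0:
        return "concordant_up"
    if slope_yMB < 0 and slope_iMB < 0:
        return "concordant_down"
    return "inverted"


def screen(table: LongitudinalFeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Run the interaction screen over every feature of a transformed table.

    BH correction is applied across all converged features; a feature is
    assigned a direction class only where its interaction FDR is at most
    ``alpha``.  Non-converged fits are reported as ``fit_failed`` and are
    excluded from the FDR family.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if table.n_features < 2:
        raise ValueError("screen requires at least 2 features")
    rows = []
    for fid in table.values.columns:
        fit = fit_feature_lmm(table, fid)
        rows.append((fid, fit))
        if not fit["converged"]:
            warnings.warn(f"fit failed for feature {fid}", stacklevel=2)
    pvals = np.array([f["p_interaction"] for _, f in rows])
    conv = np.array([f["converged"] for _, f in rows])
    fdr = np.full(len(rows), np.nan)
    if conv.any():
        fdr[conv] = multipletests(pvals[conv], method="fdr_bh")[1]
    out = []
    for (fid, fit), p, q, ok in zip(rows, pvals, fdr, conv):
        if not ok:
            direction = "fit_failed"
        elif q <= alpha:
            direction = classify_direction(fit["slope_yMB"], fit["slope_iMB"])
        else:
            direction = "not_significant"
        out.append(
            FeatureScreenResult(
                feature_id=fid,
                beta_age_iMB=fit["slope_iMB"],
                beta_age_yMB=fit["slope_yMB"],
                p_interaction=p,
                fdr_interaction=q,
                direction=direction,
            )
        )
    return pd.DataFrame([vars(r) for r in out]).set_index("feature_id")


def false_discovery_calibration(
    n_replicates: int = 50,
    alpha: float = 0.05,
    config=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo calibration of the screen on synthetic tables.

    For each replicate, a fresh table is generated (default design: 200 null
    features and 50 with a true age-by-treatment interaction, 10 mice per
    group, timepoints 8/40/72/120 weeks) and screened at FDR ``alpha``.  A
    flagged feature counts as a false discovery when its true per-treatment
    slopes are equal (no interaction).  Returns one row per replicate with
    the false-discovery proportion and the recovery rate of planted inverted
    features.
    """
    from rejuvenome.synthio import ScreenSimConfig, gen_ko_table

    if config is None:
        config = ScreenSimConfig()
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates) % (2**31)
    rows = []
    for rep_seed in rep_seeds:
        cfg = ScreenSimConfig(**{**vars(config), "seed": int(rep_seed)})
        table, truth = gen_ko_table(cfg)
        res = screen(table, alpha=alpha)
        flagged = res.index[
            ~res["direction"].isin(["not_significant", "fit_failed"])
        ]
        true_int = set(truth.has_interaction.index[truth.has_interaction])
        n_false = sum(f not in true_int for f in flagged)
        fdp = n_false / len(flagged) if len(flagged) else 0.0
        inverted = truth.features_of("inverted")
        recovery = (
            float((res.loc[inverted, "direction"] == "inverted").mean())
            if inverted
            else np.nan
        )
        rows.append((int(rep_seed), len(flagged), n_false, fdp, recovery))
    return pd.DataFrame(
        rows, columns=["seed", "n_flagged", "n_false", "fdp", "inverted_recovery"]
    )


# ---------------------------------------------------------------------------
# Pathway-level summaries
# ---------------------------------------------------------------------------


def pathway_enrichment(
    significant,
    annotation: pd.DataFrame,
    universe=None,
    min_size: int = 3,
    max_size: int = 500,
    p_report: float = 0.05,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of significant features.

    ``annotation`` is a two-column frame (``feature_id``, ``pathway_id``).
    The universe defaults to all annotated features; pathways are tested only
    at sizes ``min_size..max_size`` within the universe, BH-corrected across
    tested pathways, and reported where the raw p-value is at most
    ``p_report`` with at least ``min_overlap`` significant members.
    """
    cols = ["pathway_id", "overlap", "size", "p", "fdr", "members"]
    sig = set(significant)
    if not sig:
        return pd.DataFrame(columns=cols).set_index("pathway_id")
    ann = annotation[["feature_id", "pathway_id"]]
    if universe is None:
        universe = set(ann["feature_id"])
    else:
        universe = set(universe)
    if not sig <= universe:
        raise ValueError("significant set must be contained in the universe")
    ann = ann[ann["feature_id"].isin(universe)]
    M, n_draw = len(universe), len(sig)
    rows = []
    for pid, members in ann.groupby("pathway_id")["feature_id"]:
        mem = set(members)
        if not min_size <= len(mem) <= max_size:
            continue
        k = len(mem & sig)
        p = float(stats.hypergeom.sf(k - 1, M, len(mem), n_draw))
        rows.append((pid, k, len(mem), p, sorted(mem & sig)))
    if not rows:
        return pd.DataFrame(columns=cols).set_index("pathway_id")
    df = pd.DataFrame(rows, columns=["pathway_id", "overlap", "size", "p", "members"])
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df[(df["p"] <= p_report) & (df["overlap"] >= min_overlap)]
    df = df.sort_values("p").set_index("pathway_id")
    return df[["overlap", "size", "p", "fdr", "members"]]


def pathway_log2fc(
    table: LongitudinalFeatureTable,
    members,
    t_old: float = 120,
    t_young: float = 72,
) -> dict:
    """Per-treatment mean log2 fold change of a pathway between two ages.

    For each member feature and treatment, the log2 ratio of the mean
    relative abundance at ``t_old`` over ``t_young`` is computed; the pathway
    value is the arithmetic mean over members.  A group mean of exactly zero
    is replaced by half the smallest non-zero relative abundance in the table
    and flagged.
    """
    if table.scale != "relative":
        raise ValueError("pathway_log2fc expects relative abundances")
    members = list(members)
    missing = [m for m in members if m not in table.values.columns]
    if missing:
        raise KeyError(f"features absent from table: {missing}")
    vals = table.values[members]
    nonzero = vals.to_numpy()[vals.to_numpy() > 0]
    pseudo = nonzero.min() / 2 if nonzero.size else np.nan
    out = {"per_feature": {}, "pathway_mean": {}, "pseudocount_used": False}
    for trt in ("yMB", "iMB"):
        sel = table.meta["treatment"] == trt
        ages = table.meta.loc[sel, "age_weeks"]
        for t in (t_old, t_young):
            if not (ages == t).any():
                raise ValueError(f"timepoint {t} absent in treatment {trt}")
        old = vals[sel & (table.meta["age_weeks"] == t_old)].mean()
        young = vals[sel & (table.meta["age_weeks"] == t_young)].mean()
        if (old == 0).any() or (young == 0).any():
            out["pseudocount_used"] = True
            old = old.replace(0, pseudo)
            young = young.replace(0, pseudo)
        lfc = np.log2(old / young)
        out["per_feature"][trt] = lfc
        out["pathway_mean"][trt] = float(lfc.mean())
    return out
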