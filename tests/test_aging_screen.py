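"""Mixed-model interaction screen, direction classes, enrichment, log2FC."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from statsmodels.regression.mixed_linear_model import MixedLM

from rejuvenome import synthio
from rejuvenome.aging_screen import (
    _design,
    classify_direction,
    fit_feature_lmm,
    pathway_enrichment,
    pathway_log2fc,
    screen,
)
from tests.conftest import make_table


def _noise_free_table(slope_y=0.02, slope_i=-0.03):
    cfg = synthio.ScreenSimConfig(
        n_null=0, n_inverted=3, noise_sd=0.0, mouse_sd=0.0, seed=1
    )
    table, truth = synthio.gen_ko_table(cfg)
    return table, truth


class TestLMMFit:
    def test_noise_free_recovers_planted_slopes(self):
        table, truth = _noise_free_table()
        for fid in table.values.columns:
            fit = fit_feature_lmm(table, fid)
            assert fit["slope_yMB"] == pytest.approx(
                truth.slopes.loc[fid, "slope_yMB"], abs=1e-6
            )
            assert fit["slope_iMB"] == pytest.approx(
                truth.slopes.loc[fid, "slope_iMB"], abs=1e-6
            )

    def test_balanced_noise_free_equals_ols(self):
        table, _ = _noise_free_table()
        X, _groups = _design(table)
        for fid in table.values.columns:
            y = table.values[fid].to_numpy()
            beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
            fit = fit_feature_lmm(table, fid)
            got = np.array(list(fit["coefficients"].values()))
            np.testing.assert_allclose(got, beta_ols, atol=1e-8)

    def test_matches_general_mixed_model_fit(self):
        """Profiled-REML fitter agrees with statsmodels MixedLM (oracle)."""
        cfg = synthio.ScreenSimConfig(n_null=8, n_inverted=4, seed=11)
        table, _ = synthio.gen_ko_table(cfg)
        X, groups = _design(table)
        for fid in table.values.columns:
            mine = fit_feature_lmm(table, fid)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = MixedLM(table.values[fid].to_numpy(), X, groups=groups).fit(
                    reml=True
                )
            np.testing.assert_allclose(
                list(mine["coefficients"].values()), ref.params[:4], atol=1e-7
            )
            assert mine["p_interaction"] == pytest.approx(ref.pvalues[3], abs=5e-3)

    def test_null_interaction_p_uniform_under_permutation(self):
        """Wald p of the interaction is calibrated on permuted-label nulls."""
        from scipy import stats

        rng = np.random.default_rng(4)
        ages = [8.0, 40.0, 72.0, 120.0]
        n_mice = 12
        mice = [f"M{i}" for i in range(n_mice)]
        pvals = []
        for _ in range(200):
            treatments = rng.permutation(["yMB"] * 6 + ["iMB"] * 6)
            values = (
                1.0
                + rng.normal(0, 0.1, n_mice)[:, None]
                + rng.normal(0, 0.2, (n_mice, len(ages)))
            ).reshape(-1, 1)
            table = make_table(
                values,
                ages=ages * n_mice,
                treatments=np.repeat(treatments, len(ages)),
                mice=np.repeat(mice, len(ages)),
                scale="transformed",
            )
            pvals.append(fit_feature_lmm(table, "K00000")["p_interaction"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestScreen:
    def test_bh_adjustment_matches_hand_computation(self):
        cfg = synthio.ScreenSimConfig(n_null=6, n_inverted=3, seed=3)
        table, _ = synthio.gen_ko_table(cfg)
        res = screen(table)
        p = res["p_interaction"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            k = m - rank_from_last
            running = min(running, p[idx] * m / k)
            hand[idx] = running
        np.testing.assert_allclose(res["fdr_interaction"].to_numpy(), hand, rtol=1e-12)

    def test_planted_inverted_features_recovered(self):
        cfg = synthio.ScreenSimConfig(n_null=40, n_inverted=10, seed=5)
        table, truth = synthio.gen_ko_table(cfg)
        res = screen(table, alpha=0.05)
        inv = truth.features_of("inverted")
        assert (res.loc[inv, "direction"] == "inverted").all()

    def test_direction_assigned_only_below_alpha(self):
        cfg = synthio.ScreenSimConfig(n_null=30, n_inverted=5, seed=6)
        table, _ = synthio.gen_ko_table(cfg)
        res = screen(table, alpha=0.05)
        flagged = res["direction"] != "not_significant"
        assert (res.loc[flagged, "fdr_interaction"] <= 0.05).all()
        assert (res.loc[~flagged, "fdr_interaction"] > 0.05).all()
        assert (res["fdr_interaction"] >= res["p_interaction"] - 1e-15).all()

    def test_too_few_features_rejected(self):
        cfg = synthio.ScreenSimConfig(n_null=1, n_inverted=0, seed=0)
        table, _ = synthio.gen_ko_table(cfg)
        with pytest.raises(ValueError, match="at least 2"):
            screen(table)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "sy, si, expected",
        [
            (0.2, -0.3, "inverted"),
            (-0.2, 0.3, "inverted"),
            (0.1, 0.2, "concordant_up"),
            (-0.1, -0.2, "concordant_down"),
            (0.0, -0.2, "indeterminate"),
            (0.3, 0.0, "indeterminate"),
        ],
    )
    def test_sign_logic(self, sy, si, expected):
        assert classify_direction(sy, si) == expected

    def test_label_swap_invariance(self):
        # swapping treatment labels swaps the slopes; the class is unchanged
        # for the unordered classes and stays inverted for inverted pairs
        for sy, si in [(0.2, -0.3), (0.1, 0.2), (-0.5, -0.1)]:
            assert classify_direction(sy, si) == classify_direction(si, sy)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(np.nan, 0.1)


def _enrichment_p_oracle(M, K, n, k):
    """Upper-tail hypergeometric by direct enumeration."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, j) * math.comb(M - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestPathwayEnrichment:
    def _annotation(self, pathways):
        rows = [(f, p) for p, feats in pathways.items() for f in feats]
        return pd.DataFrame(rows, columns=["feature_id", "pathway_id"])

    def test_worked_example(self):
        universe = [f"F{i}" for i in range(20)]
        pathway = universe[:5]
        significant = universe[:4] + universe[10:12]  # overlap 4 of 6
        ann = self._annotation({"P1": pathway})
        res = pathway_enrichment(significant, ann, universe=universe)
        assert res.loc["P1", "overlap"] == 4
        assert res.loc["P1", "p"] == pytest.approx(0.013931888, abs=1e-6)
        assert res.loc["P1", "p"] == pytest.approx(
            _enrichment_p_oracle(20, 5, 6, 4), rel=1e-12
        )

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            M = int(rng.integers(8, 26))
            universe = [f"F{i}" for i in range(M)]
            K = int(rng.integers(3, M))
            n = int(rng.integers(3, M))
            pathway = list(rng.choice(universe, size=K, replace=False))
            significant = list(rng.choice(universe, size=n, replace=False))
            k = len(set(pathway) & set(significant))
            if k < 3:
                continue
            res = pathway_enrichment(
                significant,
                self._annotation({"P": pathway}),
                universe=universe,
                max_size=500,
                p_report=1.0,
            )
            if "P" in res.index:
                assert res.loc["P", "p"] == pytest.approx(
                    _enrichment_p_oracle(M, K, n, k), rel=1e-10
                )

    def test_saturated_pathway_p_one(self):
        universe = [f"F{i}" for i in range(5)]
        ann = self._annotation({"P": universe})
        res = pathway_enrichment(universe, ann, universe=universe, p_report=1.0)
        assert res.loc["P", "p"] == pytest.approx(1.0)

    def test_small_pathway_never_tested(self):
        universe = [f"F{i}" for i in range(10)]
        ann = self._annotation({"tiny": universe[:2], "ok": universe[:4]})
        res = pathway_enrichment(universe[:4], ann, universe=universe, p_report=1.0)
        assert "tiny" not in res.index
        assert "ok" in res.index

    def test_empty_significant_set(self):
        ann = self._annotation({"P": ["F1", "F2", "F3"]})
        assert pathway_enrichment([], ann).empty


class TestPathwayLog2FC:
    def _table(self, means_young, means_old):
        """Table whose group means at 72w/120w are exactly as given."""
        rows, ages, treatments, mice = [], [], [], []
        for trt in ("yMB", "iMB"):
            for t, means in ((72.0, means_young), (120.0, means_old)):
                rows.append(list(means))
                ages.append(t)
                treatments.append(trt)
                mice.append(f"{trt}{t}")
        return make_table(
            rows, ages=ages, treatments=treatments, mice=mice, scale="relative"
        )

    def test_doubling_gives_log2fc_one(self):
        t = self._table([0.02], [0.04])
        out = pathway_log2fc(t, ["K00000"])
        assert out["pathway_mean"]["yMB"] == pytest.approx(1.0)
        assert out["pathway_mean"]["iMB"] == pytest.approx(1.0)

    def test_arithmetic_mean_over_members(self):
        t = self._table([0.1, 0.2], [0.2, 0.1])  # log2FCs are {+1, -1}
        out = pathway_log2fc(t, ["K00000", "K00001"])
        assert out["pathway_mean"]["yMB"] == pytest.approx(0.0)

    def test_hand_mean(self):
        t = self._table([0.01, 0.02, 0.01], [0.02, 0.04, 0.16])  # {1, 1, 4}
        out = pathway_log2fc(t, ["K00000", "K00001", "K00002"])
        assert out["pathway_mean"]["yMB"] == pytest.approx(2.0)

    def test_zero_mean_uses_flagged_pseudocount(self):
        t = self._table([0.0, 0.5], [0.25, 0.5])
        out = pathway_log2fc(t, ["K00000", "K00001"])
        assert out["pseudocount_used"]
        # half the smallest non-zero value (0.25/2 = 0.125) replaces the zero
        assert out["per_feature"]["yMB"]["K00000"] == pytest.approx(1.0)
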