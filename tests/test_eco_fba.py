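"""FBA engine, community co-growth, and relationship classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rejuvenome.eco_fba import (
    RELATIONSHIPS,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_pair,
    classify_all_pairs,
    classify_pair,
    community_frequencies,
    compare_relationship_groups,
    fba,
    pair_growth,
    pair_record,
)
from rejuvenome.synthio.models import KINDS, gen_toy_model_pairs


def chain_model(model_id="chain", uptake=10.0):
    """Minimal A -> biomass chain with uptake bound on the exchange."""
    return MetabolicModel(
        model_id,
        [Metabolite("A_e", "e"), Metabolite("A_c", "c")],
        [
            Reaction("EX_A_e", {"A_e": -1}, lb=-uptake, ub=1000.0),
            Reaction("T_A", {"A_e": -1, "A_c": 1}, lb=-1000.0, ub=1000.0),
            Reaction("BIOMASS", {"A_c": -1}, lb=0.0, ub=1000.0),
        ],
        "BIOMASS",
    )


class TestFBA:
    def test_chain_growth_equals_uptake_bound(self):
        growth, flux, feasible = fba(chain_model(uptake=10.0))
        assert feasible
        assert growth == pytest.approx(10.0, abs=1e-8)

    def test_starvation(self):
        growth, _, feasible = fba(chain_model(uptake=0.0))
        assert feasible
        assert growth == pytest.approx(0.0, abs=1e-9)

    def test_medium_override(self):
        growth, _, _ = fba(chain_model(uptake=10.0), medium={"EX_A_e": 4.0})
        assert growth == pytest.approx(4.0, abs=1e-8)

    def test_scale_covariance(self):
        m = chain_model(uptake=7.0)
        g1, _, _ = fba(m)
        doubled = MetabolicModel(
            "x2",
            m.metabolites,
            [Reaction(r.id, r.stoichiometry, 2 * r.lb, 2 * r.ub) for r in m.reactions],
            "BIOMASS",
        )
        g2, _, _ = fba(doubled)
        assert g2 == pytest.approx(2 * g1, rel=1e-9)

    def test_steady_state_and_bounds_satisfied(self):
        for kind in KINDS:
            m1, _, medium = gen_toy_model_pairs(kind)
            own = {k: v for k, v in medium.items() if k in m1.exchanges}
            growth, flux, feasible = fba(m1, own)
            assert feasible
            scale = max(abs(r.ub) for r in m1.reactions)
            for met in m1.metabolites:
                balance = sum(
                    r.stoichiometry.get(met.id, 0.0) * flux[r.id]
                    for r in m1.reactions
                )
                assert abs(balance) <= 1e-9 * scale
            bounds = {r.id: (r.lb, r.ub) for r in m1.reactions}
            for rid, (lo, hi) in bounds.items():
                if rid in own:
                    lo = -own[rid]
                assert lo - 1e-9 <= flux[rid] <= hi + 1e-9

    def test_unbounded_model_is_a_defect(self):
        m = MetabolicModel(
            "bad",
            [Metabolite("A_c", "c")],
            [
                Reaction("SPAWN", {"A_c": 1}, lb=0.0, ub=np.inf),
                Reaction("BIOMASS", {"A_c": -1}, lb=0.0, ub=np.inf),
            ],
            "BIOMASS",
        )
        with pytest.raises(ValueError, match="unbounded"):
            fba(m)

    def test_agrees_with_cobra_oracle(self):
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("chain")
        a_e = cobra.Metabolite("A_e", compartment="e")
        a_c = cobra.Metabolite("A_c", compartment="c")
        ex = cobra.Reaction("EX_A_e", lower_bound=-10.0, upper_bound=1000.0)
        ex.add_metabolites({a_e: -1})
        t = cobra.Reaction("T_A", lower_bound=-1000.0, upper_bound=1000.0)
        t.add_metabolites({a_e: -1, a_c: 1})
        bm = cobra.Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0)
        bm.add_metabolites({a_c: -1})
        model.add_reactions([ex, t, bm])
        model.objective = "BIOMASS"
        ref = model.optimize().objective_value
        ours, _, _ = fba(chain_model(uptake=10.0))
        assert ours == pytest.approx(ref, rel=1e-9)


class TestBuildPair:
    def test_shared_substrate_total_capped(self):
        m1, m2 = chain_model("a"), chain_model("b")
        community = build_pair(m1, m2, medium={"EX_A_e": 10.0})
        g1, g2 = pair_growth(community)
        assert g1 + g2 == pytest.approx(10.0, abs=1e-6)

    def test_disjoint_substrates_independent(self):
        m1, m2, medium = gen_toy_model_pairs("neutralism")
        rec = pair_record(m1, m2, medium)
        assert rec.g_pair[0] == pytest.approx(rec.g_alone[0], abs=1e-6)
        assert rec.g_pair[1] == pytest.approx(rec.g_alone[1], abs=1e-6)

    def test_consumer_fed_only_in_pair(self):
        m1, m2, medium = gen_toy_model_pairs("commensalism")
        rec = pair_record(m1, m2, medium)
        assert rec.g_alone[1] == pytest.approx(0.0, abs=1e-9)
        assert rec.g_pair[1] > 1.0

    def test_duplicate_model_ids_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_pair(chain_model("same"), chain_model("same"))


class TestPairGrowth:
    def test_degenerate_optimum_reports_midpoint(self):
        # symmetric competition: any split of 10 is optimal -> FVA midpoint 5
        community = build_pair(
            chain_model("a"), chain_model("b"), medium={"EX_A_e": 10.0}
        )
        g1, g2 = pair_growth(community)
        assert g1 == pytest.approx(5.0, abs=1e-5)
        assert g2 == pytest.approx(5.0, abs=1e-5)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "growths, expected",
        [
            ((1, 1, 0.5, 0.5), "competition"),
            ((1, 1, 1, 1), "neutralism"),
            ((1, 0, 1, 0.3), "commensalism"),
            ((1, 1, 2, 2), "mutualism"),
            ((1, 1, 1, 0.4), "amensalism"),
            ((1, 1, 2, 0.4), "exploitation"),
        ],
    )
    def test_sign_patterns(self, growths, expected):
        assert classify_pair(*growths) == expected

    def test_symmetry_under_member_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ga1, ga2, gp1, gp2 = rng.uniform(0, 2, size=4)
            assert classify_pair(ga1, ga2, gp1, gp2) == classify_pair(
                ga2, ga1, gp2, gp1
            )

    def test_exactly_six_classes_reachable(self):
        seen = {
            classify_pair(1.0, 1.0, 1.0 + 0.5 * s1, 1.0 + 0.5 * s2)
            for s1, s2 in itertools.product((-1, 0, 1), repeat=2)
        }
        assert seen == set(RELATIONSHIPS)

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(-1, 1, 1, 1)


class TestGeneratorChain:
    @pytest.mark.parametrize("kind", KINDS)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_chain_returns_intended_class(self, kind, seed):
        m1, m2, medium = gen_toy_model_pairs(kind, seed=seed)
        rec = pair_record(m1, m2, medium)
        assert rec.relationship == kind

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            gen_toy_model_pairs("parasitism")


class TestCommunityFrequencies:
    def _labels(self, ids, label):
        return {frozenset(p): label for p in itertools.combinations(ids, 2)}

    def test_all_competition(self):
        labels = self._labels("abc", "competition")
        ab = pd.DataFrame([[0.5, 0.3, 0.2]], index=["s1"], columns=list("abc"))
        prof = community_frequencies(labels, ab)
        assert prof.loc["s1", "competition"] == pytest.approx(1.0)
        assert prof.loc["s1"].sum() == pytest.approx(1.0)

    def test_single_member_empty_profile(self):
        labels = self._labels("ab", "neutralism")
        ab = pd.DataFrame([[1.0, 0.0]], index=["s1"], columns=list("ab"))
        prof = community_frequencies(labels, ab)
        assert prof.loc["s1"].isna().all()

    def test_hand_tally_four_members(self):
        labels = {
            frozenset("ab"): "competition",
            frozenset("ac"): "competition",
            frozenset("ad"): "mutualism",
            frozenset("bc"): "neutralism",
            frozenset("bd"): "neutralism",
            frozenset("cd"): "neutralism",
        }
        ab = pd.DataFrame([[0.25] * 4], index=["s1"], columns=list("abcd"))
        prof = community_frequencies(labels, ab)
        assert prof.loc["s1", "competition"] == pytest.approx(2 / 6)
        assert prof.loc["s1", "mutualism"] == pytest.approx(1 / 6)
        assert prof.loc["s1", "neutralism"] == pytest.approx(3 / 6)

    def test_detection_threshold(self):
        labels = self._labels("abc", "competition")
        ab = pd.DataFrame([[0.9, 0.1, 0.005]], index=["s1"], columns=list("abc"))
        prof = community_frequencies(labels, ab, detection_threshold=0.01)
        # only a and b detected -> 1 pair
        assert prof.loc["s1", "competition"] == pytest.approx(1.0)


class TestGroupComparison:
    def _profiles(self, vals):
        df = pd.DataFrame(0.0, index=range(len(vals)), columns=RELATIONSHIPS)
        df["competition"] = vals
        df["neutralism"] = 1 - np.asarray(vals)
        return df

    def test_identical_groups_p_one(self):
        prof = self._profiles([0.4, 0.4, 0.4, 0.4])
        with pytest.warns(UserWarning):
            _, p = compare_relationship_groups(
                prof, ["a", "a", "b", "b"], "competition"
            )
        assert p == 1.0

    def test_label_swap_symmetric(self):
        prof = self._profiles([0.1, 0.2, 0.7, 0.9, 0.3, 0.6])
        groups = ["a", "a", "b", "b", "a", "b"]
        swapped = ["b" if g == "a" else "a" for g in groups]
        _, p1 = compare_relationship_groups(prof, groups, "competition")
        _, p2 = compare_relationship_groups(prof, swapped, "competition")
        assert p1 == pytest.approx(p2)

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            lo = rng.uniform(0.1, 0.3, size=8)
            hi = rng.uniform(0.5, 0.8, size=8)
            prof = self._profiles(np.concatenate([lo, hi]))
            _, p = compare_relationship_groups(
                prof, ["y"] * 8 + ["i"] * 8, "competition"
            )
            hits += p < 0.05
        assert hits >= 18
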