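"""Hand-designed metabolic model pairs with known ecological relationships.

Each construction is a minimal "substrate chain" organism: an exchange
reaction supplies an extracellular substrate, a transporter moves it into
the cytosol, and a biomass reaction consumes it (possibly together with a
cross-fed co-substrate, possibly secreting a byproduct).  The pairs are
designed so that the full mono-culture / co-culture FBA chain yields a
specific sign pattern:

==============  =====================================================  ========
kind            construction                                           signs
==============  =====================================================  ========
competition     two identical consumers of one limiting substrate       (-,-)
neutralism      consumers of two disjoint substrates                    (0,0)
commensalism    secretor of a byproduct + obligate consumer of it       (0,+)
mutualism       obligate two-way cross-feeders over a shared substrate  (+,+)
amensalism      grows on A but obligately nibbles B that feeds model 2  (0,-)
exploitation    needs partner's byproduct while nibbling its substrate  (+,-)
==============  =====================================================  ========

The constructions are deterministic; the ``seed`` argument exists for API
uniformity with the other generators and is unused.
"""

from __future__ import annotations

from rejuvenome.eco_fba import MetabolicModel, Metabolite, Reaction

__all__ = ["gen_toy_model_pairs", "KINDS"]

KINDS = (
    "competition",
    "neutralism",
    "commensalism",
    "mutualism",
    "amensalism",
    "exploitation",
)

_UB = 1000.0


def _organism(model_id, biomass_stoich, extracellular):
    """Chain organism: exchanges + reversible transporters + one biomass.

    ``biomass_stoich`` maps cytosolic metabolite ids to biomass-reaction
    coefficients (negative = consumed per unit growth, positive = secreted
    byproduct).  ``extracellular`` lists the metabolites with an exchange
    (uptake closed by default; the medium opens it).
    """
    mets = []
    rxns = []
    for met in extracellular:
        mets.append(Metabolite(f"{met}_e", "e"))
        mets.append(Metabolite(f"{met}_c", "c"))
        # exchange: secretion open, uptake closed until the medium allows it
        rxns.append(Reaction(f"EX_{met}_e", {f"{met}_e": -1}, lb=0.0, ub=_UB))
        rxns.append(
            Reaction(f"T_{met}", {f"{met}_e": -1, f"{met}_c": 1}, lb=-_UB, ub=_UB)
        )
    rxns.append(
        Reaction(
            "BIOMASS",
            {f"{met}_c": coef for met, coef in biomass_stoich.items()},
            lb=0.0,
            ub=_UB,
        )
    )
    return MetabolicModel(model_id, mets, rxns, "BIOMASS")


def gen_toy_model_pairs(kind: str, seed: int = 0):
    """Return ``(model1, model2, shared_medium)`` for one relationship kind."""
    if kind == "competition":
        m1 = _organism("comp1", {"A": -1}, ["A"])
        m2 = _organism("comp2", {"A": -1}, ["A"])
        medium = {"EX_A_e": 10.0}
    elif kind == "neutralism":
        m1 = _organism("neut1", {"A": -1}, ["A"])
        m2 = _organism("neut2", {"B": -1}, ["B"])
        medium = {"EX_A_e": 10.0, "EX_B_e": 10.0}
    elif kind == "commensalism":
        # model 1 grows on A and secretes B; model 2 can only grow on B
        m1 = _organism("comm1", {"A": -1, "B": 1}, ["A", "B"])
        m2 = _organism("comm2", {"B": -1}, ["B"])
        medium = {"EX_A_e": 10.0, "EX_B_e": 0.0}
    elif kind == "mutualism":
        # obligate two-way cross-feeding over the shared substrate A:
        # model 1 needs B (made by 2), model 2 needs C (made by 1)
        m1 = _organism("mut1", {"A": -1, "B": -1, "C": 1}, ["A", "B", "C"])
        m2 = _organism("mut2", {"A": -1, "C": -1, "B": 1}, ["A", "B", "C"])
        medium = {"EX_A_e": 10.0, "EX_B_e": 0.0, "EX_C_e": 0.0}
    elif kind == "amensalism":
        # model 1 is A-limited but obligately consumes a little of B,
        # the sole substrate of model 2; model 1 is unaffected by company
        m1 = _organism("amen1", {"A": -1, "B": -0.1}, ["A", "B"])
        m2 = _organism("amen2", {"B": -1}, ["B"])
        medium = {"EX_A_e": 10.0, "EX_B_e": 10.0}
    elif kind == "exploitation":
        # model 1 needs the byproduct C of model 2 and also nibbles model
        # 2's substrate B: model 1 gains, model 2 loses
        m1 = _organism("expl1", {"B": -0.1, "C": -1}, ["B", "C"])
        m2 = _organism("expl2", {"B": -1, "C": 1}, ["B", "C"])
        medium = {"EX_B_e": 10.0, "EX_C_e": 0.0}
    else:
        raise ValueError(f"unknown relationship kind {kind!r}")
    return m1, m2, medium
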