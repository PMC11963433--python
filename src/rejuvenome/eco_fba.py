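"""Toy flux-balance analysis and pairwise ecological-relationship inference.

A :class:`MetabolicModel` is a small stoichiometric model (metabolites in a
cytosolic or extracellular compartment, bounded reactions, one biomass
objective, and exchange reactions that connect extracellular metabolites to
the environment).  Growth is the optimal biomass flux of the linear program

    maximize  v_biomass   s.t.   S v = 0,   lb <= v <= ub,

solved with the HiGHS solver behind :func:`scipy.optimize.linprog`.

Two models are co-grown by merging them into one community: internal
metabolites and reactions are namespaced per member, the extracellular
compartment is shared, and each environmental resource has a single
community exchange whose bound is applied once — so shared substrates are
contested, and one member's secretions are available to the other.  The
effect of co-growth on each member (growth in the pair minus growth alone,
thresholded into -, 0, +) maps the unordered sign pair onto the six classical
pairwise ecological relationships:

    (+,+) mutualism   (+,0) commensalism  (+,-) exploitation
    (0,0) neutralism  (0,-) amensalism    (-,-) competition

Because the joint-growth optimum is often degenerate (any split of a shared
substrate maximizes the total), the default co-growth protocol maximizes the
summed biomass and then reports each member's midpoint of a flux-variability
analysis at that optimum; an equal-split protocol (each member grown alone on
half the medium) is available as an alternative.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "PairGrowthRecord",
    "fba",
    "build_pair",
    "pair_growth",
    "classify_pair",
    "pair_record",
    "classify_all_pairs",
    "community_frequencies",
    "compare_relationship_groups",
    "RELATIONSHIPS",
    "ANTAGONISTIC",
]

RELATIONSHIPS = (
    "mutualism",
    "commensalism",
    "exploitation",
    "neutralism",
    "amensalism",
    "competition",
)

#: Relationship classes in which at least one member is harmed; pooled for
#: the "antagonistic interactions" group comparison.  Configurable at the
#: call sites that consume it.
ANTAGONISTIC = frozenset({"competition", "amensalism", "exploitation"})

_SIGN_MAP = {
    frozenset({+1}): "mutualism",
    frozenset({+1, 0}): "commensalism",
    frozenset({+1, -1}): "exploitation",
    frozenset({0}): "neutralism",
    frozenset({0, -1}): "amensalism",
    frozenset({-1}): "competition",
}

_DEFAULT_UB = 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str  # "c" (cytosol) or "e" (extracellular)

    def __post_init__(self):
        if self.compartment not in ("c", "e"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict
    lb: float = 0.0
    ub: float = _DEFAULT_UB

    def __post_init__(self):
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lower bound exceeds upper")


@dataclass
class MetabolicModel:
    """Stoichiometric toy model with a biomass objective.

    Exchange reactions are single-metabolite reactions on an extracellular
    metabolite with stoichiometry ``{met: -1}``; negative flux is uptake from
    the environment, positive flux secretion.
    """

    id: str
    metabolites: list
    reactions: list
    biomass: str

    def __post_init__(self):
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            undeclared = set(r.stoichiometry) - met_ids
            if undeclared:
                raise ValueError(
                    f"reaction {r.id} references undeclared metabolites {sorted(undeclared)}"
                )
        if self.biomass not in rxn_ids:
            raise ValueError(f"biomass reaction {self.biomass!r} not found")
        if self.reaction(self.biomass).ub <= 0:
            raise ValueError("biomass reaction must have a positive upper bound")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def exchanges(self) -> list:
        comp = {m.id: m.compartment for m in self.metabolites}
        out = []
        for r in self.reactions:
            if len(r.stoichiometry) == 1:
                (met, coef), = r.stoichiometry.items()
                if comp[met] == "e" and coef == -1:
                    out.append(r.id)
        return out

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "metabolites": [vars(m) for m in self.metabolites],
                "reactions": [
                    {"id": r.id, "stoichiometry": r.stoichiometry, "lb": r.lb, "ub": r.ub}
                    for r in self.reactions
                ],
                "biomass": self.biomass,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MetabolicModel":
        d = json.loads(text)
        return cls(
            id=d["id"],
            metabolites=[Metabolite(**m) for m in d["metabolites"]],
            reactions=[Reaction(**r) for r in d["reactions"]],
            biomass=d["biomass"],
        )


@dataclass
class PairGrowthRecord:
    """Mono- and co-culture growth of an unordered model pair plus its label."""

    model_ids: tuple
    g_alone: tuple
    g_pair: tuple
    effects: tuple  # per-member sign in {-1, 0, +1}
    relationship: str


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------


def _apply_medium(model: MetabolicModel, medium) -> dict:
    """Bounds per reaction after medium overrides (uptake capacity >= 0)."""
    bounds = {r.id: (r.lb, r.ub) for r in model.reactions}
    if medium:
        exch = set(model.exchanges)
        for rid, cap in medium.items():
            if rid not in exch:
                raise KeyError(f"medium names unknown exchange reaction {rid!r}")
            if cap < 0:
                raise ValueError(f"negative uptake capacity for {rid!r}")
            bounds[rid] = (-float(cap), bounds[rid][1])
    return bounds


def _solve(model: MetabolicModel, bounds: dict, objective: dict, sense: str = "max"):
    mets = [m.id for m in model.metabolites]
    midx = {m: i for i, m in enumerate(mets)}
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rids)))
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            S[midx[met], j] = coef
    c = np.zeros(len(rids))
    for rid, w in objective.items():
        c[rids.index(rid)] = -w if sense == "max" else w
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(len(mets)),
        bounds=[bounds[r] for r in rids],
        method="highs",
    )
    if res.status == 3:
        raise ValueError(f"model {model.id}: unbounded objective (model defect)")
    if res.status != 0:
        return None, None
    flux = pd.Series(res.x, index=rids)
    value = float(sum(w * flux[rid] for rid, w in objective.items()))
    return value, flux


def fba(model: MetabolicModel, medium=None):
    """Maximize biomass flux under steady state and bounds.

    Returns ``(growth, fluxes, feasible)``; an infeasible problem yields
    growth 0 with ``feasible=False``.  ``medium`` maps exchange-reaction ids
    to maximum uptake capacities (applied as the lower bound ``-capacity``).
    """
    bounds = _apply_medium(model, medium)
    growth, flux = _solve(model, bounds, {model.biomass: 1.0})
    if growth is None:
        return 0.0, None, False
    return growth, flux, True


# ---------------------------------------------------------------------------
# Community construction and co-growth
# ---------------------------------------------------------------------------


def build_pair(m1: MetabolicModel, m2: MetabolicModel, medium=None) -> MetabolicModel:
    """Merge two models into a community sharing one extracellular pool.

    Internal metabolites and non-exchange reactions are namespaced as
    ``<model>:<id>``; extracellular metabolites keep their ids and are
    shared.  Each extracellular metabolite gets exactly one community
    exchange reaction, so medium bounds apply once and resources are
    contested.  Member biomass reactions are kept (namespaced).
    """
    if m1.id == m2.id:
        raise ValueError("community members need distinct model ids")
    mets, rxns = {}, []
    exch_bounds = {}
    for m in (m1, m2):
        comp = {x.id: x.compartment for x in m.metabolites}
        exch = set(m.exchanges)
        for x in m.metabolites:
            key = x.id if x.compartment == "e" else f"{m.id}:{x.id}"
            if key in mets and mets[key].compartment != x.compartment:
                raise ValueError(f"metabolite id collision after namespacing: {key}")
            mets[key] = Metabolite(key, x.compartment)
        for r in m.reactions:
            if r.id in exch:
                (met,) = r.stoichiometry
                lo, hi = exch_bounds.get(met, (0.0, 0.0))
                # exchange capacities are pooled conservatively: the widest
                # secretion bound, uptake set by the shared medium below
                exch_bounds[met] = (min(lo, r.lb), max(hi, r.ub))
                continue
            stoich = {
                (k if comp[k] == "e" else f"{m.id}:{k}"): v
                for k, v in r.stoichiometry.items()
            }
            rxns.append(Reaction(f"{m.id}:{r.id}", stoich, r.lb, r.ub))
    for met, (lo, hi) in exch_bounds.items():
        rxns.append(Reaction(f"EX_{met}", {met: -1}, lo, hi))
    community = MetabolicModel(
        id=f"{m1.id}|{m2.id}",
        metabolites=list(mets.values()),
        reactions=rxns,
        biomass=f"{m1.id}:{m1.biomass}",
    )
    community._member_biomass = (f"{m1.id}:{m1.biomass}", f"{m2.id}:{m2.biomass}")
    if medium:
        community_rids = {r.id for r in community.reactions}
        for rid, cap in medium.items():
            met = rid[3:] if rid.startswith("EX_") else rid
            crid = f"EX_{met}"
            if crid not in community_rids:
                # a shared environment may offer substrates this particular
                # pair cannot exchange; those entries are simply irrelevant
                continue
            community.reaction(crid).lb = -float(cap)
    return community


def pair_growth(community: MetabolicModel, protocol: str = "joint-fva", tol: float = 1e-9):
    """Co-culture growth of both members of a community model.

    ``joint-fva``: maximize the summed biomass, then report each member's
    midpoint of its flux-variability range at that optimum (deterministic
    under degenerate optima).  Returns ``(g1, g2)``; an infeasible community
    yields ``(0.0, 0.0)``.
    """
    b1, b2 = community._member_biomass
    if protocol != "joint-fva":
        raise ValueError(f"unknown co-growth protocol {protocol!r}")
    bounds = {r.id: (r.lb, r.ub) for r in community.reactions}
    total, flux = _solve(community, bounds, {b1: 1.0, b2: 1.0})
    if total is None:
        return 0.0, 0.0
    # pin the joint optimum (with slack for LP noise) via the biomass bounds
    # trick: add the constraint b1 + b2 >= total - slack as a pseudo reaction
    # is not expressible in bounds, so re-solve with an explicit row.
    g = []
    for target in (b1, b2):
        lo = _fva_bound(community, bounds, (b1, b2), total, target, "min", tol)
        hi = _fva_bound(community, bounds, (b1, b2), total, target, "max", tol)
        g.append(0.5 * (lo + hi))
    return float(g[0]), float(g[1])


def _fva_bound(model, bounds, biomasses, total, target, sense, tol):
    mets = [m.id for m in model.metabolites]
    midx = {m: i for i, m in enumerate(mets)}
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rids)))
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            S[midx[met], j] = coef
    row = np.zeros(len(rids))
    for b in biomasses:
        row[rids.index(b)] = -1.0  # -(b1+b2) <= -(total - slack)
    slack = tol * max(1.0, abs(total))
    c = np.zeros(len(rids))
    c[rids.index(target)] = 1.0 if sense == "min" else -1.0
    res = linprog(
        c,
        A_ub=row[None, :],
        b_ub=[-(total - slack)],
        A_eq=S,
        b_eq=np.zeros(len(mets)),
        bounds=[bounds[r] for r in rids],
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"FVA subproblem failed with status {res.status}")
    val = res.x[rids.index(target)]
    return float(val)


def classify_pair(
    g_alone1: float,
    g_alone2: float,
    g_pair1: float,
    g_pair2: float,
    tol_rel: float = 1e-6,
    tol_abs: float = 1e-9,
) -> str:
    """Map the two co-growth effects onto one of the six relationships.

    An effect within ``max(tol_abs, tol_rel * g_alone)`` of zero counts as
    neutral; the unordered sign pair selects the class, so the result is
    invariant to swapping the members.
    """
    if min(g_alone1, g_alone2, g_pair1, g_pair2) < 0:
        raise ValueError("growth rates must be non-negative")
    signs = []
    for ga, gp in ((g_alone1, g_pair1), (g_alone2, g_pair2)):
        eff = gp - ga
        band = max(tol_abs, tol_rel * ga)
        signs.append(0 if abs(eff) <= band else (1 if eff > 0 else -1))
    return _SIGN_MAP[frozenset(signs)]


def pair_record(
    m1: MetabolicModel,
    m2: MetabolicModel,
    medium=None,
    protocol: str = "joint-fva",
    tol_rel: float = 1e-6,
    tol_abs: float = 1e-9,
) -> PairGrowthRecord:
    """Full chain: mono-culture FBA, co-growth, and classification.

    The shared medium may name substrates a member cannot exchange; for the
    mono-culture runs it is filtered to each model's own exchange reactions.
    """
    def _own(model):
        if not medium:
            return medium
        exch = set(model.exchanges)
        return {k: v for k, v in medium.items() if k in exch}

    ga1, _, _ = fba(m1, _own(m1))
    ga2, _, _ = fba(m2, _own(m2))
    community = build_pair(m1, m2, medium)
    gp1, gp2 = pair_growth(community, protocol=protocol)
    rel = classify_pair(ga1, ga2, gp1, gp2, tol_rel=tol_rel, tol_abs=tol_abs)
    signs = tuple(
        0 if abs(gp - ga) <= max(tol_abs, tol_rel * ga) else (1 if gp > ga else -1)
        for ga, gp in ((ga1, gp1), (ga2, gp2))
    )
    return PairGrowthRecord(
        model_ids=(m1.id, m2.id),
        g_alone=(ga1, ga2),
        g_pair=(gp1, gp2),
        effects=signs,
        relationship=rel,
    )


def classify_all_pairs(models, medium=None, protocol: str = "joint-fva") -> dict:
    """Relationship label for every unordered pair of models."""
    out = {}
    for m1, m2 in itertools.combinations(models, 2):
        rec = pair_record(m1, m2, medium=medium, protocol=protocol)
        out[frozenset({m1.id, m2.id})] = rec.relationship
    return out


def community_frequencies(
    pair_labels: dict,
    abundance: pd.DataFrame,
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-sample relationship frequencies among detected community members.

    ``abundance`` holds relative abundances (samples x model ids); members
    above ``detection_threshold`` are considered present.  For each sample
    the unordered pairs of present members are tallied by their relationship
    label; frequencies are counts over the number of pairs.  Samples with
    fewer than two detected members get an all-NaN row.
    """
    rows = {}
    for sample, ab in abundance.iterrows():
        present = list(ab.index[ab > detection_threshold])
        counts = dict.fromkeys(RELATIONSHIPS, 0)
        n_pairs = 0
        for a, b in itertools.combinations(present, 2):
            rel = pair_labels[frozenset({a, b})]
            counts[rel] += 1
            n_pairs += 1
        if n_pairs == 0:
            rows[sample] = {rel: np.nan for rel in RELATIONSHIPS}
        else:
            rows[sample] = {rel: counts[rel] / n_pairs for rel in RELATIONSHIPS}
    return pd.DataFrame.from_dict(rows, orient="index")[list(RELATIONSHIPS)]


def compare_relationship_groups(
    profiles: pd.DataFrame,
    groups,
    relationship=ANTAGONISTIC,
):
    """Mann-Whitney comparison of a relationship frequency between two groups.

    ``relationship`` may be a single class name or a set of classes whose
    frequencies are summed (default: the antagonistic classes).  Returns
    ``(U, p)``.
    """
    from rejuvenome.phenotype_stats import mann_whitney

    if isinstance(relationship, str):
        cols = [relationship]
    else:
        cols = sorted(relationship)
    vals = profiles[cols].sum(axis=1)
    groups = pd.Series(np.asarray(groups), index=profiles.index)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    x = vals[groups == labels[0]].dropna()
    y = vals[groups == labels[1]].dropna()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 samples per group")
    return mann_whitney(x.to_numpy(), y.to_numpy())
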