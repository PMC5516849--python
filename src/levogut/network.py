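"""Enterocyte stoichiometric model and the levodopa transport module.

The enterocyte (small-intestinal epithelial cell) is represented as a
constraint-based metabolic network with three core compartments — intestinal
lumen ``l``, cytosol ``c`` and basolateral/blood side ``b`` — over the 20
proteinogenic amino acids plus cystine and ornithine.  Levodopa transport
follows the three-carrier scheme of the gut wall:

* a shared luminal antiporter (dibasic + neutral amino-acid carrier) that
  exchanges luminal levodopa for cytosolic amino acids — the site of
  competition between dietary amino acids and the drug;
* a basolateral antiporter (neutral amino-acid exchanger) secreting
  cytosolic levodopa against basolateral amino acids — the site of
  trans-stimulation by systemic amino acids;
* a basolateral uniporter (aromatic amino-acid carrier) carrying the
  remaining levodopa efflux.

Four fifths of basolateral levodopa secretion is routed through the
uniporter and one fifth through the antiporter; this split is enforced as a
linear coupling constraint, so it holds in every flux solution.

The module adds exactly 36 reactions: 20 luminal antiport exchanges,
13 basolateral antiport exchanges, the basolateral uniporter, and one
luminal plus one basolateral boundary exchange for levodopa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import cobra
import pandas as pd
from cobra import Metabolite, Model, Reaction

BIG = 1000.0

#: The 22 species carried by the reduced network.
AMINO_ACIDS: tuple[str, ...] = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
    "cystine", "orn",
)

#: Molecular weights, mg/mmol (free amino acids; cystine is the dimer).
AA_MW: dict[str, float] = {
    "ala": 89.09, "arg": 174.20, "asn": 132.12, "asp": 133.10, "cys": 121.16,
    "gln": 146.15, "glu": 147.13, "gly": 75.07, "his": 155.15, "ile": 131.17,
    "leu": 131.17, "lys": 146.19, "met": 149.21, "phe": 165.19, "pro": 115.13,
    "ser": 105.09, "thr": 119.12, "trp": 204.23, "tyr": 181.19, "val": 117.15,
    "cystine": 240.30, "orn": 132.16,
}

# Luminal-carrier affinity ranks (1 = highest).  Only the printed anchors —
# cystine highest, ornithine lowest — are fixed by measurement; the interior
# order (dibasic and large neutrals high, small polar amino acids low) is a
# model choice and is config-visible through the catalog.
_DEFAULT_LUMINAL_RANKS: dict[str, int] = {
    "cystine": 1, "arg": 2, "lys": 3, "leu": 4, "phe": 5, "met": 6, "ile": 7,
    "val": 8, "trp": 9, "tyr": 10, "his": 11, "cys": 12, "ala": 13, "gln": 14,
    "gly": 15, "pro": 16, "thr": 17, "ser": 18, "asn": 19, "orn": 20,
}

#: Neutral amino acids exchanged by the basolateral antiporter.
_BASOLATERAL_ANTIPORT: tuple[str, ...] = (
    "ala", "ser", "thr", "asn", "gln", "gly", "pro", "cys", "leu", "ile",
    "val", "met", "his",
)

#: Aromatic substrates of the basolateral uniporter.
_UNIPORTER: tuple[str, ...] = ("phe", "tyr", "trp")

#: Large neutral amino acids sharing the blood-brain-barrier carrier.
_BRAIN_LNAA: tuple[str, ...] = ("leu", "ile", "val", "met", "phe", "trp",
                                "tyr", "his")


class NetworkError(ValueError):
    """Structural error in a stoichiometric network operation."""


@dataclass(frozen=True)
class TransporterCatalog:
    """Carrier substrate sets, affinity ranks and the secretion split.

    ``luminal_affinity`` ranks the 20 dibasic + neutral substrates of the
    shared luminal carrier (1 = highest affinity); levodopa itself competes
    with rank ``levodopa_rank``.  Rank r maps to weight 2^-r when the shared
    capacity is allocated.  ``renal_affinity`` lists the amino acids that
    share the renal elimination carrier with levodopa (the neutral set;
    acidic amino acids use a separate system and do not interact).
    """

    luminal_affinity: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_LUMINAL_RANKS))
    levodopa_rank: int = 15
    basolateral_antiporter: tuple[str, ...] = _BASOLATERAL_ANTIPORT
    basolateral_uniporter: tuple[str, ...] = _UNIPORTER
    brain_carrier: tuple[str, ...] = _BRAIN_LNAA
    renal_affinity: tuple[str, ...] = _BASOLATERAL_ANTIPORT
    split_fraction_uniporter: float = 0.8

    def validate(self) -> None:
        ranks = self.luminal_affinity
        if len(ranks) != 20:
            raise NetworkError("luminal carrier must list exactly 20 substrates")
        ordered = sorted(ranks, key=ranks.get)
        if ordered[0] != "cystine":
            raise NetworkError("cystine must rank highest on the luminal carrier")
        if ordered[-1] != "orn":
            raise NetworkError("ornithine must rank lowest on the luminal carrier")
        if not 0.0 < self.split_fraction_uniporter < 1.0:
            raise NetworkError("split_fraction_uniporter must lie in (0, 1)")
        unknown = set(ranks) - set(AMINO_ACIDS)
        if unknown:
            raise NetworkError(f"unknown luminal substrates: {sorted(unknown)}")

    def weight(self, species: str) -> float:
        """Geometric affinity weight 2^-rank of a luminal substrate."""
        return 2.0 ** (-self.luminal_affinity[species])

    @property
    def levodopa_weight(self) -> float:
        return 2.0 ** (-self.levodopa_rank)


@dataclass
class FluxSolution:
    """Outcome of a flux-balance solve."""

    status: str
    objective_value: Optional[float]
    fluxes: Optional[pd.Series]
    diagnostic: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class StoichiometricNetwork:
    """A cobra model plus the names of its coupling constraints."""

    model: Model
    catalog: Optional[TransporterCatalog] = None

    @property
    def n_reactions(self) -> int:
        return len(self.model.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.model.metabolites)

    def has_levodopa_module(self) -> bool:
        return "levodopa_c" in {m.id for m in self.model.metabolites}

    def has_brain_kidney(self) -> bool:
        return "levodopa_brain" in {m.id for m in self.model.metabolites}

    def constraint(self, name: str):
        return self.model.solver.constraints[name]

    def copy(self) -> "StoichiometricNetwork":
        return StoichiometricNetwork(model=self.model.copy(), catalog=self.catalog)


# --------------------------------------------------------------------------
# construction

def build_reduced_siec(catalog: Optional[TransporterCatalog] = None) -> StoichiometricNetwork:
    """Deterministic reduced enterocyte network over 22 amino-acid species.

    Each species gets a luminal exchange, an apical uptake, a reversible
    basolateral transport and a basolateral exchange; a lumped biomass /
    maintenance demand consumes a fixed amino-acid blend.  The network is a
    desk-scale, synthetic stand-in for the published genome-scale enterocyte
    reconstruction; the levodopa transport module attaches to either.
    """
    catalog = catalog or TransporterCatalog()
    catalog.validate()
    model = Model("siec_reduced")
    model.compartments = {"l": "lumen", "c": "cytosol", "b": "basolateral"}

    for aa in AMINO_ACIDS:
        mets = {
            comp: Metabolite(f"{aa}_{comp}", name=f"{aa} [{comp}]", compartment=comp)
            for comp in ("l", "c", "b")
        }
        ex_l = Reaction(f"EX_{aa}_l", lower_bound=-10.0, upper_bound=BIG)
        ex_l.add_metabolites({mets["l"]: -1.0})
        upt = Reaction(f"T_{aa}_lc", lower_bound=0.0, upper_bound=BIG)
        upt.add_metabolites({mets["l"]: -1.0, mets["c"]: 1.0})
        baso = Reaction(f"T_{aa}_cb", lower_bound=-BIG, upper_bound=BIG)
        baso.add_metabolites({mets["c"]: -1.0, mets["b"]: 1.0})
        ex_b = Reaction(f"EX_{aa}_b", lower_bound=-10.0, upper_bound=BIG)
        ex_b.add_metabolites({mets["b"]: -1.0})
        model.add_reactions([ex_l, upt, baso, ex_b])

    # Interconversions keeping biomass feasible on partial diets.
    conv = [("ser", "gly"), ("glu", "gln"), ("asp", "asn")]
    for a, b in conv:
        r = Reaction(f"CONV_{a}_{b}", lower_bound=-BIG, upper_bound=BIG)
        r.add_metabolites({model.metabolites.get_by_id(f"{a}_c"): -1.0,
                           model.metabolites.get_by_id(f"{b}_c"): 1.0})
        model.add_reactions([r])

    biomass = Reaction("BIOMASS_maintenance", lower_bound=0.0, upper_bound=BIG)
    blend = {"ala": 0.1, "gln": 0.2, "gly": 0.1, "leu": 0.1, "ser": 0.1,
             "glu": 0.2, "asp": 0.1, "lys": 0.1}
    biomass.add_metabolites(
        {model.metabolites.get_by_id(f"{aa}_c"): -c for aa, c in blend.items()}
    )
    model.add_reactions([biomass])
    model.objective = "BIOMASS_maintenance"
    return StoichiometricNetwork(model=model, catalog=catalog)


def _attach_coupling_constraints(model: Model, catalog: TransporterCatalog,
                                 v_t: float = 15.0,
                                 baso_cap: float = BIG) -> None:
    """Add the carrier-capacity and secretion-split coupling constraints."""
    prob = model.problem
    lum = [model.reactions.get_by_id(f"LDOPA_LUM_ANTIPORT_{aa}").flux_expression
           for aa in sorted(catalog.luminal_affinity)]
    cap = prob.Constraint(sum(lum), lb=0.0, ub=v_t, name="luminal_carrier_cap")

    baso = [model.reactions.get_by_id(f"LDOPA_BASO_ANTIPORT_{aa}").flux_expression
            for aa in catalog.basolateral_antiporter]
    baso_sum = sum(baso)
    anti_cap = prob.Constraint(baso_sum, lb=0.0, ub=baso_cap,
                               name="baso_antiporter_cap")

    f = catalog.split_fraction_uniporter
    uni = model.reactions.get_by_id("LDOPA_BASO_UNIPORT").flux_expression
    # v_uni * (1 - f) = f * v_anti  <=>  uniporter carries fraction f.
    split = prob.Constraint((1.0 - f) * uni - f * baso_sum, lb=0.0, ub=0.0,
                            name="levodopa_secretion_split")
    model.add_cons_vars([cap, anti_cap, split])


def add_levodopa_module(net: StoichiometricNetwork,
                        catalog: Optional[TransporterCatalog] = None,
                        v_t: float = 15.0) -> StoichiometricNetwork:
    """Attach the 36-reaction levodopa transport module to *net* (in place).

    Raises on duplicate application.
    """
    if net.has_levodopa_module():
        raise NetworkError("levodopa module already present")
    catalog = catalog or net.catalog or TransporterCatalog()
    catalog.validate()
    model = net.model

    mets = {comp: Metabolite(f"levodopa_{comp}", name=f"levodopa [{comp}]",
                             compartment=comp) for comp in ("l", "c", "b")}
    model.add_metabolites(list(mets.values()))

    reactions = []
    for aa in sorted(catalog.luminal_affinity):
        r = Reaction(f"LDOPA_LUM_ANTIPORT_{aa}", lower_bound=0.0, upper_bound=BIG)
        r.add_metabolites({
            mets["l"]: -1.0,
            model.metabolites.get_by_id(f"{aa}_c"): -1.0,
            mets["c"]: 1.0,
            model.metabolites.get_by_id(f"{aa}_l"): 1.0,
        })
        reactions.append(r)
    for aa in catalog.basolateral_antiporter:
        r = Reaction(f"LDOPA_BASO_ANTIPORT_{aa}", lower_bound=0.0, upper_bound=BIG)
        r.add_metabolites({
            mets["c"]: -1.0,
            model.metabolites.get_by_id(f"{aa}_b"): -1.0,
            mets["b"]: 1.0,
            model.metabolites.get_by_id(f"{aa}_c"): 1.0,
        })
        reactions.append(r)
    uni = Reaction("LDOPA_BASO_UNIPORT", lower_bound=0.0, upper_bound=BIG)
    uni.add_metabolites({mets["c"]: -1.0, mets["b"]: 1.0})
    ex_l = Reaction("EX_levodopa_l", lower_bound=0.0, upper_bound=BIG)
    ex_l.add_metabolites({mets["l"]: -1.0})
    ex_b = Reaction("EX_levodopa_b", lower_bound=0.0, upper_bound=BIG)
    ex_b.add_metabolites({mets["b"]: -1.0})
    reactions.extend([uni, ex_l, ex_b])
    assert len(reactions) == 36
    model.add_reactions(reactions)

    _attach_coupling_constraints(model, catalog, v_t=v_t)
    net.catalog = catalog
    return net


def extend_brain_kidney(net: StoichiometricNetwork) -> StoichiometricNetwork:
    """Extend the enterocyte model with systemic, brain and renal routes.

    Adds a systemic levodopa pool fed from the basolateral side, an
    enterocyte consumption route (gut-wall metabolism), a brain-delivery
    reaction across the blood-brain barrier (shared with large neutral
    amino acids), a renal elimination reaction (shared with neutral amino
    acids), and a residual systemic sink.
    """
    if not net.has_levodopa_module():
        raise NetworkError("levodopa module must be added before the extension")
    if net.has_brain_kidney():
        raise NetworkError("brain/kidney extension already present")
    model = net.model
    catalog = net.catalog or TransporterCatalog()

    m_sys = Metabolite("levodopa_sys", compartment="s")
    m_brain = Metabolite("levodopa_brain", compartment="brain")
    m_urine = Metabolite("levodopa_u", compartment="u")
    model.add_metabolites([m_sys, m_brain, m_urine])

    ldopa_b = model.metabolites.get_by_id("levodopa_b")
    ldopa_c = model.metabolites.get_by_id("levodopa_c")

    rxns = []
    deliver = Reaction("LDOPA_SYS_DELIVERY", lower_bound=0.0, upper_bound=BIG)
    deliver.add_metabolites({ldopa_b: -1.0, m_sys: 1.0})
    gutmet = Reaction("LDOPA_GUTWALL_MET", lower_bound=0.0, upper_bound=BIG)
    gutmet.add_metabolites({ldopa_c: -1.0})
    renal = Reaction("LDOPA_RENAL_ELIM", lower_bound=0.0, upper_bound=BIG)
    renal.add_metabolites({m_sys: -1.0, m_urine: 1.0})
    brain = Reaction("LDOPA_BRAIN_UPTAKE", lower_bound=0.0, upper_bound=BIG)
    brain.add_metabolites({m_sys: -1.0, m_brain: 1.0})
    sink_s = Reaction("SINK_levodopa_sys", lower_bound=0.0, upper_bound=BIG)
    sink_s.add_metabolites({m_sys: -1.0})
    ex_brain = Reaction("EX_levodopa_brain", lower_bound=0.0, upper_bound=BIG)
    ex_brain.add_metabolites({m_brain: -1.0})
    ex_u = Reaction("EX_levodopa_u", lower_bound=0.0, upper_bound=BIG)
    ex_u.add_metabolites({m_urine: -1.0})
    rxns += [deliver, gutmet, renal, brain, sink_s, ex_brain, ex_u]

    for aa in catalog.renal_affinity:
        r = Reaction(f"RENAL_ELIM_{aa}", lower_bound=0.0, upper_bound=BIG)
        r.add_metabolites({model.metabolites.get_by_id(f"{aa}_b"): -1.0})
        rxns.append(r)
    for aa in catalog.brain_carrier:
        r = Reaction(f"BRAIN_UPTAKE_{aa}", lower_bound=0.0, upper_bound=BIG)
        r.add_metabolites({model.metabolites.get_by_id(f"{aa}_b"): -1.0})
        rxns.append(r)
    model.add_reactions(rxns)
    return net


# --------------------------------------------------------------------------
# FBA

def fba(net: StoichiometricNetwork, objective: str,
        extra_bounds: Optional[Mapping[str, tuple[float, float]]] = None,
        maximize: bool = True,
        minimize_total_flux: bool = True) -> FluxSolution:
    """Solve flux balance analysis for *objective* (a reaction id).

    Alternate optima are resolved lexicographically: the objective optimum is
    fixed, then the total absolute flux is minimised, so the returned flux
    vector is deterministic across solvers.
    """
    model = net.model
    if objective not in model.reactions:
        raise NetworkError(f"objective reaction {objective!r} not in network")
    with model:
        if extra_bounds:
            for rid, (lb, ub) in extra_bounds.items():
                if rid in model.reactions:
                    model.reactions.get_by_id(rid).bounds = (lb, ub)
                elif rid in model.solver.constraints:
                    # Coupling-constraint bound update (e.g. carrier caps).
                    cons = model.solver.constraints[rid]
                    cons.lb, cons.ub = lb, ub
                else:
                    raise NetworkError(f"unknown reaction or constraint {rid!r}")
        model.objective = objective
        model.objective_direction = "max" if maximize else "min"
        if minimize_total_flux:
            try:
                sol = cobra.flux_analysis.pfba(model, fraction_of_optimum=1.0)
            except Exception as exc:  # infeasible or unbounded
                return FluxSolution(status="infeasible", objective_value=None,
                                    fluxes=None, diagnostic=str(exc))
            value = float(sol.fluxes[objective])
            return FluxSolution(status="optimal", objective_value=value,
                                fluxes=sol.fluxes)
        sol = model.optimize()
        if sol.status != "optimal":
            return FluxSolution(status=sol.status, objective_value=None,
                                fluxes=None,
                                diagnostic=f"solver status {sol.status}")
        return FluxSolution(status="optimal",
                            objective_value=float(sol.objective_value),
                            fluxes=sol.fluxes)


def apply_competition_bounds(net: StoichiometricNetwork,
                             luminal_aa_amounts: Mapping[str, float],
                             levodopa_lumen: float,
                             catalog: Optional[TransporterCatalog] = None,
                             v_t: float = 15.0) -> dict[str, tuple[float, float]]:
    """Affinity-weighted allocation of the shared luminal carrier.

    The carrier capacity ``v_t`` (mmol/gDW/h) is split between levodopa and
    the competing amino acids in proportion to weight x amount; with no
    amino acids present the full capacity goes to levodopa.  Returns a bound
    map suitable for :func:`fba` (keyed by the carrier-cap constraint).
    """
    catalog = catalog or net.catalog or TransporterCatalog()
    if levodopa_lumen < 0 or any(a < 0 for a in luminal_aa_amounts.values()):
        raise ValueError("amounts must be nonnegative")
    unknown = set(luminal_aa_amounts) - set(catalog.luminal_affinity)
    if unknown:
        raise NetworkError(f"unknown luminal species: {sorted(unknown)}")
    competitor = sum(catalog.weight(aa) * amt
                     for aa, amt in luminal_aa_amounts.items())
    if competitor <= 0.0:
        share = v_t
    else:
        own = catalog.levodopa_weight * levodopa_lumen
        share = v_t * own / (own + competitor)
    return {"luminal_carrier_cap": (0.0, share)}


# --------------------------------------------------------------------------
# SBML round trip

def write_network(net: StoichiometricNetwork, path: str) -> None:
    """Write the network as SBML level 3 with flux bounds."""
    cobra.io.write_sbml_model(net.model, path)


def load_network(path: str, catalog: Optional[TransporterCatalog] = None,
                 v_t: float = 15.0) -> StoichiometricNetwork:
    """Load an SBML network; re-attach coupling constraints if the levodopa
    module is present (linear couplings are not part of SBML)."""
    try:
        model = cobra.io.read_sbml_model(path)
    except Exception as exc:
        raise NetworkError(f"failed to parse SBML at {path}: {exc}") from exc
    net = StoichiometricNetwork(model=model, catalog=catalog)
    if net.has_levodopa_module():
        cat = catalog or TransporterCatalog()
        _attach_coupling_constraints(model, cat, v_t=v_t)
        net.catalog = cat
    return net
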