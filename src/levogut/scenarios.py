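"""Dietary scenarios, efficacy-threshold scoring and amino-acid ranking.

The scenarios encode the clinically motivated dosing/diet patterns:

* ``ac`` — ante cibum: levodopa on an empty stomach, fasted physiology;
* ``fed_aproteic`` / ``fed_proteic`` — dose with a meal (fed physiology),
  without or with its protein-derived amino-acid load;
* ``lpd`` — low-protein diet: dose taken before each meal (fasted-at-dose
  physiology), with the per-meal protein allowance present in the lumen;
  single-amino-acid variants (``lpd_cystine``, ``lpd_ornithine``) probe the
  extremes of the luminal-carrier affinity order;
* ``prd`` — protein redistribution diet: the daily protein allowance was
  moved to the previous evening, so the day starts with elevated plasma
  amino acids (trans-stimulation) and no luminal load;
* ``serine_rich`` — ante cibum dosing followed by a serine-rich meal one
  hour after each dose, loading the plasma pool with a non-competing
  antiporter substrate.

Scenario value is scored as the area under the plasma curve above
stage-specific efficacy thresholds (Hoehn-Yahr 1-4), and reported as a
relative change against the reference (first) scenario.

The amino-acid ranking runs the extended enterocyte-kidney-brain network
(sIEC*) at a fixed luminal levodopa influx, applies the fasting-state
calibration (66% of the influx reaches the systemic circulation; 30% of the
absorbed flux is eliminated renally) and maximises the blood-brain-barrier
delivery reaction under co-administration of each amino acid in turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_CONFIG,
    catalog_from_config,
    coupling_from_config,
    kinetics_from_config,
    physiology_from_config,
)
from .coupling import CoupledResult, DietSchedule, run_coupled
from .network import (
    AA_MW,
    AMINO_ACIDS,
    NetworkError,
    StoichiometricNetwork,
    TransporterCatalog,
    add_levodopa_module,
    apply_competition_bounds,
    build_reduced_siec,
    extend_brain_kidney,
    fba,
)
from .params import DoseRegimen, SI_SEGMENTS
from .pbpk import auc_above_threshold, build_wb_acat, cmax_tmax

SCENARIO_NAMES = ("ac", "fed_aproteic", "fed_proteic", "lpd", "lpd_cystine",
                  "lpd_ornithine", "prd", "serine_rich", "custom")


@dataclass(frozen=True)
class HYThresholds:
    """Stage-specific plasma efficacy thresholds, mg/l (strictly increasing)."""

    by_stage: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFIG["thresholds"]))

    def validate(self) -> None:
        vals = list(self.by_stage.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("efficacy thresholds must increase with stage")
        if any(v < 0 for v in vals):
            raise ValueError("thresholds must be nonnegative")


@dataclass
class DietScenario:
    """A dosing regimen plus its amino-acid schedule and physiology flag."""

    name: str
    regimen: DoseRegimen
    schedule: DietSchedule
    prandial: str = "fasted"


def _equimolar_meal(grams: float, species: Sequence[str]) -> dict[str, float]:
    per = grams / len(species)
    return {aa: per * 1000.0 / AA_MW[aa] for aa in species}


def build_scenario(name: str, config: Optional[Mapping[str, Any]] = None,
                   species: Optional[str] = None) -> DietScenario:
    """Construct one of the named dietary scenarios from the config tree."""
    cfg = config or DEFAULT_CONFIG
    diet = cfg["diet"]
    bw = cfg["physiology"]["body_weight"]
    reg = cfg["regimen"]
    base_regimen = DoseRegimen.repeated(reg["amount_mg"], reg["interval_h"],
                                        reg["n_doses"], reg["horizon_h"])
    lpd_regimen = DoseRegimen.repeated(diet["lpd_dose_mg"], reg["interval_h"],
                                       reg["n_doses"], reg["horizon_h"])
    dose_times = [t for t, _ in base_regimen.events]
    protein_g = diet["protein_g_per_kg"] * bw * diet["meal_free_fraction"]

    if name == "ac":
        return DietScenario(name, base_regimen, DietSchedule(), "fasted")
    if name == "fed_aproteic":
        return DietScenario(name, base_regimen, DietSchedule(), "fed")
    if name == "fed_proteic":
        meals = tuple((t, _equimolar_meal(protein_g, AMINO_ACIDS))
                      for t in dose_times)
        return DietScenario(name, base_regimen, DietSchedule(meal_events=meals),
                            "fed")
    if name in ("lpd", "lpd_cystine", "lpd_ornithine"):
        sp = species or {"lpd": diet["lpd_species"],
                         "lpd_cystine": "cystine",
                         "lpd_ornithine": "orn"}[name]
        if sp == "equimolar":
            load = _equimolar_meal(protein_g, AMINO_ACIDS)
        else:
            load = {sp: protein_g * 1000.0 / AA_MW[sp]}
        meals = tuple((t, dict(load)) for t in dose_times)
        # dose taken before the meal: fasted physiology at dosing
        return DietScenario(name, lpd_regimen, DietSchedule(meal_events=meals),
                            "fasted")
    if name == "prd":
        return DietScenario(
            name, lpd_regimen,
            DietSchedule(plasma_init_multiplier=diet["prd_plasma_multiplier"]),
            "fasted")
    if name == "serine_rich":
        events = tuple((t + diet["serine_delay_h"],
                        {"ser": diet["serine_meal_mmol"]}) for t in dose_times)
        return DietScenario(name, base_regimen,
                            DietSchedule(plasma_events=events), "fasted")
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")


@dataclass
class ScenarioReport:
    """Per-scenario metrics and relative changes against the reference."""

    table: pd.DataFrame
    results: dict[str, CoupledResult]
    reference: str


def run_and_compare(scenarios: Sequence[DietScenario],
                    thresholds: Optional[HYThresholds] = None,
                    config: Optional[Mapping[str, Any]] = None,
                    base_network: Optional[StoichiometricNetwork] = None
                    ) -> ScenarioReport:
    """Run each scenario through the coupled model and score it.

    The first scenario is the reference; relative changes are
    ``100 * (AUC_s - AUC_ref) / AUC_ref`` per efficacy stage.
    """
    if not scenarios:
        raise ValueError("at least one scenario required")
    cfg = config or DEFAULT_CONFIG
    thresholds = thresholds or HYThresholds(dict(cfg["thresholds"]))
    thresholds.validate()
    ccfg = coupling_from_config(cfg)
    kin = kinetics_from_config(cfg)
    catalog = catalog_from_config(cfg)
    if base_network is None:
        base_network = build_reduced_siec(catalog)
        add_levodopa_module(base_network, catalog, v_t=ccfg.v_t)

    rows = []
    results: dict[str, CoupledResult] = {}
    for sc in scenarios:
        phys = physiology_from_config(cfg, sc.prandial)
        model = build_wb_acat(phys, kin)
        nets = [base_network.copy() for _ in SI_SEGMENTS]
        res = run_coupled(model, nets, sc.regimen, sc.schedule, ccfg)
        results[sc.name] = res
        tc = res.timecourse
        cmax, tmax = cmax_tmax(tc)
        row = {"scenario": sc.name, "cmax_mg_l": cmax, "tmax_h": tmax,
               "auc_mg_h_l": float(np.trapezoid(tc.plasma, tc.times))}
        for stage, thr in thresholds.by_stage.items():
            row[f"auc_above_{stage}"] = auc_above_threshold(tc, thr)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("scenario")
    ref = table.index[0]
    for stage in thresholds.by_stage:
        col = f"auc_above_{stage}"
        ref_val = table.loc[ref, col]
        if ref_val > 0:
            table[f"rel_change_{stage}_pct"] = 100.0 * (table[col] - ref_val) / ref_val
        else:
            table[f"rel_change_{stage}_pct"] = np.nan
    return ScenarioReport(table=table, results=results, reference=ref)


# --------------------------------------------------------------------------
# the extended-network (sIEC*) fasting reference and amino-acid ranking

#: Fasting-state calibration: fraction of the luminal influx that reaches
#: the systemic circulation, and fraction of the absorbed flux that is
#: eliminated renally.
SYSTEMIC_FRACTION = 0.66
RENAL_FRACTION = 0.30


def build_siec_star(catalog: Optional[TransporterCatalog] = None,
                    v_t: float = 15.0) -> StoichiometricNetwork:
    """Reduced enterocyte network + levodopa module + brain/kidney extension."""
    net = build_reduced_siec(catalog)
    add_levodopa_module(net, catalog, v_t=v_t)
    extend_brain_kidney(net)
    return net


@dataclass
class FastingReference:
    """Fluxes of the fasting-state sIEC* reference solve (mmol/gDW/h)."""

    influx: float
    uptake: float
    systemic: float
    renal: float
    brain: float

    @property
    def systemic_pct_of_influx(self) -> float:
        return 100.0 * self.systemic / self.influx

    @property
    def renal_pct_of_absorbed(self) -> float:
        return 100.0 * self.renal / self.uptake


def _ratio_constraints(model, renal_frac: float):
    """Attach the fasting flux-ratio equality constraints; return handles."""
    prob = model.problem
    v_exl = model.reactions.get_by_id("EX_levodopa_l").flux_expression
    v_sys = model.reactions.get_by_id("LDOPA_SYS_DELIVERY").flux_expression
    v_ren = model.reactions.get_by_id("LDOPA_RENAL_ELIM").flux_expression
    # uptake = -v_exl
    c_sys = prob.Constraint(v_sys + SYSTEMIC_FRACTION * v_exl, lb=0.0, ub=0.0,
                            name="fasting_systemic_ratio")
    c_ren = prob.Constraint(v_ren + renal_frac * v_exl, lb=0.0, ub=0.0,
                            name="fasting_renal_ratio")
    model.add_cons_vars([c_sys, c_ren])
    return [c_sys, c_ren]


def _solve_reference(net: StoichiometricNetwork, influx: float,
                     carrier_share: float, renal_frac: float,
                     brain_cap: Optional[float] = None) -> FastingReference:
    model = net.model
    cons = _ratio_constraints(model, renal_frac)
    try:
        bounds = {
            "EX_levodopa_l": (-influx, 1000.0),
            "luminal_carrier_cap": (0.0, carrier_share),
            # static simulation: kinetic caps do not apply
            "baso_antiporter_cap": (0.0, 1000.0),
            "LDOPA_GUTWALL_MET": (0.0, 1000.0),
        }
        if brain_cap is not None:
            bounds["LDOPA_BRAIN_UPTAKE"] = (0.0, brain_cap)
        sol = fba(net, "LDOPA_BRAIN_UPTAKE", extra_bounds=bounds,
                  minimize_total_flux=True)
        if not sol.optimal:
            raise NetworkError(f"fasting reference LP: {sol.status} "
                               f"({sol.diagnostic})")
        uptake = -float(sol.fluxes["EX_levodopa_l"])
        return FastingReference(
            influx=influx,
            uptake=uptake,
            systemic=float(sol.fluxes["LDOPA_SYS_DELIVERY"]),
            renal=float(sol.fluxes["LDOPA_RENAL_ELIM"]),
            brain=float(sol.fluxes["LDOPA_BRAIN_UPTAKE"]),
        )
    finally:
        model.remove_cons_vars(cons)


def fasting_reference(net: Optional[StoichiometricNetwork] = None,
                      influx: float = 15.0,
                      v_t: float = 15.0) -> FastingReference:
    """Fasting-state flux-balance reference of the extended network.

    Levodopa luminal influx is fixed (default 15 mmol/gDW/h), the fasting
    flux-ratio calibration is applied, and brain delivery is maximised.
    """
    net = net or build_siec_star(v_t=v_t)
    if not net.has_brain_kidney():
        raise NetworkError("brain/kidney extension required")
    return _solve_reference(net, influx, carrier_share=v_t,
                            renal_frac=RENAL_FRACTION)


@dataclass
class AminoAcidRanking:
    """Descending brain-delivery ranking with class partition."""

    table: pd.DataFrame
    reference_brain_flux: float

    def amino_acids_in_class(self, label: str) -> list[str]:
        return list(self.table.index[self.table["class"] == label])


def rank_amino_acids(siec_star: Optional[StoichiometricNetwork] = None,
                     influx: float = 15.0,
                     aa_load: Optional[float] = None,
                     brain_capacity_ratio: float = 2.0 / 3.0,
                     catalog: Optional[TransporterCatalog] = None
                     ) -> AminoAcidRanking:
    """Rank amino acids by the maximal levodopa flux delivered to the brain.

    Each amino acid is co-administered as a luminal load (default: equal to
    the levodopa influx).  Competition at the shared luminal carrier reduces
    the drug's uptake share; amino acids sharing the renal carrier displace
    levodopa from renal elimination; large neutral amino acids compete at
    the blood-brain barrier.  Classes: ``improving`` / ``neutral`` /
    ``competing`` relative to the fasting (no amino acid) reference.

    All capacities (luminal carrier, brain carrier) scale with the influx,
    so the class partition is invariant to the arbitrary influx value.
    """
    v_t = influx  # carrier capacity matches the arbitrary influx setting
    net = siec_star or build_siec_star(catalog, v_t=v_t)
    if not net.has_brain_kidney():
        raise NetworkError("brain/kidney extension required")
    catalog = catalog or net.catalog or TransporterCatalog()
    load = influx if aa_load is None else aa_load

    ref = _solve_reference(net, influx, carrier_share=v_t,
                           renal_frac=RENAL_FRACTION)
    rows = []
    for aa in AMINO_ACIDS:
        if aa in catalog.luminal_affinity:
            share = apply_competition_bounds(
                net, {aa: load}, influx, catalog=catalog,
                v_t=v_t)["luminal_carrier_cap"][1]
        else:
            share = v_t
        renal_frac = RENAL_FRACTION
        if aa in catalog.renal_affinity:
            # equal-affinity renal carrier: the co-administered amino acid
            # takes a load-proportional share of levodopa's elimination
            renal_frac = RENAL_FRACTION * influx / (influx + load)
        brain_cap = None
        if aa in catalog.brain_carrier:
            brain_cap = brain_capacity_ratio * influx * influx / (influx + load)
        try:
            res = _solve_reference(net, influx, carrier_share=share,
                                   renal_frac=renal_frac, brain_cap=brain_cap)
            rows.append({"amino_acid": aa, "brain_flux": res.brain,
                         "uptake": res.uptake, "renal": res.renal,
                         "status": "optimal"})
        except NetworkError as exc:
            rows.append({"amino_acid": aa, "brain_flux": np.nan,
                         "uptake": np.nan, "renal": np.nan,
                         "status": str(exc)})

    table = pd.DataFrame(rows).set_index("amino_acid")
    tol = 1e-6 * max(ref.brain, 1.0)
    def classify(b):
        if not np.isfinite(b):
            return "infeasible"
        if b > ref.brain + tol:
            return "improving"
        if b < ref.brain - tol:
            return "competing"
        return "neutral"
    table["class"] = table["brain_flux"].map(classify)
    table = table.sort_values("brain_flux", ascending=False)
    return AminoAcidRanking(table=table, reference_brain_flux=ref.brain)
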