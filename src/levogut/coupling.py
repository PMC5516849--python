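"""Dynamic flux-balance coupling of the whole-body model to seven enterocyte models.

The static optimization approach discretises the simulation horizon
(default 18 h) into fixed steps (default 0.1 h).  In each step, for each
small-intestinal segment:

1. the current luminal levodopa and amino-acid amounts and the plasma
   amino-acid concentrations are read off the dynamical state;
2. the exchange mode is selected — *competition* while dietary amino acids
   occupy the lumen, *trans-stimulation* when the lumen is clear but plasma
   amino acids are elevated above the fasting baseline;
3. amount-limited and carrier-share bounds are derived and set on that
   segment's enterocyte model;
4. flux balance analysis is solved with the levodopa luminal uptake
   (competition) or basolateral secretion (trans-stimulation) as objective;
5. the optimal fluxes are converted to mg/h rates that debit the segment
   lumen and credit the portal vein during the next integration step.

Dietary amino acids follow a parallel luminal transit chain (same gastric
emptying and segmental transit rates as the drug), are absorbed only in the
proximal jejunum, and feed a well-mixed plasma pool with first-order
disposal.  These amino-acid states are auxiliary and sit outside the
42-state levodopa census.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    AMINO_ACIDS,
    FluxSolution,
    StoichiometricNetwork,
    TransporterCatalog,
    apply_competition_bounds,
)
from .params import LEVODOPA_MW, SI_SEGMENTS, DoseRegimen, PhysiologyParameters
from .pbpk import K_FAST, CompiledWholeBodyModel, TimeCourse, integrate_window

COMPETITION = "competition"
TRANS_STIMULATION = "trans_stimulation"


class CouplingError(RuntimeError):
    """LP infeasibility or configuration error during a coupled run."""


@dataclass(frozen=True)
class CouplingConfig:
    """Step size, horizon and exchange-policy parameters of the coupled run.

    ``v_t`` is the shared luminal-carrier capacity (mmol/gDW/h);
    ``k_ts`` converts the total plasma concentration of neutral amino acids
    (mmol/l) into the basolateral-antiporter capacity (mmol/gDW/h per mM) —
    the trans-stimulation gain.  ``epsilon_lum`` is the luminal amino-acid
    amount (mmol) above which a segment is in competition mode.
    """

    step: float = 0.1
    duration: float = 18.0
    epsilon_lum: float = 1e-6
    molecular_weight: float = LEVODOPA_MW
    v_t: float = 15.0
    k_ts: float = 0.2
    aa_absorption_rate: float = 3.0   # 1/h, proximal jejunum only
    aa_plasma_clearance: float = 0.25  # 1/h, first-order plasma disposal
    aa_plasma_volume: float = 15.0     # l, amino-acid distribution volume
    fasting_plasma_aa: float = 0.12    # mmol/l per species

    def validate(self) -> None:
        if self.step <= 0:
            raise CouplingError("step must be positive")
        n = self.duration / self.step
        if abs(n - round(n)) > 1e-9:
            raise CouplingError("duration must be an integer number of steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.step))

    def fasting_neutral_plasma(self, catalog: TransporterCatalog) -> float:
        """Baseline total plasma concentration of antiporter substrates, mM."""
        return self.fasting_plasma_aa * len(catalog.basolateral_antiporter)


@dataclass
class SegmentExchange:
    """Per-segment snapshot handed between the two model scales."""

    segment: int
    luminal_levodopa: float                 # mmol
    luminal_aa: dict[str, float]            # mmol per species
    plasma_aa: dict[str, float]             # mmol/l per species
    uptake: float = 0.0                     # mg/h, resolved
    secretion: float = 0.0                  # mg/h, resolved


@dataclass
class DietSchedule:
    """Meal and plasma amino-acid events driving a coupled run.

    ``meal_events`` add luminal amino acids to the stomach (time h, species
    -> mmol); ``plasma_events`` add amino acids directly to the plasma pool
    (post-absorptive loads); ``plasma_init_multiplier`` scales the fasting
    plasma baseline at t = 0 with first-order return to baseline.
    """

    meal_events: tuple[tuple[float, dict[str, float]], ...] = ()
    plasma_events: tuple[tuple[float, dict[str, float]], ...] = ()
    plasma_init_multiplier: float = 1.0


def select_mode(segment: SegmentExchange, config: CouplingConfig,
                catalog: Optional[TransporterCatalog] = None) -> str:
    """Exchange-mode policy for one segment.

    Competition while luminal amino acids exceed ``epsilon_lum``;
    trans-stimulation when the lumen is clear and plasma amino acids exceed
    the fasting baseline; otherwise plain uptake, treated as competition
    with an empty competitor set.
    """
    catalog = catalog or TransporterCatalog()
    lum_total = sum(segment.luminal_aa.values())
    if lum_total > config.epsilon_lum:
        return COMPETITION
    baseline = config.fasting_neutral_plasma(catalog)
    plasma_neutral = sum(segment.plasma_aa.get(aa, 0.0)
                         for aa in catalog.basolateral_antiporter)
    if plasma_neutral > baseline * (1.0 + 1e-9):
        return TRANS_STIMULATION
    return COMPETITION


def derive_bounds(segment: SegmentExchange, step: float,
                  config: CouplingConfig,
                  net: StoichiometricNetwork,
                  dry_weight: float) -> dict[str, tuple[float, float]]:
    """Per-reaction bound map for one segment LP.

    Uptake is limited by both the affinity-weighted carrier share and the
    amount available in the lumen over the step (``amount / (step x gDW)``
    in flux units), so no step can extract more than the segment contains.
    The basolateral antiporter capacity scales with the plasma
    concentration of its substrates.
    """
    if dry_weight <= 0:
        raise CouplingError("segment dry weight must be positive")
    catalog = net.catalog or TransporterCatalog()
    bounds = apply_competition_bounds(
        net, segment.luminal_aa, segment.luminal_levodopa,
        catalog=catalog, v_t=config.v_t)

    # Amount-limited supply: never more than the segment contains over the
    # step, and never faster than the intrinsic extraction rate (so the
    # effective conductance does not depend on the step size).
    k_avail = min(1.0 / step, K_FAST)
    supply = segment.luminal_levodopa * k_avail / dry_weight
    bounds["EX_levodopa_l"] = (-supply, 1000.0)

    for aa, amount in segment.luminal_aa.items():
        rid = f"EX_{aa}_l"
        bounds[rid] = (-amount * k_avail / dry_weight, 1000.0)

    plasma_neutral = sum(segment.plasma_aa.get(aa, 0.0)
                         for aa in catalog.basolateral_antiporter)
    bounds["baso_antiporter_cap"] = (0.0, config.k_ts * plasma_neutral)
    return bounds


def fluxes_to_derivatives(sol: FluxSolution, segment: int,
                          config: CouplingConfig,
                          dry_weights: Sequence[float]) -> tuple[float, float]:
    """Convert an optimal flux solution into mg/h exchange rates.

    ``rate = flux [mmol/gDW/h] x gDW x MW``; uptake debits the segment
    lumen, secretion credits the portal vein.
    """
    if not sol.optimal:
        raise CouplingError("flux solution is not optimal")
    gdw = dry_weights[segment]
    uptake = -float(sol.fluxes["EX_levodopa_l"]) * gdw * config.molecular_weight
    secretion = float(sol.fluxes["EX_levodopa_b"]) * gdw * config.molecular_weight
    return uptake, secretion


# --------------------------------------------------------------------------
# dietary amino-acid dynamics (auxiliary linear chain)

class AminoAcidDynamics:
    """Luminal transit and plasma kinetics of dietary amino acids.

    States per species: stomach, seven small-intestinal segments, colon and
    a plasma-excess pool (amounts in mmol).  Transit uses the prandial
    gastric-emptying and segmental rates; absorption occurs only in the two
    proximal jejunum segments; the plasma excess decays first order towards
    the fasting baseline.
    """

    N_LUMEN = 9  # stomach + 7 segments + colon
    JEJUNUM_SLOTS = (2, 3)  # chain indices of jejunum1/jejunum2

    def __init__(self, physiology: PhysiologyParameters,
                 config: CouplingConfig,
                 schedule: DietSchedule,
                 species: Sequence[str] = AMINO_ACIDS):
        self.species = tuple(species)
        self.config = config
        self.physiology = physiology
        self.schedule = schedule

    def _rhs(self, t: float, y_flat: np.ndarray) -> np.ndarray:
        cfg = self.config
        phys = self.physiology
        n_sp = len(self.species)
        y = y_flat.reshape(n_sp, self.N_LUMEN + 1)
        lum = y[:, :self.N_LUMEN]
        excess = y[:, self.N_LUMEN]

        k_out = np.array([phys.ger] + [phys.si_transit_rate] * 7 + [1.0])
        out = lum * k_out
        dlum = -out
        dlum[:, 1:] += out[:, :-1]
        absorbed = np.zeros(n_sp)
        for j in self.JEJUNUM_SLOTS:
            a = cfg.aa_absorption_rate * lum[:, j]
            dlum[:, j] -= a
            absorbed += a
        dexcess = absorbed - cfg.aa_plasma_clearance * excess
        dy = np.concatenate([dlum, dexcess[:, None]], axis=1)
        return dy.ravel()

    def trajectories(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample luminal amounts and plasma concentrations at step starts.

        Returns ``(lumen, plasma)`` with shapes
        ``(n_steps + 1, 7 segments, n_species)`` mmol and
        ``(n_steps + 1, n_species)`` mmol/l.
        """
        cfg = self.config
        n_sp = len(self.species)
        n_steps = cfg.n_steps
        grid = np.linspace(0.0, cfg.duration, n_steps + 1)
        sp_index = {s: i for i, s in enumerate(self.species)}

        y = np.zeros((n_sp, self.N_LUMEN + 1))
        y[:, self.N_LUMEN] = (cfg.fasting_plasma_aa * cfg.aa_plasma_volume
                              * (self.schedule.plasma_init_multiplier - 1.0))

        events: dict[float, list[tuple[int, int, float]]] = {}
        for t, load in self.schedule.meal_events:
            for aa, mmol in load.items():
                events.setdefault(t, []).append((sp_index[aa], 0, mmol))
        for t, load in self.schedule.plasma_events:
            for aa, mmol in load.items():
                events.setdefault(t, []).append((sp_index[aa], self.N_LUMEN, mmol))

        breaks = sorted({0.0, cfg.duration, *events})
        lum_out = np.zeros((n_steps + 1, 7, n_sp))
        pl_out = np.zeros((n_steps + 1, n_sp))

        def record(times: np.ndarray, states: np.ndarray) -> None:
            for t, s in zip(times, states):
                k = int(round(t / cfg.step))
                if 0 <= k <= n_steps and abs(t - k * cfg.step) < 1e-9:
                    arr = s.reshape(n_sp, self.N_LUMEN + 1)
                    lum_out[k] = arr[:, 1:8].T
                    pl_out[k] = (cfg.fasting_plasma_aa
                                 + arr[:, self.N_LUMEN] / cfg.aa_plasma_volume)

        for t0, t1 in zip(breaks[:-1], breaks[1:]):
            for i, slot, mmol in events.get(t0, []):
                y[i, slot] += mmol
            k0, k1 = int(round(t0 / cfg.step)), int(round(t1 / cfg.step))
            t_eval = grid[(grid >= t0 - 1e-12) & (grid <= t1 + 1e-12)]
            if len(t_eval) < 2:
                t_eval = np.array([t0, t1])
            if y.any():
                sol = solve_ivp(self._rhs, (t0, t1), y.ravel(), method="LSODA",
                                t_eval=t_eval, rtol=1e-8, atol=1e-12)
                record(sol.t, sol.y.T)
                y = sol.y[:, -1].reshape(n_sp, self.N_LUMEN + 1).copy()
            else:
                record(t_eval, np.tile(y.ravel(), (len(t_eval), 1)))
        # ensure the final grid point is recorded even if t1 missed the grid
        return lum_out, pl_out


# --------------------------------------------------------------------------
# the coupled run

@dataclass
class CoupledResult:
    """Time course of the coupled run plus the per-step flux log."""

    timecourse: TimeCourse
    flux_log: pd.DataFrame


def run_coupled(model: CompiledWholeBodyModel,
                networks: Sequence[StoichiometricNetwork],
                regimen: DoseRegimen,
                diet: Optional[DietSchedule] = None,
                config: Optional[CouplingConfig] = None,
                rtol: float = 1e-8, atol: float = 1e-10) -> CoupledResult:
    """Run the static-optimization-approach coupled simulation.

    Requires exactly one enterocyte network per small-intestinal segment.
    Raises :class:`CouplingError` with the step index and segment if any
    segment LP is infeasible.
    """
    config = config or CouplingConfig()
    config.validate()
    diet = diet or DietSchedule()
    regimen.validate()
    if len(networks) != len(SI_SEGMENTS):
        raise CouplingError(
            f"exactly {len(SI_SEGMENTS)} networks required, got {len(networks)}")
    for net in networks:
        if not net.has_levodopa_module():
            raise CouplingError("all networks need the levodopa module")

    phys = model.physiology
    mw = config.molecular_weight
    dry = phys.segment_dry_weight
    step = config.step
    n_steps = config.n_steps
    catalog = networks[0].catalog or TransporterCatalog()

    aa = AminoAcidDynamics(phys, config, diet)
    lum_aa, plasma_aa = aa.trajectories()
    species = aa.species

    dis_idx = [model.index[f"{seg}_dissolved"] for seg in SI_SEGMENTS]
    dose_at = {t: a for t, a in regimen.events if t < config.duration}

    # Pre-resolve LP handles per segment for fast in-place bound updates.
    handles = []
    for net in networks:
        m = net.model
        if m.reactions.has_id("LDOPA_GUTWALL_MET"):
            m.reactions.LDOPA_GUTWALL_MET.bounds = (0.0, 0.0)
        if m.reactions.has_id("BIOMASS_maintenance"):
            m.reactions.BIOMASS_maintenance.bounds = (0.0, 0.0)
        handles.append({
            "model": m,
            "ex_l": m.reactions.get_by_id("EX_levodopa_l"),
            "ex_b": m.reactions.get_by_id("EX_levodopa_b"),
            "cap": m.solver.constraints["luminal_carrier_cap"],
            "baso_cap": m.solver.constraints["baso_antiporter_cap"],
            "aa_ex": {s: m.reactions.get_by_id(f"EX_{s}_l") for s in species},
        })

    y = np.zeros(len(model.state_names))
    times = [0.0]
    states = [y.copy()]
    log_rows: list[dict] = []
    k_avail = min(1.0 / step, K_FAST)

    for k in range(n_steps):
        t0 = k * step
        for t_dose, amount in dose_at.items():
            if abs(t_dose - t0) < 1e-9:
                model.dose_injector(y, amount)

        uptake = np.zeros(len(SI_SEGMENTS))
        secretion = np.zeros(len(SI_SEGMENTS))
        for s in range(len(SI_SEGMENTS)):
            a_l = max(y[dis_idx[s]], 0.0) / mw  # mmol
            lum = {species[j]: lum_aa[k, s, j] for j in range(len(species))
                   if lum_aa[k, s, j] > 0.0}
            pl = {species[j]: plasma_aa[k, j] for j in range(len(species))}
            seg = SegmentExchange(segment=s, luminal_levodopa=a_l,
                                  luminal_aa=lum, plasma_aa=pl)
            mode = select_mode(seg, config, catalog)

            h = handles[s]
            share = apply_competition_bounds(
                networks[s], lum, a_l, catalog=catalog,
                v_t=config.v_t)["luminal_carrier_cap"][1]
            supply = a_l * k_avail / dry[s]
            h["cap"].ub = share
            h["ex_l"].lower_bound = -supply
            plasma_neutral = sum(pl.get(x, 0.0)
                                 for x in catalog.basolateral_antiporter)
            h["baso_cap"].ub = config.k_ts * plasma_neutral
            for sp, rxn in h["aa_ex"].items():
                amt = lum.get(sp, 0.0)
                rxn.lower_bound = -amt * k_avail / dry[s]

            m = h["model"]
            if mode == COMPETITION:
                m.objective = {h["ex_l"]: -1.0}
            else:
                m.objective = {h["ex_b"]: 1.0}
            m.objective_direction = "max"
            value = m.slim_optimize(error_value=None)
            if value is None:
                raise CouplingError(
                    f"segment LP infeasible at step {k} (t={t0:.1f} h), "
                    f"segment {SI_SEGMENTS[s]}")
            v_upt = -h["ex_l"].flux
            v_sec = h["ex_b"].flux
            uptake[s] = v_upt * dry[s] * mw
            secretion[s] = v_sec * dry[s] * mw
            log_rows.append({
                "step": k, "time_h": t0, "segment": SI_SEGMENTS[s],
                "mode": mode, "uptake_flux": v_upt, "secretion_flux": v_sec,
            })

        sol = integrate_window(model, y, t0, t0 + step,
                               t_eval=np.array([t0, t0 + step]),
                               uptake_rates=uptake, secretion_rates=secretion,
                               rtol=rtol, atol=atol)
        y = sol.y[:, -1].copy()
        times.append(t0 + step)
        states.append(y.copy())

    tc = TimeCourse(
        times=np.array(times),
        states=np.vstack(states),
        state_names=model.state_names,
        venous_volume=model.kinetics.organ_volumes["venous_blood"],
    )
    return CoupledResult(timecourse=tc, flux_log=pd.DataFrame(log_rows))
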