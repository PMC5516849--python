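"""Whole-body PBPK model with a compartmental-absorption-and-transit gut.

The assembled system has exactly 42 states:

* 18 luminal states — nine gastrointestinal compartments (stomach, seven
  small-intestinal segments, colon), each split into undissolved solid and
  dissolved drug;
* 7 enterocyte states — gut-wall drug per small-intestinal segment;
* 17 systemic states — venous, arterial and portal blood, twelve
  perfusion-limited organs, and two cumulative sinks (urine; degraded +
  fecal + metabolised drug).

Drug amounts are carried in mg throughout.  Between dose events the total
of all 42 states is conserved exactly by construction: transit, dissolution
and absorption move mass between states, degradation and clearances move it
into the cumulative sinks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    SI_SEGMENTS,
    DoseRegimen,
    KineticParameters,
    PhysiologyParameters,
)

N_STATES = 42

#: Intrinsic gut-wall extraction rate constant (1/h).  Externally imposed
#: per-step exchange rates act as caps on a fast first-order extraction,
#: ``realised = min(rate, K_FAST * dissolved)``: a constant per-step rate can
#: never overdraw an emptying segment, and the standing luminal stock under
#: quasi-steady absorption is independent of the coupling step size (the
#: value keeps ``K_FAST <= 1/step`` for steps up to 0.1 h, so the realised
#: extraction also respects the per-step amount limit).
K_FAST = 10.0

_LUMEN_COMPARTMENTS = ("stomach",) + SI_SEGMENTS + ("colon",)

_SYSTEMIC_STATES = (
    "venous_blood",
    "arterial_blood",
    "portal_vein",
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "kidney",
    "liver",
    "spleen",
    "pancreas",
    "rest_of_body",
    "urine_cum",
    "eliminated_cum",
)


def state_layout() -> tuple[str, ...]:
    """The fixed ordering of the 42 model states."""
    names: list[str] = []
    for comp in _LUMEN_COMPARTMENTS:
        names.append(f"{comp}_solid")
        names.append(f"{comp}_dissolved")
    for seg in SI_SEGMENTS:
        names.append(f"enterocyte_{seg}")
    names.extend(_SYSTEMIC_STATES)
    return tuple(names)


class SimulationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


def saturation_solubility(ph: float, kinetics: KineticParameters) -> float:
    """Piecewise-linear solubility (mg/ml) at luminal *ph*."""
    pts = kinetics.solubility_by_ph
    phs = np.array([p for p, _ in pts])
    sols = np.array([s for _, s in pts])
    return float(np.interp(ph, phs, sols))


def dissolution_flux(solid_mass: float, dissolved_conc: float, ph: float,
                     volume: float, kinetics: KineticParameters) -> float:
    """Noyes-Whitney dissolution rate, mg/h.

    ``kd * solid^(2/3) * (Csat(ph) - C)``, floored at zero (re-precipitation
    is not modelled).  The 2/3 exponent is the surface-area scaling of a
    shrinking particle mass.
    """
    if solid_mass < 0 or volume < 0:
        raise ValueError("solid_mass and volume must be nonnegative")
    if solid_mass == 0.0:
        return 0.0
    csat = saturation_solubility(ph, kinetics)
    driving = csat - dissolved_conc
    if driving <= 0.0:
        return 0.0
    return kinetics.dissolution_coefficient * solid_mass ** (2.0 / 3.0) * driving


@dataclass
class TimeCourse:
    """Simulated trajectories: times (h) and the 42 named state amounts (mg).

    Plasma concentration (mg/l) is derived as venous amount / venous volume.
    """

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 42)
    state_names: tuple[str, ...]
    venous_volume: float

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValueError("empty time course")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    @property
    def plasma(self) -> np.ndarray:
        """Venous plasma concentration, mg/l."""
        return self["venous_blood"] / self.venous_volume

    def total_drug(self) -> np.ndarray:
        """Sum of all drug-containing states plus cumulative sinks, mg."""
        return self.states.sum(axis=1)

    def to_frame(self):
        """Tidy (time, state, value) DataFrame."""
        import pandas as pd

        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, len(self.state_names)),
                "state": np.tile(self.state_names, n_t),
                "value_mg": self.states.ravel(),
            }
        )


@dataclass
class CompiledWholeBodyModel:
    """The assembled 42-state whole-body ACAT model.

    ``rhs(t, y, uptake_rates, secretion_rates)`` evaluates the derivative
    vector; when both rate arrays are ``None`` the model runs uncoupled with
    first-order segmental absorption (``ka_fallback``).  ``dose_injector``
    adds a per-os dose to the stomach-solid state.
    """

    state_names: tuple[str, ...]
    physiology: PhysiologyParameters
    kinetics: KineticParameters
    rhs: Callable[..., np.ndarray]
    dose_injector: Callable[[np.ndarray, float], None]
    index: dict[str, int]


def build_wb_acat(physiology: PhysiologyParameters,
                  kinetics: KineticParameters) -> CompiledWholeBodyModel:
    """Compile the whole-body ACAT right-hand side for one parameter set."""
    physiology.validate()
    kinetics.validate()

    names = state_layout()
    index = {n: i for i, n in enumerate(names)}
    n_seg = len(SI_SEGMENTS)

    # Luminal geometry: stomach, 7 SI segments, colon.
    sol_idx = np.array([index[f"{c}_solid"] for c in _LUMEN_COMPARTMENTS])
    dis_idx = np.array([index[f"{c}_dissolved"] for c in _LUMEN_COMPARTMENTS])
    ent_idx = np.array([index[f"enterocyte_{s}"] for s in SI_SEGMENTS])

    volumes_ml = np.array(
        [physiology.stomach_volume, *physiology.segment_volumes, physiology.colon_volume]
    )
    ph = np.array([physiology.gastric_ph, *physiology.si_ph_profile, physiology.colon_ph])
    csat = np.array([saturation_solubility(p, kinetics) for p in ph])
    # Outflow rate of each luminal compartment in the transit chain.
    k_out = np.array(
        [physiology.ger]
        + [physiology.si_transit_rate] * n_seg
        + [kinetics.colon_elimination_rate]
    )
    # First-order luminal degradation (dissolved drug only).
    k_deg = np.array(
        [kinetics.k_deg_stomach] + [kinetics.k_deg_lumen] * (n_seg + 1)
    )

    kd = kinetics.dissolution_coefficient
    ka = kinetics.ka_fallback
    k_baso = kinetics.basolateral_rate

    flows = kinetics.organ_blood_flows
    vols = kinetics.organ_volumes
    kp = kinetics.partition_coefficients

    co = kinetics.cardiac_output
    q_pv = flows["gut"] + flows["spleen"] + flows["pancreas"]
    q_liver_total = flows["liver_arterial"] + q_pv

    i_ven = index["venous_blood"]
    i_art = index["arterial_blood"]
    i_por = index["portal_vein"]
    i_lung = index["lung"]
    i_kid = index["kidney"]
    i_liv = index["liver"]
    i_spl = index["spleen"]
    i_pan = index["pancreas"]
    i_urine = index["urine_cum"]
    i_elim = index["eliminated_cum"]

    # Organs perfused from arterial blood whose venous outflow returns
    # directly (kidney and liver handled separately for clearance/portal).
    direct_organs = ("heart", "brain", "muscle", "adipose", "skin", "bone",
                     "rest_of_body")
    d_idx = np.array([index[o] for o in direct_organs])
    d_q = np.array([flows[o] for o in direct_organs])
    d_vk = np.array([vols[o] * kp[o] for o in direct_organs])

    v_ven = vols["venous_blood"]
    v_art = vols["arterial_blood"]
    v_por = vols["portal_vein"]
    vk_lung = vols["lung"] * kp["lung"]
    vk_kid = vols["kidney"] * kp["kidney"]
    vk_liv = vols["liver"] * kp["liver"]
    vk_spl = vols["spleen"] * kp["spleen"]
    vk_pan = vols["pancreas"] * kp["pancreas"]
    cl_h = kinetics.hepatic_clearance
    cl_r = kinetics.renal_clearance

    def rhs(t: float, y: np.ndarray,
            uptake_rates: Optional[np.ndarray] = None,
            secretion_rates: Optional[np.ndarray] = None) -> np.ndarray:
        dy = np.zeros(N_STATES)

        solid = y[sol_idx]
        diss = y[dis_idx]

        # Dissolution, vectorised over the nine luminal compartments.
        s_pos = np.maximum(solid, 0.0)
        conc = np.maximum(diss, 0.0) / volumes_ml
        drive = np.maximum(csat - conc, 0.0)
        dflux = kd * s_pos ** (2.0 / 3.0) * drive
        dflux[s_pos == 0.0] = 0.0

        out_s = k_out * solid
        out_d = k_out * diss
        deg = k_deg * diss

        dy[sol_idx] = -out_s - dflux
        dy[dis_idx] = -out_d + dflux - deg
        # Transit chain: compartment i feeds compartment i+1.
        dy[sol_idx[1:]] += out_s[:-1]
        dy[dis_idx[1:]] += out_d[:-1]

        # Absorption across the gut wall (SI segments are chain slots 1..7).
        ent = y[ent_idx]
        if uptake_rates is None:
            upt = ka * diss[1:1 + n_seg]
            sec = k_baso * ent if secretion_rates is None else secretion_rates
        else:
            # Externally resolved rates cap a fast first-order extraction;
            # uptake and secretion scale together so the wall throughput
            # stays balanced.
            d = np.maximum(diss[1:1 + n_seg], 0.0)
            upt = np.minimum(uptake_rates, K_FAST * d)
            if secretion_rates is None:
                sec = k_baso * ent
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    scale = np.where(uptake_rates > 0.0,
                                     upt / np.where(uptake_rates > 0.0,
                                                    uptake_rates, 1.0),
                                     0.0)
                sec = secretion_rates * scale
        dy[dis_idx[1:1 + n_seg]] -= upt
        dy[ent_idx] = upt - sec

        # Blood and organs (amounts mg; concentrations mg/l).
        c_ven = y[i_ven] / v_ven
        c_art = y[i_art] / v_art
        c_por = y[i_por] / v_por
        c_lung_out = y[i_lung] / vk_lung
        c_kid_out = y[i_kid] / vk_kid
        c_liv_out = y[i_liv] / vk_liv
        c_spl_out = y[i_spl] / vk_spl
        c_pan_out = y[i_pan] / vk_pan
        c_d_out = y[d_idx] / d_vk

        dy[i_lung] = co * (c_ven - c_lung_out)
        dy[i_art] = co * (c_lung_out - c_art)
        dy[d_idx] = d_q * (c_art - c_d_out)
        dy[i_kid] = flows["kidney"] * (c_art - c_kid_out) - cl_r * c_kid_out
        dy[i_spl] = flows["spleen"] * (c_art - c_spl_out)
        dy[i_pan] = flows["pancreas"] * (c_art - c_pan_out)
        dy[i_por] = (flows["gut"] * c_art + flows["spleen"] * c_spl_out
                     + flows["pancreas"] * c_pan_out + float(np.sum(sec))
                     - q_pv * c_por)
        dy[i_liv] = (flows["liver_arterial"] * c_art + q_pv * c_por
                     - q_liver_total * c_liv_out - cl_h * c_liv_out)
        dy[i_ven] = (float(np.dot(d_q, c_d_out))
                     + flows["kidney"] * c_kid_out
                     + q_liver_total * c_liv_out
                     - co * c_ven)

        dy[i_urine] = cl_r * c_kid_out
        # Fecal loss (colon outflow), luminal degradation, hepatic metabolism.
        dy[i_elim] = out_s[-1] + out_d[-1] + float(np.sum(deg)) + cl_h * c_liv_out
        return dy

    def dose_injector(y: np.ndarray, amount_mg: float) -> None:
        y[index["stomach_solid"]] += amount_mg

    return CompiledWholeBodyModel(
        state_names=names,
        physiology=physiology,
        kinetics=kinetics,
        rhs=rhs,
        dose_injector=dose_injector,
        index=index,
    )


def integrate_window(model: CompiledWholeBodyModel, y0: np.ndarray,
                     t0: float, t1: float,
                     t_eval: Optional[np.ndarray] = None,
                     uptake_rates: Optional[np.ndarray] = None,
                     secretion_rates: Optional[np.ndarray] = None,
                     rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the model over [t0, t1] with fixed gut-wall exchange rates."""
    sol = solve_ivp(
        model.rhs,
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=t_eval,
        args=(uptake_rates, secretion_rates),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else t0
        raise SimulationError(f"integration failed: {sol.message}", last)
    return sol


def simulate(model: CompiledWholeBodyModel, regimen: DoseRegimen,
             duration: float,
             uptake_callback: Optional[Callable[[float, np.ndarray],
                                                tuple[np.ndarray, np.ndarray]]] = None,
             output_dt: float = 0.02,
             rtol: float = 1e-8, atol: float = 1e-10,
             y0: Optional[np.ndarray] = None) -> TimeCourse:
    """Simulate the model under a dose regimen.

    Dose events are applied as discontinuous additions to the stomach-solid
    state with stop-and-restart integration.  When *uptake_callback* is
    given it is evaluated at the start of each output step and must return
    per-segment (uptake, secretion) rate arrays in mg/h; otherwise the model
    runs uncoupled with first-order absorption.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    regimen.validate()

    y = np.zeros(N_STATES) if y0 is None else np.array(y0, dtype=float)
    events = [(t, a) for t, a in regimen.events if t <= duration]

    # Breakpoints: dose times partition the horizon.
    breaks = sorted({0.0, duration, *(t for t, _ in events)})
    dose_at = {t: a for t, a in events}

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t0 in dose_at:
            model.dose_injector(y, dose_at[t0])
        n = max(2, int(round((t1 - t0) / output_dt)) + 1)
        t_eval = np.linspace(t0, t1, n)
        if uptake_callback is None:
            sol = integrate_window(model, y, t0, t1, t_eval, rtol=rtol, atol=atol)
        else:
            upt, sec = uptake_callback(t0, y)
            sol = integrate_window(model, y, t0, t1, t_eval, upt, sec,
                                   rtol=rtol, atol=atol)
        y = sol.y[:, -1].copy()
        keep = slice(0, -1) if t1 != breaks[-1] else slice(None)
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep].T)
    # Trailing dose exactly at the horizon would be a no-op; ignore.

    return TimeCourse(
        times=np.concatenate(times_out),
        states=np.vstack(states_out),
        state_names=model.state_names,
        venous_volume=model.kinetics.organ_volumes["venous_blood"],
    )


def auc_above_threshold(tc: TimeCourse, threshold: float) -> float:
    """Trapezoidal integral of max(C(t) - threshold, 0), mg*h/l."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    excess = np.maximum(tc.plasma - threshold, 0.0)
    return float(np.trapezoid(excess, tc.times))


def cmax_tmax(tc: TimeCourse) -> tuple[float, float]:
    """Maximum plasma concentration (mg/l) and the first time achieving it."""
    c = tc.plasma
    i = int(np.argmax(c))
    return float(c[i]), float(tc.times[i])
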