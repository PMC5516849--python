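"""Physiological and drug-specific parameter sets for the whole-body ACAT model.

The gastrointestinal tract is discretised into nine luminal compartments
(stomach, seven small-intestinal segments, colon); drug in each luminal
compartment exists as undissolved solid and as dissolved material.  The
systemic side is a generic perfusion-limited whole-body organ set.  Prandial
state (fasted vs fed) switches five physiological parameters: gastric
emptying rate, stomach and colon volumes, small-intestinal transit rate and
gastric pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

# Seven small-intestinal segments of the compartmental absorption model.
SI_SEGMENTS: tuple[str, ...] = (
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "ileum4",
)

#: Levodopa molecular weight, mg/mmol.
LEVODOPA_MW: float = 197.19

# Fed versus fasted physiology (gastric emptying rate per h, volumes ml,
# small-intestinal transit rate per h per segment, gastric pH).
PRANDIAL_TABLE: dict[str, dict[str, float]] = {
    "fasted": {
        "ger": 3.96,
        "stomach_volume": 50.0,
        "colon_volume": 1000.0,
        "si_transit_rate": 2.1,
        "gastric_ph": 2.0,
    },
    "fed": {
        "ger": 0.33,
        "stomach_volume": 1000.0,
        "colon_volume": 7000.0,
        "si_transit_rate": 0.57,
        "gastric_ph": 5.0,
    },
}

#: Perfusion-limited organs receiving arterial blood directly.
SYSTEMIC_ORGANS: tuple[str, ...] = (
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "kidney",
    "spleen",
    "pancreas",
    "rest_of_body",
)


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class PhysiologyParameters:
    """Prandial-state physiology of the gastrointestinal tract.

    Parameters
    ----------
    ger : float
        Gastric emptying rate, 1/h (first-order stomach-to-duodenum transfer).
    stomach_volume, colon_volume : float
        Luminal fluid volumes, ml.
    si_transit_rate : float
        Per-segment small-intestinal transit rate, 1/h.
    gastric_ph : float
        Stomach luminal pH.
    si_ph_profile : tuple of 7 floats
        Luminal pH per small-intestinal segment, proximal to distal.
    segment_volumes : tuple of 7 floats
        Luminal fluid volume per small-intestinal segment, ml.
    segment_dry_weight : tuple of 7 floats
        Effective carrier-expressing mucosal dry weight per segment, g.
        This is the normalisation basis of metabolic fluxes (mmol/gDW/h).
    body_weight : float
        Subject body weight, kg.
    colon_ph : float
        Colonic luminal pH (used only for dissolution).
    """

    ger: float = 3.96
    stomach_volume: float = 50.0
    colon_volume: float = 1000.0
    si_transit_rate: float = 2.1
    gastric_ph: float = 2.0
    si_ph_profile: tuple[float, ...] = (6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.2)
    segment_volumes: tuple[float, ...] = (50.0, 50.0, 50.0, 40.0, 40.0, 40.0, 40.0)
    segment_dry_weight: tuple[float, ...] = (0.05,) * 7
    body_weight: float = 70.0
    colon_ph: float = 6.8

    def validate(self) -> None:
        for name in ("ger", "stomach_volume", "colon_volume", "si_transit_rate",
                     "body_weight"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"physiology.{name} must be strictly positive")
        for name in ("gastric_ph", "colon_ph"):
            if not 1.0 <= getattr(self, name) <= 9.0:
                raise ParameterError(f"physiology.{name} must lie in [1, 9]")
        for name in ("si_ph_profile", "segment_volumes", "segment_dry_weight"):
            vals = getattr(self, name)
            if len(vals) != len(SI_SEGMENTS):
                raise ParameterError(
                    f"physiology.{name} must have exactly {len(SI_SEGMENTS)} entries"
                )
        if any(not 1.0 <= p <= 9.0 for p in self.si_ph_profile):
            raise ParameterError("physiology.si_ph_profile values must lie in [1, 9]")
        if any(v <= 0 for v in self.segment_volumes):
            raise ParameterError("physiology.segment_volumes must be strictly positive")
        if any(w <= 0 for w in self.segment_dry_weight):
            raise ParameterError("physiology.segment_dry_weight must be strictly positive")


def set_prandial_state(physiology: PhysiologyParameters, state: str) -> PhysiologyParameters:
    """Return a copy of *physiology* with the five prandial fields set.

    ``state`` is ``"fasted"`` or ``"fed"``; all other fields are untouched.
    """
    if state not in PRANDIAL_TABLE:
        raise ParameterError(
            f"unknown prandial state {state!r}; expected 'fasted' or 'fed'"
        )
    return replace(physiology, **PRANDIAL_TABLE[state])


def _default_flows() -> dict[str, float]:
    # l/h; cardiac output is the sum (= 390 l/h).
    return {
        "heart": 15.0,
        "brain": 46.0,
        "muscle": 66.0,
        "adipose": 20.0,
        "skin": 20.0,
        "bone": 20.0,
        "kidney": 70.0,
        "liver_arterial": 25.0,
        "spleen": 8.0,
        "pancreas": 4.0,
        "gut": 66.0,
        "rest_of_body": 30.0,
    }


def _default_volumes() -> dict[str, float]:
    # l
    return {
        "venous_blood": 3.0,
        "arterial_blood": 1.5,
        "portal_vein": 0.07,
        "lung": 0.5,
        "heart": 0.3,
        "brain": 1.45,
        "muscle": 29.0,
        "adipose": 12.0,
        "skin": 3.4,
        "bone": 8.0,
        "kidney": 0.3,
        "liver": 1.7,
        "spleen": 0.18,
        "pancreas": 0.1,
        "rest_of_body": 3.0,
    }


def _default_partition() -> dict[str, float]:
    # Levodopa distributes mainly into lean tissue; brain entry is
    # carrier-limited, adipose partitioning negligible.
    return {
        "lung": 0.8,
        "heart": 0.8,
        "brain": 0.12,
        "muscle": 0.7,
        "adipose": 0.15,
        "skin": 0.6,
        "bone": 0.4,
        "kidney": 0.9,
        "liver": 0.9,
        "spleen": 0.8,
        "pancreas": 0.8,
        "rest_of_body": 0.6,
    }


@dataclass(frozen=True)
class KineticParameters:
    """Drug-specific rate, partition and clearance parameters.

    Flows are l/h, volumes l, clearances l/h, first-order rates 1/h.
    ``dissolution_coefficient`` is the Noyes-Whitney rate constant
    (mg/h per mg^(2/3) of solid per mg/ml of undersaturation);
    ``solubility_by_ph`` is a piecewise-linear (pH, mg/ml) lookup.
    ``ka_fallback`` is the per-segment first-order absorption constant used
    only when the model runs uncoupled from the enterocyte networks;
    ``basolateral_rate`` moves enterocyte drug into the portal vein in that
    mode.
    """

    organ_blood_flows: Mapping[str, float] = field(default_factory=_default_flows)
    organ_volumes: Mapping[str, float] = field(default_factory=_default_volumes)
    partition_coefficients: Mapping[str, float] = field(default_factory=_default_partition)
    hepatic_clearance: float = 20.0
    renal_clearance: float = 6.0
    k_deg_stomach: float = 0.3
    k_deg_lumen: float = 0.5
    dissolution_coefficient: float = 2.0
    solubility_by_ph: tuple[tuple[float, float], ...] = ((2.0, 3.5), (5.0, 1.5), (7.4, 1.0))
    ka_fallback: float = 2.5
    basolateral_rate: float = 10.0
    colon_elimination_rate: float = 0.5

    def validate(self) -> None:
        for name in ("hepatic_clearance", "renal_clearance", "k_deg_stomach",
                     "k_deg_lumen", "dissolution_coefficient", "ka_fallback",
                     "basolateral_rate", "colon_elimination_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"kinetics.{name} must be nonnegative")
        for key in _default_flows():
            if key not in self.organ_blood_flows:
                raise ParameterError(f"kinetics.organ_blood_flows missing {key!r}")
            if self.organ_blood_flows[key] < 0:
                raise ParameterError(f"kinetics.organ_blood_flows.{key} must be nonnegative")
        for key in _default_volumes():
            if key not in self.organ_volumes:
                raise ParameterError(f"kinetics.organ_volumes missing {key!r}")
            if self.organ_volumes[key] <= 0:
                raise ParameterError(f"kinetics.organ_volumes.{key} must be strictly positive")
        for key in _default_partition():
            if key not in self.partition_coefficients:
                raise ParameterError(f"kinetics.partition_coefficients missing {key!r}")
            if self.partition_coefficients[key] <= 0:
                raise ParameterError(
                    f"kinetics.partition_coefficients.{key} must be strictly positive"
                )
        phs = [p for p, _ in self.solubility_by_ph]
        if len(phs) < 2 or sorted(phs) != phs:
            raise ParameterError(
                "kinetics.solubility_by_ph needs >= 2 points with increasing pH"
            )
        if any(s <= 0 for _, s in self.solubility_by_ph):
            raise ParameterError("kinetics.solubility_by_ph solubilities must be positive")

    @property
    def cardiac_output(self) -> float:
        """Total lung (pulmonary) blood flow; equals venous return, l/h."""
        return float(sum(self.organ_blood_flows.values()))


@dataclass(frozen=True)
class DoseRegimen:
    """Per-os dose events: (time h, amount mg) pairs within a horizon."""

    events: tuple[tuple[float, float], ...]
    horizon: float

    def validate(self) -> None:
        prev = -1.0
        for t, amt in self.events:
            if t < 0:
                raise ParameterError("dose event times must be nonnegative")
            if t <= prev:
                raise ParameterError("dose event times must be strictly increasing")
            if amt <= 0:
                raise ParameterError("dose amounts must be positive")
            prev = t
        if self.events and self.events[-1][0] > self.horizon:
            raise ParameterError("dose events must lie within the regimen horizon")

    @staticmethod
    def repeated(amount_mg: float, interval_h: float, n_doses: int,
                 horizon: float) -> "DoseRegimen":
        events = tuple((i * interval_h, amount_mg) for i in range(n_doses))
        reg = DoseRegimen(events=events, horizon=horizon)
        reg.validate()
        return reg
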