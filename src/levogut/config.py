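"""Configuration tree: defaults, YAML loading, validation and constructors.

There is a single source of truth for every model constant (prandial
physiology, kinetic defaults, coupling step and horizon, carrier
parameters, efficacy thresholds): the default tree below.  A user YAML/JSON
file is deep-merged onto it; unknown keys are rejected with a path-qualified
message.
"""

from __future__ import annotations

import copy
import json
from typing import Any, Mapping, Optional

import yaml

from .coupling import CouplingConfig
from .network import TransporterCatalog
from .params import (
    LEVODOPA_MW,
    DoseRegimen,
    KineticParameters,
    PhysiologyParameters,
    _default_flows,
    _default_partition,
    _default_volumes,
)


class ConfigError(ValueError):
    """Schema violation with the offending key path."""


DEFAULT_CONFIG: dict[str, Any] = {
    "physiology": {
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
        "si_ph_profile": [6.0, 6.2, 6.4, 6.6, 6.8, 7.0, 7.2],
        "segment_volumes": [50.0, 50.0, 50.0, 40.0, 40.0, 40.0, 40.0],
        "segment_dry_weight": [0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05],
        "body_weight": 70.0,
        "colon_ph": 6.8,
    },
    "kinetics": {
        "organ_blood_flows": _default_flows(),
        "organ_volumes": _default_volumes(),
        "partition_coefficients": _default_partition(),
        "hepatic_clearance": 20.0,
        "renal_clearance": 6.0,
        "k_deg_stomach": 0.3,
        "k_deg_lumen": 0.5,
        "dissolution_coefficient": 2.0,
        "solubility_by_ph": [[2.0, 3.5], [5.0, 1.5], [7.4, 1.0]],
        "ka_fallback": 2.5,
        "basolateral_rate": 10.0,
        "colon_elimination_rate": 0.5,
    },
    "regimen": {
        "amount_mg": 100.0,
        "interval_h": 6.0,
        "n_doses": 3,
        "horizon_h": 18.0,
    },
    "solver": {"rtol": 1e-8, "atol": 1e-10, "output_dt": 0.02},
    "coupling": {
        "step": 0.1,
        "duration": 18.0,
        "epsilon_lum": 1e-6,
        "molecular_weight": LEVODOPA_MW,
        "v_t": 15.0,
        "k_ts": 0.2,
        "aa_absorption_rate": 3.0,
        "aa_plasma_clearance": 0.25,
        "aa_plasma_volume": 15.0,
        "fasting_plasma_aa": 0.12,
    },
    "network": {"levodopa_rank": 15, "split_fraction_uniporter": 0.8},
    # Stage-specific efficacy thresholds (mg/l); placeholder defaults,
    # strictly increasing with disease stage, meant to be user-supplied.
    "thresholds": {"HY1": 0.5, "HY2": 0.9, "HY3": 1.4, "HY4": 2.0},
    "diet": {
        "protein_g_per_kg": 0.8,
        "lpd_dose_mg": 200.0,
        "lpd_species": "equimolar",
        "prd_plasma_multiplier": 3.0,
        "serine_meal_mmol": 50.0,
        "serine_delay_h": 1.0,
        "meal_free_fraction": 1.0,
    },
}

# Mapping-valued nodes whose keys are data (species, organs), not schema.
_OPEN_KEY_PATHS = {
    "kinetics.organ_blood_flows",
    "kinetics.organ_volumes",
    "kinetics.partition_coefficients",
    "thresholds",
}


def _merge(default: Any, override: Any, path: str) -> Any:
    if isinstance(default, dict):
        if not isinstance(override, dict):
            raise ConfigError(f"{path or 'config'}: expected a mapping")
        out = copy.deepcopy(default)
        open_keys = path in _OPEN_KEY_PATHS
        for key, val in override.items():
            child = f"{path}.{key}" if path else str(key)
            if key not in default and not open_keys:
                raise ConfigError(f"unknown configuration key: {child}")
            out[key] = _merge(default.get(key), val, child) \
                if key in default else copy.deepcopy(val)
        return out
    return copy.deepcopy(override)


def load_config(path: Optional[str] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> dict[str, Any]:
    """Load and validate a YAML/JSON configuration file.

    Omitted sections fall back to the defaults (prandial physiology
    pre-filled); unknown keys raise :class:`ConfigError` naming the key.
    """
    tree = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("top-level configuration must be a mapping")
        tree = _merge(tree, user, "")
    if overrides:
        tree = _merge(tree, dict(overrides), "")
    return tree


def dump_config(cfg: Mapping[str, Any], path: str) -> None:
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(cfg, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(dict(cfg), fh, sort_keys=True)


# --------------------------------------------------------------------------
# constructors

def physiology_from_config(cfg: Mapping[str, Any],
                           prandial: str = "fasted") -> PhysiologyParameters:
    p = cfg["physiology"]
    if prandial not in ("fasted", "fed"):
        raise ConfigError(f"unknown prandial state {prandial!r}")
    return PhysiologyParameters(
        **p[prandial],
        si_ph_profile=tuple(p["si_ph_profile"]),
        segment_volumes=tuple(p["segment_volumes"]),
        segment_dry_weight=tuple(p["segment_dry_weight"]),
        body_weight=p["body_weight"],
        colon_ph=p["colon_ph"],
    )


def kinetics_from_config(cfg: Mapping[str, Any]) -> KineticParameters:
    k = cfg["kinetics"]
    return KineticParameters(
        organ_blood_flows=dict(k["organ_blood_flows"]),
        organ_volumes=dict(k["organ_volumes"]),
        partition_coefficients=dict(k["partition_coefficients"]),
        hepatic_clearance=k["hepatic_clearance"],
        renal_clearance=k["renal_clearance"],
        k_deg_stomach=k["k_deg_stomach"],
        k_deg_lumen=k["k_deg_lumen"],
        dissolution_coefficient=k["dissolution_coefficient"],
        solubility_by_ph=tuple((ph, s) for ph, s in k["solubility_by_ph"]),
        ka_fallback=k["ka_fallback"],
        basolateral_rate=k["basolateral_rate"],
        colon_elimination_rate=k["colon_elimination_rate"],
    )


def regimen_from_config(cfg: Mapping[str, Any]) -> DoseRegimen:
    r = cfg["regimen"]
    return DoseRegimen.repeated(r["amount_mg"], r["interval_h"], r["n_doses"],
                                r["horizon_h"])


def coupling_from_config(cfg: Mapping[str, Any]) -> CouplingConfig:
    return CouplingConfig(**cfg["coupling"])


def catalog_from_config(cfg: Mapping[str, Any]) -> TransporterCatalog:
    n = cfg["network"]
    return TransporterCatalog(
        levodopa_rank=n["levodopa_rank"],
        split_fraction_uniporter=n["split_fraction_uniporter"],
    )
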