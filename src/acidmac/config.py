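"""Run configuration: defaults, validation, YAML/JSON round-tripping.

All model parameters live in one nested mapping with documented defaults.
Loading merges a user file over the defaults, rejecting unknown keys and
naming the offending key on any constraint violation, so a saved config
always round-trips to an identical object.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .grid import FIELD_NAMES, H_NEUTRAL
from .macrophage import INSENSITIVE, SENSITIVE, MacrophageParams
from .tumour import MetabolismParams

SCHEMA_VERSION = 1

HOURS_PER_YEAR = 24 * 365  # 8760

_LN2 = 0.6931471805599453

DEFAULTS = {
    "schema_version": SCHEMA_VERSION,
    "grid": {
        "width": 50,
        "height": 50,
        "site_spacing": 20.0,        # µm, one cell diameter
        "vessel_density": 0.05,      # fraction of sites that are vessels
        "ph_min": 6.0,
        "ph_max": 7.6,
    },
    # Diffusion coefficients are µm²/s from the hybrid-CA literature; decay
    # rates are 1/s (cytokine half-life 1 h; proton buffering half-life 3 h
    # towards the arterial baseline); vessel values are the Dirichlet
    # concentrations restored at vessel sites (normalised units for oxygen
    # and glucose, mol/L for protons).
    "fields": {
        "oxygen": {"diffusion_coefficient": 1820.0, "decay_rate": 0.0,
                   "vessel_value": 1.0, "baseline": 0.0},
        "glucose": {"diffusion_coefficient": 500.0, "decay_rate": 0.0,
                    "vessel_value": 1.0, "baseline": 0.0},
        "proton": {"diffusion_coefficient": 1080.0, "decay_rate": _LN2 / (3 * 3600.0),
                   "vessel_value": H_NEUTRAL, "baseline": H_NEUTRAL},
        "pro_cytokine": {"diffusion_coefficient": 100.0, "decay_rate": _LN2 / 3600.0,
                         "vessel_value": 0.0, "baseline": 0.0},
        "anti_cytokine": {"diffusion_coefficient": 100.0, "decay_rate": _LN2 / 3600.0,
                          "vessel_value": 0.0, "baseline": 0.0},
    },
    "numerics": {
        "substeps_per_step": 10,     # field sub-steps per 1 h cell step
        "stability_fraction": 0.2,   # target D*dt/dx² for the fastest field
    },
    "tumour": {
        "ox_flux_max": 1.0,
        "gly_flux_base": 1.0,
        "atp_per_ox": 29.0,
        "atp_per_gly": 2.0,
        "k_oxygen": 0.3,
        "k_glucose": 0.3,
        "oxygen_per_ox": 0.12,
        "glucose_per_flux": 0.004,
        "proton_per_gly": 1.0e-8,
        "atp_death": 6.0,
        "atp_quiescence": 12.0,
        "acid_death_prob": 0.3,
        "necrotic_lysis_prob": 0.02,
        "normal_turnover_prob": 0.002,
        "division_time": 24.0,
        "g_max": 40.0,
        "mutation_prob": 0.1,
        "gly_mutation_step": 0.5,
        "acid_mutation_step": 0.05,
        "acid_resistance_min": 6.0,
        "acid_resistance_max": 7.1,
        "normal_acid_threshold": 6.9,
        "initial_cluster_size": 9,
        "initial_glycolytic_rate": 20.0,
        "initial_acid_resistance": 6.3,
    },
    "macrophages": {
        "count_fraction": 0.04,
        "p_kill": 1.0,
        "p_clear": 1.0,
        "capacity": 4,
        "digestion_time": 6.0,
        "s_pro": 0.5,
        "s_anti": 0.5,
        "p_move": 0.7,
        "k_half_pro": 0.3,
        "k_half_anti": 0.3,
        "scenario": SENSITIVE,
    },
    "experiment": {
        "n_replicates": 20,
        "takeover_threshold": 0.9,
        "time_cap_years": 10.0,
        "base_seed": 0,
    },
}


class RunConfig:
    """Validated nested configuration with attribute-style section access."""

    def __init__(self, data: dict | None = None):
        merged = copy.deepcopy(DEFAULTS)
        if data:
            _merge(merged, data, path="")
        _validate(merged)
        self._data = merged

    def __getitem__(self, key):
        return self._data[key]

    def __eq__(self, other):
        return isinstance(other, RunConfig) and self._data == other._data

    @property
    def data(self) -> dict:
        return copy.deepcopy(self._data)

    def section(self, name: str) -> dict:
        return copy.deepcopy(self._data[name])

    def metabolism_params(self) -> MetabolismParams:
        t = self._data["tumour"]
        return MetabolismParams(
            ox_flux_max=t["ox_flux_max"], gly_flux_base=t["gly_flux_base"],
            atp_per_ox=t["atp_per_ox"], atp_per_gly=t["atp_per_gly"],
            k_oxygen=t["k_oxygen"], k_glucose=t["k_glucose"],
            oxygen_per_ox=t["oxygen_per_ox"], glucose_per_flux=t["glucose_per_flux"],
            proton_per_gly=t["proton_per_gly"], atp_death=t["atp_death"],
            atp_quiescence=t["atp_quiescence"], acid_death_prob=t["acid_death_prob"],
            necrotic_lysis_prob=t["necrotic_lysis_prob"],
            normal_turnover_prob=t["normal_turnover_prob"],
            division_time=t["division_time"], g_max=t["g_max"],
            mutation_prob=t["mutation_prob"], gly_mutation_step=t["gly_mutation_step"],
            acid_mutation_step=t["acid_mutation_step"],
            acid_resistance_bounds=(t["acid_resistance_min"], t["acid_resistance_max"]),
            normal_acid_threshold=t["normal_acid_threshold"],
        )

    def macrophage_params(self) -> MacrophageParams:
        m = self._data["macrophages"]
        return MacrophageParams(
            count_fraction=m["count_fraction"], p_kill=m["p_kill"],
            p_clear=m["p_clear"], capacity=m["capacity"],
            digestion_time=m["digestion_time"], s_pro=m["s_pro"],
            s_anti=m["s_anti"], p_move=m["p_move"],
            k_half_pro=m["k_half_pro"], k_half_anti=m["k_half_anti"],
        )

    @property
    def time_cap_hours(self) -> float:
        return self._data["experiment"]["time_cap_years"] * HOURS_PER_YEAR

    def settings_hash(self) -> str:
        """Stable hash of the full configuration content."""
        blob = json.dumps(self._data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self._data, sort_keys=True))


def _merge(base: dict, override: dict, path: str) -> None:
    if not isinstance(override, dict):
        raise ConfigurationError(f"config section {path or '<root>'!r} must be a mapping")
    for key, value in override.items():
        full = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigurationError(f"unknown config key {full!r}")
        if isinstance(base[key], dict):
            _merge(base[key], value, full)
        else:
            base[key] = value


def _require(cond: bool, key: str, constraint: str) -> None:
    if not cond:
        raise ConfigurationError(f"config key {key!r} violates constraint: {constraint}")


def _validate(d: dict) -> None:
    grd = d["grid"]
    _require(int(grd["width"]) >= 4 and int(grd["height"]) >= 4,
             "grid.width/height", "must be >= 4")
    _require(0 < grd["vessel_density"] < 0.2, "grid.vessel_density", "0 < density < 0.2")
    _require(grd["ph_min"] < grd["ph_max"], "grid.ph_min", "ph_min < ph_max")
    for name in FIELD_NAMES:
        f = d["fields"][name]
        _require(f["diffusion_coefficient"] >= 0,
                 f"fields.{name}.diffusion_coefficient", ">= 0")
        _require(f["decay_rate"] >= 0, f"fields.{name}.decay_rate", ">= 0")
        _require(f["vessel_value"] >= 0, f"fields.{name}.vessel_value", ">= 0")
    num = d["numerics"]
    _require(int(num["substeps_per_step"]) >= 1, "numerics.substeps_per_step", ">= 1")
    _require(0 < num["stability_fraction"] <= 0.25,
             "numerics.stability_fraction", "0 < fraction <= 0.25")
    exp = d["experiment"]
    _require(0 < exp["takeover_threshold"] <= 1,
             "experiment.takeover_threshold", "0 < threshold <= 1")
    _require(int(exp["n_replicates"]) >= 1, "experiment.n_replicates", ">= 1")
    _require(exp["time_cap_years"] > 0, "experiment.time_cap_years", "> 0")
    mac = d["macrophages"]
    _require(mac["scenario"] in (SENSITIVE, INSENSITIVE),
             "macrophages.scenario", f"one of {SENSITIVE!r}, {INSENSITIVE!r}")
    tum = d["tumour"]
    _require(tum["atp_quiescence"] > tum["atp_death"],
             "tumour.atp_quiescence", "must exceed tumour.atp_death")
    _require(tum["initial_cluster_size"] >= 0, "tumour.initial_cluster_size", ">= 0")
    _require(tum["initial_glycolytic_rate"] >= 1.0,
             "tumour.initial_glycolytic_rate", ">= 1")


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file.

    An empty file yields the full-default configuration.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    try:
        data = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config file {p}: {exc}") from exc
    return RunConfig(data or {})
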