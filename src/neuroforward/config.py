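"""Configuration loading and validation.

A single YAML (or JSON) file configures every stage: network, neuron and
synapse parameters, external drive, mean-field settings, LFP kernels,
conductor geometry, sensor and state detection. Units are fixed per field
and encoded in the field names (``*_pF``, ``*_nS``, ``*_mV``, ``*_pA``,
``*_ms``, ``*_um``, ``*_mm``, ``*_S_per_m``); values are never auto-converted.
Defaults are the reference slow-wave study conditions; unknown keys are
rejected with the offending key named.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import data_path
from .adex_spiking import (
    AdExNeuronParams,
    ExternalDrive,
    NetworkSpec,
    SynapseParams,
    TwoCompartmentParams,
)
from .adex_meanfield import OrnsteinUhlenbeckDrive
from .dipole_forward import (
    ConductorModel,
    ConductorPatch,
    DipoleParams,
    HybridCompartmentParams,
    SensorSpec,
)
from .ulfp_kernel import ElectrodeSpec, load_kernels

__all__ = ["RunConfig", "load_and_validate_config", "default_config_dict", "ProvenanceRecord"]

SCHEMA_VERSION = 1

_DEFAULTS = {
    "schema_version": SCHEMA_VERSION,
    "network": {
        "n_total": 10000,
        "frac_excitatory": 0.8,
        "p_connect": 0.05,
        "sheet_extent_mm": [1.0, 1.0],
        "seed": 0,
    },
    "neurons": {
        "excitatory": {
            "C_pF": 200.0,
            "g_L_nS": 10.0,
            "E_L_mV": -63.0,
            "V_T_mV": -50.0,
            "Delta_T_mV": 2.0,
            "a_nS": 0.0,
            "b_pA": 60.0,
            "tau_w_ms": 500.0,
            "V_reset_mV": -65.0,
            "V_spike_cut_mV": 0.0,
            "t_ref_ms": 5.0,
        },
        "inhibitory": {
            "C_pF": 200.0,
            "g_L_nS": 10.0,
            "E_L_mV": -63.0,
            "V_T_mV": -50.0,
            "Delta_T_mV": 0.5,
            "a_nS": 0.0,
            "b_pA": 0.0,
            "tau_w_ms": 500.0,
            "V_reset_mV": -65.0,
            "V_spike_cut_mV": 0.0,
            "t_ref_ms": 5.0,
        },
    },
    "two_compartment": {
        "C_S_pF": 200.0,
        "C_D_pF": 10.0,
        "g_LS_nS": 10.0,
        "g_LD_nS": 2.0,
        "g_A_nS": 400.0,
        "E_L_mV": -63.0,
        "V_T_mV": -50.0,
        "Delta_T_mV": 2.0,
        "a_nS": 0.0,
        "b_pA": 60.0,
        "tau_w_ms": 500.0,
        "V_detect_mV": -40.0,
        "V_reset_mV": -55.0,
        "t_ref_ms": 5.0,
        "p_e1": 0.3,
        "p_e2": 0.7,
        "p_i1": 0.6,
        "p_i2": 0.4,
        # inhibitory point cells of the two-compartment network use their
        # own detection threshold / reset
        "inh_V_detect_mV": -47.5,
        "inh_V_reset_mV": -65.0,
        # the two-compartment network has its own slow-wave drive point
        "drive_rate_hz": 0.32,
        "drive_i_fraction": 0.15,
        "drive_ou_sigma_rel": 0.5,
    },
    "synapses": {
        "q_e_nS": 1.5,
        "q_i_nS": 5.0,
        "tau_e_ms": 5.0,
        "tau_i_ms": 5.0,
        "E_e_mV": 0.0,
        "E_i_mV": -80.0,
    },
    "drive": {
        "rate_hz": 0.32,
        "n_ext": 400,
        # fraction of the drive rate received by inhibitory neurons
        "i_fraction": 0.3,
        # slow global modulation of the drive rate (state initiation)
        "ou_sigma_rel": 0.3,
        "ou_tau_ms": 300.0,
    },
    "spiking": {"duration_ms": 20000.0, "dt_ms": 0.1, "synaptic_delay_ms": 1.0},
    "meanfield": {
        "T_ms": 5.0,
        "dt_ms": 0.1,
        "duration_ms": 30000.0,
        "tf_coeffs_file": None,  # None -> shipped default
        "drive": {
            "rate_hz": 0.528,
            "sigma_hz": 0.0,
            "tau_ms": 100.0,
            "K_ext": None,
            "i_fraction": 0.3,
        },
    },
    "kernels": {"file": None},  # None -> shipped default
    "electrode": {"x_mm": 0.5, "y_mm": 0.5, "z": "surface"},
    "dipole": {"L_um": 322.0, "orientation": [1.0, 0.0, 0.0]},
    "conductor": {
        "patches": [
            {
                "sigma_in_S_per_m": 0.3,  # gray matter
                "sigma_out_S_per_m": 2.1,  # cerebrospinal fluid
                "z_um": 800.0,
                "extent_mm": [1.0, 1.0],
                "center_mm": [0.5, 0.5],
                "grid": [21, 21],
                "label": "surface",
            }
        ]
    },
    "sensor": {"position_mm": [0.0, 0.0, 30.0]},
    "detection": {
        "k_sd": 3.0,
        "baseline_mode": "mode",
        "min_duration_s": 0.1,
        "merge_gap_s": 0.05,
        "rate_bin_ms": 2.0,
        "rate_smoothing_ms": 6.0,
        "lfp_dt_ms": 1.0,
    },
    "output": {"format": "hdf5", "csv_mirror": True},
}


class ConfigError(ValueError):
    pass


def default_config_dict() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(defaults, user, path=""):
    if not isinstance(user, dict):
        raise ConfigError(f"section '{path or '<root>'}' must be a mapping")
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key '{here}'")
        if isinstance(defaults[key], dict) and not (
            path == "conductor" and key == "patches"
        ):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class ProvenanceRecord:
    config_hash: str
    seed: int
    package_version: str
    timestamp: str
    checksums: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "package_version": self.package_version,
            "timestamp": self.timestamp,
            "checksums": self.checksums,
        }


@dataclass
class RunConfig:
    """Validated configuration with typed accessors for every stage."""

    raw: dict

    def __post_init__(self):
        if self.raw.get("schema_version") != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.raw.get('schema_version')!r}"
            )
        # eager construction validates ranges through the dataclasses
        self.network_spec()
        self.neuron_params("excitatory")
        self.neuron_params("inhibitory")
        self.synapse_params()
        self.two_compartment_params()
        self.dipole_params(n_e=self.network_spec().n_excitatory)
        self.conductor_model()
        self.sensor_spec()
        d = self.raw["drive"]
        if not 0.0 <= float(d["i_fraction"]) <= 1.0:
            raise ConfigError("drive.i_fraction must lie in [0, 1]")
        if float(d["rate_hz"]) < 0:
            raise ConfigError("drive.rate_hz must be non-negative")

    # -- typed accessors ---------------------------------------------------
    def network_spec(self) -> NetworkSpec:
        n = self.raw["network"]
        return NetworkSpec(
            n_total=int(n["n_total"]),
            frac_excitatory=float(n["frac_excitatory"]),
            p_connect=float(n["p_connect"]),
            sheet_extent_mm=tuple(n["sheet_extent_mm"]),
            seed=int(n["seed"]),
        )

    def neuron_params(self, which: str) -> AdExNeuronParams:
        return AdExNeuronParams(**self.raw["neurons"][which])

    def synapse_params(self) -> SynapseParams:
        return SynapseParams(**self.raw["synapses"])

    def two_compartment_params(self) -> TwoCompartmentParams:
        tc = {
            k: v
            for k, v in self.raw["two_compartment"].items()
            if not k.startswith(("inh_", "drive_"))
        }
        return TwoCompartmentParams(**tc)

    def two_compartment_drive(self, is_excitatory) -> ExternalDrive:
        tc = self.raw["two_compartment"]
        d = self.raw["drive"]
        rate = float(tc["drive_rate_hz"])
        rates = np.where(
            np.asarray(is_excitatory), rate, rate * float(tc["drive_i_fraction"])
        )
        return ExternalDrive(
            rate_hz=rates,
            n_ext=int(d["n_ext"]),
            ou_sigma_rel=float(tc["drive_ou_sigma_rel"]),
            ou_tau_ms=float(d["ou_tau_ms"]),
        )

    def two_compartment_inhibitory(self) -> AdExNeuronParams:
        base = dict(self.raw["neurons"]["inhibitory"])
        base["V_spike_cut_mV"] = self.raw["two_compartment"]["inh_V_detect_mV"]
        base["V_reset_mV"] = self.raw["two_compartment"]["inh_V_reset_mV"]
        return AdExNeuronParams(**base)

    def external_drive(self, is_excitatory=None, rate_hz=None) -> ExternalDrive:
        d = self.raw["drive"]
        rate = float(d["rate_hz"]) if rate_hz is None else float(rate_hz)
        f_i = float(d["i_fraction"])
        if f_i < 1.0:
            if is_excitatory is None:
                raise ConfigError(
                    "drive.i_fraction < 1 needs the connectivity labels"
                )
            rate = np.where(np.asarray(is_excitatory), rate, rate * f_i)
        return ExternalDrive(
            rate_hz=rate,
            n_ext=int(d["n_ext"]),
            ou_sigma_rel=float(d["ou_sigma_rel"]),
            ou_tau_ms=float(d["ou_tau_ms"]),
        )

    def meanfield_drive(self) -> OrnsteinUhlenbeckDrive:
        d = self.raw["meanfield"]["drive"]
        return OrnsteinUhlenbeckDrive(
            rate_hz=float(d["rate_hz"]),
            sigma_hz=float(d["sigma_hz"]),
            tau_ms=float(d["tau_ms"]),
            K_ext=d["K_ext"],
            i_fraction=float(d["i_fraction"]),
        )

    def kernels(self) -> dict:
        path = self.raw["kernels"]["file"] or data_path("kernels_default.yaml")
        return load_kernels(path)

    def tf_coeffs_file(self):
        return self.raw["meanfield"]["tf_coeffs_file"] or data_path(
            "tf_coeffs_default.yaml"
        )

    def electrode(self) -> ElectrodeSpec:
        e = self.raw["electrode"]
        return ElectrodeSpec(float(e["x_mm"]), float(e["y_mm"]), e["z"])

    def dipole_params(self, n_e: int) -> DipoleParams:
        d = self.raw["dipole"]
        return DipoleParams(
            n_e=n_e, L_um=float(d["L_um"]), orientation=np.asarray(d["orientation"])
        )

    def hybrid_params(self) -> HybridCompartmentParams:
        net = self.network_spec()
        tc = self.raw["two_compartment"]
        syn = self.raw["synapses"]
        p_o = net.p_connect
        return HybridCompartmentParams(
            g_L1_nS=float(tc["g_LS_nS"]),
            g_L2_nS=float(tc["g_LD_nS"]),
            E_L_mV=float(tc["E_L_mV"]),
            R_A_MOhm=1e3 / float(tc["g_A_nS"]),
            K_e1=net.n_excitatory * p_o * float(tc["p_e1"]),
            K_e2=net.n_excitatory * p_o * float(tc["p_e2"]),
            K_i1=net.n_inhibitory * p_o * float(tc["p_i1"]),
            K_i2=net.n_inhibitory * p_o * float(tc["p_i2"]),
            q_e_nS=float(syn["q_e_nS"]),
            q_i_nS=float(syn["q_i_nS"]),
            tau_e_ms=float(syn["tau_e_ms"]),
            tau_i_ms=float(syn["tau_i_ms"]),
            E_e_mV=float(syn["E_e_mV"]),
            E_i_mV=float(syn["E_i_mV"]),
        )

    def conductor_model(self) -> ConductorModel:
        patches = [
            ConductorPatch(
                sigma_in_S_per_m=float(p["sigma_in_S_per_m"]),
                sigma_out_S_per_m=float(p["sigma_out_S_per_m"]),
                z_um=float(p["z_um"]),
                extent_mm=tuple(p.get("extent_mm", (1.0, 1.0))),
                center_mm=tuple(p.get("center_mm", (0.5, 0.5))),
                grid=tuple(p.get("grid", (21, 21))),
                label=p.get("label", ""),
            )
            for p in self.raw["conductor"]["patches"]
        ]
        return ConductorModel(patches)

    def sensor_spec(self) -> SensorSpec:
        return SensorSpec(np.asarray(self.raw["sensor"]["position_mm"], dtype=float))

    def detection_kwargs(self) -> dict:
        d = self.raw["detection"]
        return {
            "k_sd": float(d["k_sd"]),
            "baseline_mode": d["baseline_mode"],
            "min_duration_s": float(d["min_duration_s"]),
            "merge_gap_s": float(d["merge_gap_s"]),
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_and_validate_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config, fill defaults, validate, reject unknown keys.

    ``path=None`` yields the shipped defaults; ``overrides`` (a nested dict)
    is merged last.
    """
    raw = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"configuration file not found: {p}")
        with open(p) as fh:
            raw = yaml.safe_load(fh) or {}
    merged = _merge(_DEFAULTS, raw)
    if overrides:
        merged = _merge(merged, overrides)
    try:
        return RunConfig(merged)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid configuration: {exc}") from exc
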