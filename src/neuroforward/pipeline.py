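"""End-to-end validation pipeline: slow-wave LFP and MEG from both routes.

Four headline experiments, all driven by one :class:`~neuroforward.config.RunConfig`:

1. mean-field slow waves -> rate-based kernel LFP -> up-state statistics;
2. spiking-network slow waves -> spike-based kernel LFP -> up-state statistics;
3. mean-field slow waves -> axial-current + conduction dipoles -> MEG
   up-state statistics;
4. two-compartment spiking network -> mean axial current -> MEG up-state
   statistics.

``reproduce_reference()`` runs all four and writes a JSON report comparing
the measured amplitudes/durations with the published reference values.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .adex_meanfield import MeanFieldParams, MeanFieldTrace, load_tf_coeffs, simulate_meanfield
from .adex_spiking import (
    build_network,
    population_rates,
    simulate_point_network,
    simulate_two_compartment_network,
)
from .config import ProvenanceRecord, RunConfig, load_and_validate_config
from .dipole_forward import meg_from_meanfield, meg_from_spiking
from .state_metrics import detect_states, summarize_states
from .ulfp_kernel import lfp_from_rates, lfp_from_spikes, rate_lfp_field

__all__ = [
    "REFERENCE_VALUES",
    "ExperimentResult",
    "meanfield_slow_waves",
    "spiking_slow_waves",
    "lfp_meanfield_experiment",
    "lfp_spiking_experiment",
    "meg_meanfield_experiment",
    "meg_spiking_experiment",
    "reproduce_reference",
]

#: Published slow-wave statistics used for comparison in reports
#: (mean, SD) per experiment.
REFERENCE_VALUES = {
    "lfp_meanfield": {"amplitude_uV": (209.0, 2.0), "duration_s": (0.57, 0.09)},
    "lfp_spiking": {"amplitude_uV": (206.0, 26.0), "duration_s": (0.59, 0.14)},
    "meg_meanfield": {"amplitude_fT": (305.0, 3.0), "duration_s": (0.53, 0.01)},
    "meg_spiking": {"amplitude_fT": (276.0, 40.0), "duration_s": (0.87, 0.43)},
}


@dataclass
class ExperimentResult:
    name: str
    summary: dict
    n_states: int

    def to_dict(self) -> dict:
        return {"name": self.name, "n_states": self.n_states, **self.summary}


def _mf_params(cfg: RunConfig) -> MeanFieldParams:
    coeffs_e, coeffs_i = load_tf_coeffs(cfg.tf_coeffs_file())
    net = cfg.network_spec()
    return MeanFieldParams(
        neuron_e=cfg.neuron_params("excitatory"),
        neuron_i=cfg.neuron_params("inhibitory"),
        syn=cfg.synapse_params(),
        coeffs_e=coeffs_e,
        coeffs_i=coeffs_i,
        n_e=net.n_excitatory,
        n_i=net.n_inhibitory,
        p_connect=net.p_connect,
        T_ms=float(cfg.raw["meanfield"]["T_ms"]),
    )


def meanfield_slow_waves(cfg: RunConfig, seed: int = 0, duration_ms=None) -> MeanFieldTrace:
    mf = cfg.raw["meanfield"]
    return simulate_meanfield(
        _mf_params(cfg),
        duration_ms=float(duration_ms or mf["duration_ms"]),
        dt_ms=float(mf["dt_ms"]),
        drive=cfg.meanfield_drive(),
        seed=seed,
    )


def spiking_slow_waves(cfg: RunConfig, seed: int = 0, duration_ms=None, two_compartment=False):
    conn = build_network(cfg.network_spec(), seed=cfg.network_spec().seed)
    sp = cfg.raw["spiking"]
    duration = float(duration_ms or sp["duration_ms"])
    if two_compartment:
        drive = cfg.two_compartment_drive(conn.is_excitatory)
        return conn, simulate_two_compartment_network(
            conn,
            cfg.two_compartment_params(),
            cfg.two_compartment_inhibitory(),
            cfg.synapse_params(),
            drive,
            duration,
            dt_ms=float(sp["dt_ms"]),
            seed=seed,
            axial_subsample=10,
            synaptic_delay_ms=float(sp["synaptic_delay_ms"]),
        )
    drive = cfg.external_drive(conn.is_excitatory)
    return conn, simulate_point_network(
        conn,
        cfg.neuron_params("excitatory"),
        cfg.neuron_params("inhibitory"),
        cfg.synapse_params(),
        drive,
        duration,
        dt_ms=float(sp["dt_ms"]),
        seed=seed,
        synaptic_delay_ms=float(sp["synaptic_delay_ms"]),
    )


def _detect(cfg: RunConfig, times_ms, signal, discard_ms=500.0):
    keep = np.asarray(times_ms) >= discard_ms
    segs, base, thr = detect_states(
        np.asarray(times_ms)[keep] * 1e-3,
        np.asarray(signal)[keep],
        **cfg.detection_kwargs(),
    )
    return summarize_states(segs, base, thr)


def lfp_meanfield_experiment(cfg: RunConfig, seed: int = 0, duration_ms=None):
    """Mean-field -> rate-kernel LFP -> up-state statistics."""
    trace = meanfield_slow_waves(cfg, seed=seed, duration_ms=duration_ms)
    kern = cfg.kernels()
    net = cfg.network_spec()
    ds = max(1, int(round(cfg.raw["detection"]["lfp_dt_ms"] / cfg.raw["meanfield"]["dt_ms"])))
    t = trace.times_ms[::ds]
    lfp = lfp_from_rates(
        t,
        trace.nu_e_Hz[::ds],
        trace.nu_i_Hz[::ds],
        net.n_excitatory,
        net.n_inhibitory,
        [cfg.electrode()],
        kern["excitatory"],
        kern["inhibitory"],
    )
    s = _detect(cfg, t, lfp.V_uV[0])
    result = ExperimentResult(
        "lfp_meanfield",
        {
            "amplitude_uV": s.amplitude_mean,
            "amplitude_sd_uV": s.amplitude_sd,
            "duration_s": s.duration_mean_s,
            "duration_sd_s": s.duration_sd_s,
        },
        s.n_states,
    )
    return result, trace, lfp


def lfp_spiking_experiment(cfg: RunConfig, seed: int = 0, duration_ms=None):
    """Spiking network -> spike-kernel LFP -> up-state statistics."""
    conn, (rec, _) = spiking_slow_waves(cfg, seed=seed, duration_ms=duration_ms)
    kern = cfg.kernels()
    dt_lfp = float(cfg.raw["detection"]["lfp_dt_ms"])
    t = np.arange(0.0, rec.duration_ms, dt_lfp)
    lfp = lfp_from_spikes(
        rec, [cfg.electrode()], kern["excitatory"], kern["inhibitory"], t
    )
    s = _detect(cfg, t, lfp.V_uV[0])
    result = ExperimentResult(
        "lfp_spiking",
        {
            "amplitude_uV": s.amplitude_mean,
            "amplitude_sd_uV": s.amplitude_sd,
            "duration_s": s.duration_mean_s,
            "duration_sd_s": s.duration_sd_s,
        },
        s.n_states,
    )
    return result, rec, lfp


def meg_meanfield_experiment(cfg: RunConfig, seed: int = 0, duration_ms=None, trace=None):
    """Mean-field -> stationary axial current + conduction dipole -> MEG."""
    if trace is None:
        trace = meanfield_slow_waves(cfg, seed=seed, duration_ms=duration_ms)
    net = cfg.network_spec()
    kern = cfg.kernels()
    ds = max(1, int(round(cfg.raw["detection"]["lfp_dt_ms"] / cfg.raw["meanfield"]["dt_ms"])))
    sub = MeanFieldTrace(
        trace.times_ms[::ds], trace.nu_e_Hz[::ds], trace.nu_i_Hz[::ds], trace.W_pA[::ds]
    )
    field = rate_lfp_field(
        sub.times_ms,
        sub.nu_e_Hz,
        sub.nu_i_Hz,
        net.n_excitatory,
        net.n_inhibitory,
        kern["excitatory"],
        kern["inhibitory"],
        sheet_extent_mm=net.sheet_extent_mm,
    )
    ts = meg_from_meanfield(
        sub,
        cfg.hybrid_params(),
        cfg.dipole_params(net.n_excitatory),
        cfg.sensor_spec(),
        cm=cfg.conductor_model(),
        lfp_field=field,
    )
    signal = np.linalg.norm(ts.B_total_fT, axis=1) * np.sign(
        ts.B_total_fT @ _principal_direction(ts.B_total_fT)
    )
    s = _detect(cfg, sub.times_ms, signal)
    result = ExperimentResult(
        "meg_meanfield",
        {
            "amplitude_fT": s.amplitude_mean,
            "amplitude_sd_fT": s.amplitude_sd,
            "duration_s": s.duration_mean_s,
            "duration_sd_s": s.duration_sd_s,
        },
        s.n_states,
    )
    return result, trace, ts


def meg_spiking_experiment(cfg: RunConfig, seed: int = 0, duration_ms=None):
    """Two-compartment spiking network -> mean axial current -> MEG."""
    conn, (rec, axial) = spiking_slow_waves(
        cfg, seed=seed, duration_ms=duration_ms, two_compartment=True
    )
    net = cfg.network_spec()
    ts = meg_from_spiking(
        axial, cfg.dipole_params(net.n_excitatory), cfg.sensor_spec()
    )
    signal = np.linalg.norm(ts.B_total_fT, axis=1) * np.sign(
        ts.B_total_fT @ _principal_direction(ts.B_total_fT)
    )
    s = _detect(cfg, ts.times_ms, signal)
    result = ExperimentResult(
        "meg_spiking",
        {
            "amplitude_fT": s.amplitude_mean,
            "amplitude_sd_fT": s.amplitude_sd,
            "duration_s": s.duration_mean_s,
            "duration_sd_s": s.duration_sd_s,
        },
        s.n_states,
    )
    return result, rec, ts


def _principal_direction(B: np.ndarray) -> np.ndarray:
    """Unit vector of the dominant field component (for a signed scalar trace)."""
    idx = int(np.argmax(np.abs(B).max(axis=0)))
    e = np.zeros(3)
    e[idx] = 1.0
    return e


def reproduce_reference(out_dir, seed: int = 0, config_path=None, fast: bool = False) -> dict:
    """Run the four headline experiments and write ``report.json``.

    ``fast=True`` shortens the spiking runs (demonstration mode); the
    defaults reproduce the full validation protocol.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_and_validate_config(config_path)
    dur_spk = 6000.0 if fast else None
    dur_mf = 10000.0 if fast else None
    results = {}
    r, _, _ = lfp_meanfield_experiment(cfg, seed=seed, duration_ms=dur_mf)
    results["lfp_meanfield"] = r
    r, _, _ = meg_meanfield_experiment(cfg, seed=seed, duration_ms=dur_mf)
    results["meg_meanfield"] = r
    r, _, _ = lfp_spiking_experiment(cfg, seed=seed, duration_ms=dur_spk)
    results["lfp_spiking"] = r
    r, _, _ = meg_spiking_experiment(cfg, seed=seed, duration_ms=dur_spk)
    results["meg_spiking"] = r

    report = {"comparisons": [], "results": {}, "provenance": {}}
    for name, res in results.items():
        report["results"][name] = res.to_dict()
        ref = REFERENCE_VALUES[name]
        for key, (ref_mean, ref_sd) in ref.items():
            run_key = key if key in res.summary else None
            if run_key is None:
                continue
            run_val = res.summary[run_key]
            sd_key = (
                key.replace("amplitude_", "amplitude_sd_")
                if key.startswith("amplitude")
                else "duration_sd_s"
            )
            run_sd = res.summary.get(sd_key, 0.0)
            tol = max(ref_sd, run_sd if np.isfinite(run_sd) else 0.0)
            ok = bool(np.isfinite(run_val) and abs(run_val - ref_mean) <= tol)
            report["comparisons"].append(
                {
                    "experiment": name,
                    "quantity": key,
                    "measured": run_val,
                    "measured_sd": run_sd,
                    "reference": ref_mean,
                    "reference_sd": ref_sd,
                    "within_tolerance": ok,
                }
            )
    prov = ProvenanceRecord(
        config_hash=cfg.hash(),
        seed=seed,
        package_version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    report["provenance"] = prov.to_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
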