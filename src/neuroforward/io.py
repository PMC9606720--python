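"""Readers and writers for simulation products.

HDF5 is the canonical container; CSV mirrors exist for 1-D/2-D outputs.
Every writer/reader pair round-trips its schema exactly.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .adex_meanfield import MeanFieldTrace
from .adex_spiking import AxialCurrentTrace, SpikeRecord
from .ulfp_kernel import LFPTrace

__all__ = [
    "write_spikes_h5",
    "read_spikes_h5",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_trace_h5",
    "read_trace_h5",
    "write_meanfield_csv",
    "read_meanfield_csv",
    "write_lfp_csv",
    "write_dipole_h5",
]


def write_spikes_h5(path, rec: SpikeRecord):
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("ids", data=np.asarray(rec.spike_ids, dtype=np.int64))
        g.create_dataset("times", data=np.asarray(rec.spike_times_ms, dtype=float))
        n = f.create_group("neurons")
        n.create_dataset("xy", data=np.asarray(rec.positions_mm, dtype=float))
        n.create_dataset("label", data=np.asarray(rec.is_excitatory, dtype=np.int8))
        f.attrs["n_neurons"] = rec.n_neurons
        f.attrs["duration_ms"] = rec.duration_ms


def read_spikes_h5(path) -> SpikeRecord:
    with h5py.File(path, "r") as f:
        return SpikeRecord(
            n_neurons=int(f.attrs["n_neurons"]),
            spike_ids=f["spikes/ids"][:],
            spike_times_ms=f["spikes/times"][:],
            positions_mm=f["neurons/xy"][:],
            is_excitatory=f["neurons/label"][:].astype(bool),
            duration_ms=float(f.attrs["duration_ms"]),
        )


def write_spikes_csv(path, rec: SpikeRecord):
    """Two CSVs: ``<path>`` with (neuron_id, time_ms) and
    ``<path stem>_neurons.csv`` with positions and labels."""
    path = Path(path)
    pd.DataFrame(
        {"neuron_id": rec.spike_ids, "time_ms": rec.spike_times_ms}
    ).to_csv(path, index=False)
    meta = pd.DataFrame(
        {
            "neuron_id": np.arange(rec.n_neurons),
            "x_mm": rec.positions_mm[:, 0],
            "y_mm": rec.positions_mm[:, 1],
            "label": np.where(rec.is_excitatory, "E", "I"),
        }
    )
    meta.to_csv(path.with_name(path.stem + "_neurons.csv"), index=False)


def read_spikes_csv(path, duration_ms: float = 0.0) -> SpikeRecord:
    path = Path(path)
    spikes = pd.read_csv(path)
    meta = pd.read_csv(path.with_name(path.stem + "_neurons.csv"))
    return SpikeRecord(
        n_neurons=len(meta),
        spike_ids=spikes["neuron_id"].to_numpy(dtype=np.int64),
        spike_times_ms=spikes["time_ms"].to_numpy(dtype=float),
        positions_mm=meta[["x_mm", "y_mm"]].to_numpy(dtype=float),
        is_excitatory=(meta["label"] == "E").to_numpy(),
        duration_ms=duration_ms,
    )


def write_trace_h5(path, group: str, times_ms, **datasets):
    mode = "a" if Path(path).exists() else "w"
    with h5py.File(path, mode) as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("times_ms", data=np.asarray(times_ms, dtype=float))
        for name, data in datasets.items():
            g.create_dataset(name, data=np.asarray(data, dtype=float))


def read_trace_h5(path, group: str) -> dict:
    with h5py.File(path, "r") as f:
        g = f[group]
        return {name: g[name][:] for name in g}


def write_meanfield_csv(path, trace: MeanFieldTrace):
    pd.DataFrame(
        {
            "t_ms": trace.times_ms,
            "nu_e_Hz": trace.nu_e_Hz,
            "nu_i_Hz": trace.nu_i_Hz,
            "W_pA": trace.W_pA,
        }
    ).to_csv(path, index=False)


def read_meanfield_csv(path) -> MeanFieldTrace:
    df = pd.read_csv(path)
    return MeanFieldTrace(
        df["t_ms"].to_numpy(),
        df["nu_e_Hz"].to_numpy(),
        df["nu_i_Hz"].to_numpy(),
        df["W_pA"].to_numpy(),
    )


def write_lfp_csv(path, lfp: LFPTrace):
    cols = {"t_ms": lfp.times_ms}
    for k in range(lfp.V_uV.shape[0]):
        el = lfp.electrodes[k] if k < len(lfp.electrodes) else None
        name = f"V_uV_{k}" if el is None else f"V_uV_{el.x_mm}_{el.y_mm}_{el.z}"
        cols[name] = lfp.V_uV[k]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_dipole_h5(path, ts):
    """DipoleTimeSeries -> HDF5 (B_total, B_axial, B_conduction, Q_s, Q_c...)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times_ms", data=ts.times_ms)
        f.create_dataset("Q_s_nAm", data=ts.Q_s_nAm)
        f.create_dataset("Q_c_nAm", data=ts.Q_c_nAm)
        f.create_dataset("B_total_fT", data=ts.B_total_fT)
        f.create_dataset("B_axial_fT", data=ts.B_axial_fT)
        f.create_dataset("B_conduction_fT", data=ts.B_conduction_fT)
        if ts.Q_c_per_patch_nAm is not None:
            f.create_dataset("Q_c_per_patch_nAm", data=ts.Q_c_per_patch_nAm)
        if ts.I_A_pA is not None:
            f.create_dataset("I_A_pA", data=ts.I_A_pA)


def write_axial_csv(path, axial: AxialCurrentTrace):
    pd.DataFrame(
        {"t_ms": axial.times_ms, "mean_I_A_pA": axial.mean_I_A_pA}
    ).to_csv(path, index=False)


def read_axial_csv(path) -> AxialCurrentTrace:
    df = pd.read_csv(path)
    return AxialCurrentTrace(
        df["t_ms"].to_numpy(), df["mean_I_A_pA"].to_numpy()
    )
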