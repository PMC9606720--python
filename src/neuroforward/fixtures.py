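"""Programmatic generators for test and demonstration inputs.

These build the ingredients the forward models consume without running a
network simulation: Poisson spike records on a neuron sheet, constructed
slow-wave-like rate traces, and square-wave test signals for the state
detector. All are deterministic per seed.
"""

from __future__ import annotations

import numpy as np

from .adex_spiking import SpikeRecord

__all__ = ["make_poisson_fixture", "make_square_wave", "make_rate_pulse_train"]


def make_poisson_fixture(
    n_e: int,
    n_i: int,
    rate_profile,
    duration_ms: float,
    sheet_extent_mm=(1.0, 1.0),
    seed: int = 0,
    dt_ms: float = 0.1,
) -> SpikeRecord:
    """Independent (in)homogeneous Poisson spike trains on a uniform sheet.

    ``rate_profile`` is either a scalar rate (Hz), a pair of scalars
    ``(rate_e, rate_i)``, or a callable ``t_ms -> (rate_e, rate_i)``
    evaluated on a ``dt_ms`` grid for inhomogeneous trains.
    """
    rng = np.random.default_rng(seed)
    n = n_e + n_i
    positions = rng.random((n, 2)) * np.asarray(sheet_extent_mm, dtype=float)
    is_exc = np.zeros(n, dtype=bool)
    is_exc[:n_e] = True

    t_grid = np.arange(0.0, duration_ms, dt_ms)
    if callable(rate_profile):
        re_raw, ri_raw = rate_profile(t_grid)
        re_t = np.broadcast_to(np.asarray(re_raw, dtype=float), t_grid.shape)
        ri_t = np.broadcast_to(np.asarray(ri_raw, dtype=float), t_grid.shape)
    else:
        pair = np.atleast_1d(np.asarray(rate_profile, dtype=float))
        re_t = np.full(t_grid.shape, pair[0])
        ri_t = np.full(t_grid.shape, pair[-1])
    if np.any(re_t < 0) or np.any(ri_t < 0):
        raise ValueError("rates must be non-negative")

    ids_out, times_out = [], []
    for rates, idx in ((re_t, np.arange(n_e)), (ri_t, np.arange(n_e, n))):
        if idx.size == 0 or not np.any(rates > 0):
            continue
        lam = rates * 1e-3 * dt_ms  # per-neuron expected count per step
        counts = rng.poisson(lam[None, :].repeat(idx.size, axis=0))
        nz_n, nz_t = np.nonzero(counts)
        reps = counts[nz_n, nz_t]
        ids_out.append(np.repeat(idx[nz_n], reps))
        # uniform jitter within the step keeps trains simple-point-process
        times_out.append(
            np.repeat(t_grid[nz_t], reps) + rng.random(int(reps.sum())) * dt_ms
        )
    if ids_out:
        ids = np.concatenate(ids_out)
        times = np.concatenate(times_out)
        order = np.argsort(times, kind="stable")
        ids, times = ids[order], times[order]
    else:
        ids, times = np.empty(0, dtype=np.int64), np.empty(0)
    return SpikeRecord(
        n_neurons=n,
        spike_ids=ids,
        spike_times_ms=times,
        positions_mm=positions,
        is_excitatory=is_exc,
        duration_ms=duration_ms,
    )


def make_square_wave(
    duration_s: float = 10.0,
    dt_s: float = 0.001,
    period_s: float = 2.0,
    plateau_s: float = 0.5,
    amplitude: float = 10.0,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Baseline-zero square wave with Gaussian noise: a constructed signal
    with known state amplitudes/durations for detector tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt_s)
    phase = np.mod(t, period_s)
    x = np.where(phase < plateau_s, amplitude, 0.0)
    return t, x + noise_sd * rng.standard_normal(t.size)


def make_rate_pulse_train(
    duration_ms: float = 10000.0,
    dt_ms: float = 1.0,
    up_ms: float = 550.0,
    period_ms: float = 1500.0,
    nu_e_up: float = 5.0,
    nu_i_up: float = 12.0,
    edge_ms: float = 30.0,
):
    """Smoothed up/down rate traces emulating slow-wave alternation."""
    t = np.arange(0.0, duration_ms, dt_ms)
    phase = np.mod(t, period_ms)
    gate = ((phase > 100.0) & (phase < 100.0 + up_ms)).astype(float)
    if edge_ms > 0:
        from scipy.ndimage import gaussian_filter1d

        gate = gaussian_filter1d(gate, edge_ms / dt_ms)
    return t, nu_e_up * gate, nu_i_up * gate
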