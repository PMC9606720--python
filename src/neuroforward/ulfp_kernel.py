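"""Unitary-LFP kernel construction and LFP synthesis.

The extracellular potential is modeled as a superposition of unitary LFPs
(uLFPs): the small field transient generated by the postsynaptic currents of a
single presynaptic cell. Each uLFP is a Gaussian in time whose peak amplitude
decays exponentially with radial distance from the source and whose peak time
is delayed by axonal propagation. Two synthesis routes are provided:

* spike-based: every spike of every neuron deposits its kernel at the
  electrode, with per-neuron amplitude and delay (the spiking-network route);
* rate-based: population firing-rate traces are convolved with a
  population-averaged kernel in which the radial decay is replaced by its
  mean over a disk of radius ``2 * lambda`` (factor ``(1 - 3 e^-2)/2``, about
  0.3) and the axonal-propagation term is dropped.

Units: time in ms, in-plane positions in mm, depths and space constants in
micrometers, amplitudes and LFP in microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "UlfpKernel",
    "ElectrodeSpec",
    "LFPTrace",
    "DEPTH_LABELS",
    "disk_average_factor",
    "disk_average_factor_quadrature",
    "evaluate_kernel",
    "population_kernel",
    "lfp_from_spikes",
    "lfp_from_rates",
    "load_kernels",
]

#: Named electrode depths (micrometers): deep layers, soma level, superficial
#: layers and cortical surface.
DEPTH_LABELS = {"deep": -400.0, "soma": 0.0, "superficial": 400.0, "surface": 800.0}


@dataclass
class UlfpKernel:
    """Gaussian uLFP template for one presynaptic cell type.

    Parameters
    ----------
    depths_um, A0_uV:
        Tabulated peak amplitude versus electrode depth. ``A0`` may be
        negative; the sign encodes the polarity of the deflection.
    lambda_um:
        Radial space constant of the amplitude decay.
    sigma_ms:
        Temporal standard deviation of the Gaussian.
    d_ms:
        Constant synaptic/dendritic delay between spike and uLFP peak.
    va_mm_per_s:
        Axonal propagation speed (adds ``distance / va`` to the peak time).
    """

    depths_um: np.ndarray
    A0_uV: np.ndarray
    lambda_um: float = 200.0
    sigma_ms: float = 3.15
    d_ms: float = 10.4
    va_mm_per_s: float = 200.0

    def __post_init__(self):
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.A0_uV = np.asarray(self.A0_uV, dtype=float)
        if self.depths_um.shape != self.A0_uV.shape or self.depths_um.ndim != 1:
            raise ValueError("depths_um and A0_uV must be matching 1-D arrays")
        if not np.all(np.diff(self.depths_um) > 0):
            raise ValueError("depths_um must be strictly increasing")
        if self.lambda_um <= 0 or self.sigma_ms <= 0 or self.va_mm_per_s <= 0:
            raise ValueError("lambda_um, sigma_ms and va_mm_per_s must be positive")

    def A0(self, z):
        """Peak amplitude at depth ``z`` (label or micrometers), linearly
        interpolated between tabulated depths and clamped outside the range."""
        z_um = resolve_depth(z)
        lo, hi = self.depths_um[0], self.depths_um[-1]
        if np.any(np.asarray(z_um) < lo) or np.any(np.asarray(z_um) > hi):
            warnings.warn(
                f"depth {z_um} um outside tabulated range [{lo}, {hi}]; clamping",
                stacklevel=2,
            )
        return np.interp(z_um, self.depths_um, self.A0_uV)


def resolve_depth(z) -> float:
    """Map a depth label ('surface', 'soma', ...) or numeric value to um."""
    if isinstance(z, str):
        try:
            return DEPTH_LABELS[z.lower()]
        except KeyError:
            raise ValueError(
                f"unknown depth label {z!r}; use one of {sorted(DEPTH_LABELS)}"
            ) from None
    return float(z)


@dataclass
class ElectrodeSpec:
    """Electrode position: in-plane coordinates (mm) and depth (label or um)."""

    x_mm: float
    y_mm: float
    z: object = "surface"

    @property
    def z_um(self) -> float:
        return resolve_depth(self.z)


@dataclass
class LFPTrace:
    times_ms: np.ndarray
    #: (n_electrodes, n_times) potential in microvolts
    V_uV: np.ndarray
    electrodes: list = field(default_factory=list)

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.V_uV = np.atleast_2d(np.asarray(self.V_uV, dtype=float))
        if self.V_uV.shape[-1] != self.times_ms.size:
            raise ValueError("V_uV and times_ms have inconsistent shapes")
        if not np.all(np.isfinite(self.V_uV)):
            raise ValueError("LFP trace contains non-finite values")


def disk_average_factor() -> float:
    """Closed-form mean of ``exp(-r/lambda)`` over a disk of radius ``2*lambda``.

    ``(2/R^2) * int_0^R r exp(-r/lambda) dr`` with ``R = 2 lambda`` gives
    ``(1 - 3 e^-2) / 2``, independent of lambda (about 0.297).
    """
    return 0.5 * (1.0 - 3.0 * np.exp(-2.0))


def disk_average_factor_quadrature(lambda_um: float = 200.0, n: int = 2000) -> float:
    """Radial quadrature of the disk average, for cross-checking the closed form."""
    R = 2.0 * lambda_um
    r = (np.arange(n) + 0.5) * (R / n)
    w = 2.0 * np.pi * r * (R / n)  # annulus areas
    return float(np.sum(np.exp(-r / lambda_um) * w) / (np.pi * R**2))


def evaluate_kernel(kernel, electrode, source_xy_mm, t0_ms, t_grid_ms):
    """Single-source uLFP time course at one electrode.

    Gaussian of SD ``sigma`` centered at ``t0 + d + distance/va``, with peak
    amplitude ``A0(z) * exp(-distance/lambda)``; the distance is radial, in
    the sheet plane.
    """
    t = np.asarray(t_grid_ms, dtype=float)
    sx, sy = source_xy_mm
    r_mm = np.hypot(electrode.x_mm - sx, electrode.y_mm - sy)
    amp = kernel.A0(electrode.z) * np.exp(-r_mm * 1e3 / kernel.lambda_um)
    t_p = t0_ms + kernel.d_ms + r_mm / kernel.va_mm_per_s * 1e3
    return amp * np.exp(-((t - t_p) ** 2) / (2.0 * kernel.sigma_ms**2))


def population_kernel(kernel: UlfpKernel, z):
    """Disk-averaged kernel for rate-based synthesis.

    Returns ``(amplitude_uV, sigma_ms, d_ms)``: peak amplitude
    ``A0(z) * (1 - 3 e^-2)/2``, peak time ``d`` (axonal propagation dropped).
    """
    return float(kernel.A0(z)) * disk_average_factor(), kernel.sigma_ms, kernel.d_ms


def _gaussian_stencil(sigma_ms: float, dt: float):
    half = int(np.ceil(5.0 * sigma_ms / dt))
    tt = np.arange(-half, half + 1) * dt
    return np.exp(-(tt**2) / (2.0 * sigma_ms**2)), half


def lfp_from_spikes(rec, electrodes, kernel_E, kernel_I, t_grid_ms) -> LFPTrace:
    """Spike-based LFP (superposition of per-spike kernels).

    For every spike, a Gaussian of amplitude ``A0(z) exp(-r/lambda)`` peaking
    at ``t_spike + d + r/va`` is added at each electrode; excitatory and
    inhibitory presynaptic neurons use their respective kernels. Peak times
    are quantized to the output grid step (the grid should resolve sigma).
    Spikes whose kernel support falls outside the grid contribute only the
    overlapping part.
    """
    t = np.asarray(t_grid_ms, dtype=float)
    dt = float(t[1] - t[0])
    electrodes = list(electrodes)
    V = np.zeros((len(electrodes), t.size))
    ids = np.asarray(rec.spike_ids, dtype=np.int64)
    times = np.asarray(rec.spike_times_ms, dtype=float)
    if ids.size == 0:
        return LFPTrace(t, V, electrodes)
    pos = np.asarray(rec.positions_mm, dtype=float)
    is_exc = np.asarray(rec.is_excitatory, dtype=bool)
    for ei, el in enumerate(electrodes):
        r_mm = np.hypot(pos[:, 0] - el.x_mm, pos[:, 1] - el.y_mm)
        for kern, sel in ((kernel_E, is_exc[ids]), (kernel_I, ~is_exc[ids])):
            if not np.any(sel):
                continue
            amp_n = kern.A0(el.z) * np.exp(-r_mm * 1e3 / kern.lambda_um)
            delay_n = kern.d_ms + r_mm / kern.va_mm_per_s * 1e3
            t_peak = times[sel] + delay_n[ids[sel]]
            w = amp_n[ids[sel]]
            # amplitude-weighted histogram of peak times, then one convolution
            stencil, half = _gaussian_stencil(kern.sigma_ms, dt)
            lo, hi = t[0] - half * dt, t[-1] + half * dt
            keep = (t_peak >= lo) & (t_peak <= hi)
            idx = np.round((t_peak[keep] - t[0]) / dt).astype(np.int64) + half
            hist = np.zeros(t.size + 2 * half)
            np.add.at(hist, idx, w[keep])
            V[ei] += np.convolve(hist, stencil, mode="same")[half : half + t.size]
    return LFPTrace(t, V, electrodes)


def lfp_from_rates(
    times_ms,
    nu_e_Hz,
    nu_i_Hz,
    n_e: int,
    n_i: int,
    electrodes,
    kernel_E,
    kernel_I,
) -> LFPTrace:
    """Rate-based LFP: population spike flux convolved with the disk-averaged
    kernel.

    The flux of population ``p`` is ``n_p * nu_p`` (spikes/ms with rates in
    Hz); convolution with the population kernel (amplitude ``~0.3 A0``, peak
    at ``d``) yields microvolts. Zero-padded boundaries; the first ``5 sigma``
    of output is convolution burn-in.
    """
    t = np.asarray(times_ms, dtype=float)
    dt = float(t[1] - t[0])
    nu_e = np.clip(np.asarray(nu_e_Hz, dtype=float), 0.0, None)
    nu_i = np.clip(np.asarray(nu_i_Hz, dtype=float), 0.0, None)
    if nu_e.shape != t.shape or nu_i.shape != t.shape:
        raise ValueError("rate traces must share the time grid")
    electrodes = list(electrodes)
    V = np.zeros((len(electrodes), t.size))
    for ei, el in enumerate(electrodes):
        for kern, nu, n_pop in ((kernel_E, nu_e, n_e), (kernel_I, nu_i, n_i)):
            amp, sigma, d = population_kernel(kern, el.z)
            flux = n_pop * nu * 1e-3  # spikes per ms
            stencil, half = _gaussian_stencil(sigma, dt)
            shift = int(round(d / dt))
            contrib = np.convolve(flux, stencil * amp * dt, mode="full")
            contrib = contrib[half : half + t.size]  # align peak at lag d=0
            out = np.zeros(t.size)
            out[shift:] = contrib[: t.size - shift] if shift > 0 else contrib
            V[ei] += out
    return LFPTrace(t, V, electrodes)


def sheet_average_factor(
    kernel: UlfpKernel, x_mm, y_mm, sheet_extent_mm=(1.0, 1.0), n_grid: int = 40
):
    """Mean of ``exp(-r/lambda)`` over sources uniform on the sheet, per
    evaluation point (the spatial weight of a uniformly distributed
    population seen from arbitrary in-plane positions)."""
    wx, wy = sheet_extent_mm
    sx = (np.arange(n_grid) + 0.5) * wx / n_grid
    sy = (np.arange(n_grid) + 0.5) * wy / n_grid
    SX, SY = np.meshgrid(sx, sy, indexing="ij")
    x = np.atleast_1d(np.asarray(x_mm, dtype=float))
    y = np.atleast_1d(np.asarray(y_mm, dtype=float))
    r = np.hypot(
        x[:, None] - SX.ravel()[None, :], y[:, None] - SY.ravel()[None, :]
    )
    return np.mean(np.exp(-r * 1e3 / kernel.lambda_um), axis=1)


def rate_lfp_field(
    times_ms,
    nu_e_Hz,
    nu_i_Hz,
    n_e: int,
    n_i: int,
    kernel_E: UlfpKernel,
    kernel_I: UlfpKernel,
    sheet_extent_mm=(1.0, 1.0),
    n_grid: int = 40,
):
    """Spatially resolved rate-based LFP: a callable ``Phi(x, y, z, t_grid)``.

    Separable form ``Phi = A0_E(z) f_E(x,y) S_E(t) + A0_I(z) f_I(x,y) S_I(t)``
    with ``f`` the sheet-averaged radial decay and ``S`` the population spike
    flux convolved with the unit-amplitude temporal Gaussian (peak delay d).
    Used as the potential over conductor interfaces for the secondary-current
    dipole.
    """
    t = np.asarray(times_ms, dtype=float)
    dt = float(t[1] - t[0])
    S = {}
    for key, kern, nu, n_pop in (
        ("e", kernel_E, np.asarray(nu_e_Hz, float), n_e),
        ("i", kernel_I, np.asarray(nu_i_Hz, float), n_i),
    ):
        flux = n_pop * np.clip(nu, 0.0, None) * 1e-3
        stencil, half = _gaussian_stencil(kern.sigma_ms, dt)
        shift = int(round(kern.d_ms / dt))
        conv = np.convolve(flux, stencil * dt, mode="full")[half : half + t.size]
        out = np.zeros(t.size)
        out[shift:] = conv[: t.size - shift] if shift > 0 else conv
        S[key] = out

    def field(x_mm, y_mm, z_um, t_grid_ms):
        tq = np.asarray(t_grid_ms, dtype=float)
        if tq.size != t.size or not np.allclose(tq, t):
            raise ValueError("field evaluated on a different time grid")
        fE = sheet_average_factor(kernel_E, x_mm, y_mm, sheet_extent_mm, n_grid)
        fI = sheet_average_factor(kernel_I, x_mm, y_mm, sheet_extent_mm, n_grid)
        return (
            kernel_E.A0(z_um) * fE[:, None] * S["e"][None, :]
            + kernel_I.A0(z_um) * fI[:, None] * S["i"][None, :]
        )

    return field


def load_kernels(path) -> dict:
    """Load per-cell-type uLFP kernels from a YAML parameter file.

    Returns a dict with keys ``'excitatory'`` and ``'inhibitory'``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for key in ("excitatory", "inhibitory"):
        blk = raw[key]
        table = blk["A0_uV"]
        depths = np.array([resolve_depth(k) for k in table])
        order = np.argsort(depths)
        amps = np.array([list(table.values())[i] for i in order], dtype=float)
        out[key] = UlfpKernel(
            depths_um=depths[order],
            A0_uV=amps,
            lambda_um=float(blk["lambda_um"]),
            sigma_ms=float(blk["sigma_ms"]),
            d_ms=float(blk["d_ms"]),
            va_mm_per_s=float(blk["va_mm_per_s"]),
        )
    return out
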