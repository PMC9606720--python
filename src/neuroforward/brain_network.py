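"""Networks of mean-field nodes coupled through a weighted, delayed connectome.

Each region is one AdEx mean-field unit; long-range connections are
excitatory only and enter the excitatory input ``nu_e_bar`` of the target
region as ``g * sum_j w_ij * nu_e_j(t - delay_ij)``, with delays given by
tract length over conduction speed. A synthetic connectome generator stands
in for empirical tractography; its defaults mirror a 68-region parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adex_meanfield import (
    MeanFieldParams,
    MeanFieldTrace,
    OrnsteinUhlenbeckDrive,
    subthreshold_moments,
    transfer_function,
)
from .dipole_forward import (
    DipoleParams,
    HybridCompartmentParams,
    SensorSpec,
    diagonal_gain_matrix,
    mean_axial_current,
    stationary_compartment_voltages,
    synaptic_dipole,
)
from .ulfp_kernel import ElectrodeSpec, lfp_from_rates

__all__ = [
    "Connectome",
    "RegionTraceSet",
    "generate_synthetic_connectome",
    "simulate_network_of_meanfields",
    "forward_per_region",
]


@dataclass
class Connectome:
    weights: np.ndarray  # (n, n), row = target, column = source, >= 0
    lengths_mm: np.ndarray  # (n, n) tract lengths
    speed_mm_per_ms: float = 10.0
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n) or self.lengths_mm.shape != (n, n):
            raise ValueError("weight and length matrices must be square and matching")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-coupling must be zero")
        if self.speed_mm_per_ms <= 0:
            raise ValueError("conduction speed must be positive")
        if not self.labels:
            self.labels = [f"region_{k}" for k in range(n)]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def delays_ms(self) -> np.ndarray:
        return self.lengths_mm / self.speed_mm_per_ms


@dataclass
class RegionTraceSet:
    times_ms: np.ndarray
    nu_e_Hz: np.ndarray  # (n_regions, n_t)
    nu_i_Hz: np.ndarray
    W_pA: np.ndarray
    lfp_uV: np.ndarray | None = None
    B_fT: np.ndarray | None = None

    def region_trace(self, k: int) -> MeanFieldTrace:
        return MeanFieldTrace(
            self.times_ms, self.nu_e_Hz[k], self.nu_i_Hz[k], self.W_pA[k]
        )


def generate_synthetic_connectome(
    n_regions: int = 68,
    density: float = 0.3,
    weight_scale: float = 1.0,
    length_range_mm: tuple = (10.0, 150.0),
    speed_mm_per_ms: float = 10.0,
    seed: int = 0,
) -> Connectome:
    """Random sparse connectome: Bernoulli(density) edges with log-normal
    weight magnitudes and uniform tract lengths. Deterministic per seed."""
    if n_regions < 2:
        raise ValueError("need at least two regions")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_regions, n_regions)) < density
    np.fill_diagonal(mask, False)
    weights = np.where(mask, rng.lognormal(0.0, 0.5, (n_regions, n_regions)), 0.0)
    weights *= weight_scale
    lengths = rng.uniform(*length_range_mm, (n_regions, n_regions))
    lengths = np.where(mask, lengths, 0.0)
    return Connectome(weights, lengths, speed_mm_per_ms)


def simulate_network_of_meanfields(
    connectome: Connectome,
    params: MeanFieldParams,
    g: float = 0.1,
    duration_ms: float = 5000.0,
    dt_ms: float = 0.1,
    drive: OrnsteinUhlenbeckDrive | None = None,
    seed: int = 0,
    init=(1.0, 1.0, 0.0),
) -> RegionTraceSet:
    """Coupled Euler(-Maruyama) integration of all regions.

    Per-region noise streams are independent; with ``g = 0`` each region
    reproduces the single-node simulator exactly (same seed convention:
    region k uses ``seed + k``).
    """
    drive = drive or OrnsteinUhlenbeckDrive()
    n = connectome.n_regions
    delays = connectome.delays_ms()
    coupled = connectome.weights > 0
    if np.any(coupled & (delays > 0) & (delays < dt_ms)):
        raise ValueError(
            "some delays are shorter than dt; reduce dt so the ring buffer "
            "resolves the smallest delay"
        )
    delay_steps = np.round(delays / dt_ms).astype(np.int64)
    max_delay = int(delay_steps.max()) if n else 0
    n_steps = int(round(duration_ms / dt_ms))
    rngs = [np.random.default_rng(seed + k) for k in range(n)]

    nu_e = np.full(n, float(init[0]))
    nu_i = np.full(n, float(init[1]))
    W = np.full(n, float(init[2]))
    xi = np.zeros(n)
    history = np.zeros((max_delay + 1, n))  # ring buffer of nu_e
    history[:] = nu_e
    K_ext = drive.K_ext if drive.K_ext is not None else params.K_e
    scale_ext = K_ext / params.K_e
    sq = np.sqrt(2.0 * dt_ms / drive.tau_ms) if drive.sigma_hz > 0 else 0.0
    tau_w = params.neuron_e.tau_w_ms
    b_e, a_e = params.neuron_e.b_pA, params.neuron_e.a_nS

    ne_tr = np.empty((n, n_steps))
    ni_tr = np.empty((n, n_steps))
    w_tr = np.empty((n, n_steps))
    rows = np.arange(n)
    for k in range(n_steps):
        ptr = k % (max_delay + 1)
        # delayed afferent excitatory rates
        src_ptr = (k - delay_steps) % (max_delay + 1)
        delayed = history[src_ptr, np.broadcast_to(rows, (n, n))]
        long_range = g * np.sum(connectome.weights * delayed, axis=1)
        if drive.sigma_hz > 0:
            noise = np.array([r.standard_normal() for r in rngs])
            xi += -xi * dt_ms / drive.tau_ms + drive.sigma_hz * sq * noise
        ext = np.maximum(drive.rate_hz + xi, 0.0) * scale_ext
        nu_e_bar = nu_e + ext + long_range
        nu_e_bar_i = nu_e + ext * drive.i_fraction + long_range
        Fe = transfer_function(
            nu_e_bar, nu_i, W, params.coeffs_e, params.neuron_e, params.syn,
            params.K_e, params.K_i,
        )
        Fi = transfer_function(
            nu_e_bar_i, nu_i, np.zeros(n), params.coeffs_i, params.neuron_i,
            params.syn, params.K_e, params.K_i,
        )
        mu_V, _, _ = subthreshold_moments(
            nu_e_bar, nu_i, W, params.neuron_e, params.syn, params.K_e, params.K_i
        )
        nu_e = np.maximum(nu_e + dt_ms / params.T_ms * (Fe - nu_e), 0.0)
        nu_i = np.maximum(nu_i + dt_ms / params.T_ms * (Fi - nu_i), 0.0)
        W = W + dt_ms * (
            -W / tau_w + b_e * nu_e * 1e-3 + a_e * (mu_V - params.neuron_e.E_L_mV) / tau_w
        )
        history[ptr] = nu_e
        ne_tr[:, k], ni_tr[:, k], w_tr[:, k] = nu_e, nu_i, W
    times = (np.arange(n_steps) + 1) * dt_ms
    return RegionTraceSet(times, ne_tr, ni_tr, w_tr)


def forward_per_region(
    traces: RegionTraceSet,
    kernel_E,
    kernel_I,
    hp: HybridCompartmentParams,
    dp: DipoleParams,
    n_e: int,
    n_i: int,
    electrode: ElectrodeSpec | None = None,
    sensor_distance_mm: float = 30.0,
    downsample: int = 1,
) -> RegionTraceSet:
    """Per-region LFP (rate-based kernel) and MEG (axial-current dipole
    through the diagonal gain matrix, homogeneous medium)."""
    t = traces.times_ms[::downsample]
    el = electrode or ElectrodeSpec(0.5, 0.5, "surface")
    n_regions = traces.nu_e_Hz.shape[0]
    lfp = np.empty((n_regions, t.size))
    Q = np.empty((n_regions, t.size))
    for k in range(n_regions):
        lfp[k] = lfp_from_rates(
            t,
            traces.nu_e_Hz[k, ::downsample],
            traces.nu_i_Hz[k, ::downsample],
            n_e,
            n_i,
            [el],
            kernel_E,
            kernel_I,
        ).V_uV[0]
        mu1, mu2 = stationary_compartment_voltages(
            traces.nu_e_Hz[k, ::downsample], traces.nu_i_Hz[k, ::downsample],
            traces.W_pA[k, ::downsample], hp,
        )
        I_A = mean_axial_current(mu1, mu2, hp.R_A_MOhm)
        Q[k] = np.linalg.norm(synaptic_dipole(I_A, dp), axis=1) * np.sign(I_A)
    G = diagonal_gain_matrix(n_regions, sensor_distance_mm)
    B = (Q.T @ G.T).T
    return RegionTraceSet(
        t,
        traces.nu_e_Hz[:, ::downsample],
        traces.nu_i_Hz[:, ::downsample],
        traces.W_pA[:, ::downsample],
        lfp_uV=lfp,
        B_fT=B,
    )
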