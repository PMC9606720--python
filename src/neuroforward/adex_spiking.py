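"""Spiking networks of adaptive exponential integrate-and-fire (AdEx) neurons.

Two network variants are implemented:

* a point-neuron network (80% excitatory / 20% inhibitory by default,
  Erdos-Renyi connectivity) with conductance-based exponential synapses and
  spike-triggered adaptation on the excitatory cells, which produces
  slow-wave (up/down state) activity under weak external Poisson drive; and
* a two-compartment variant in which each excitatory cell has a spiking
  soma plus a passive apical dendrite coupled by an axial conductance
  ``g_A``; the population-mean axial current ``I_A = g_A (V_D - V_S)`` is the
  primary current source for the MEG forward model.

Integration is forward Euler at ``dt <= 0.1 ms``; the exponential spike-
initiation term is clipped at the spike-detection voltage to avoid overflow,
and a spike is registered when the membrane crosses that detection voltage
(the exponential upstroke makes the crossing time insensitive to the exact
cut, shifts well below 1 ms). The stiff dendritic compartment (time constant
``C_D / (g_LD + g_A) ~ 25 us`` with the default parameters) is advanced with
an exact exponential update of its linear ODE instead of Euler.

Units: pF, nS, mV, pA, ms; positions in mm; rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

__all__ = [
    "AdExNeuronParams",
    "SynapseParams",
    "NetworkSpec",
    "TwoCompartmentParams",
    "ExternalDrive",
    "ConnectivityRealization",
    "SpikeRecord",
    "RateTrace",
    "AxialCurrentTrace",
    "build_network",
    "simulate_point_network",
    "simulate_two_compartment_network",
    "population_rates",
]


@dataclass
class AdExNeuronParams:
    C_pF: float = 200.0
    g_L_nS: float = 10.0
    E_L_mV: float = -63.0
    V_T_mV: float = -50.0  # slope point of the exponential term
    Delta_T_mV: float = 2.0
    a_nS: float = 0.0
    b_pA: float = 0.0
    tau_w_ms: float = 500.0
    V_reset_mV: float = -65.0
    V_spike_cut_mV: float = 0.0  # numerical spike-detection ceiling
    t_ref_ms: float = 5.0

    def __post_init__(self):
        if self.C_pF <= 0 or self.g_L_nS <= 0:
            raise ValueError("C and g_L must be positive")
        if self.Delta_T_mV <= 0 or self.tau_w_ms <= 0:
            raise ValueError("Delta_T and tau_w must be positive")
        if self.t_ref_ms < 0:
            raise ValueError("t_ref must be non-negative")
        if self.V_reset_mV >= self.V_spike_cut_mV:
            raise ValueError("V_reset must lie below the spike-detection cut")


@dataclass
class SynapseParams:
    q_e_nS: float = 1.5
    q_i_nS: float = 5.0
    tau_e_ms: float = 5.0
    tau_i_ms: float = 5.0
    E_e_mV: float = 0.0
    E_i_mV: float = -80.0

    def __post_init__(self):
        if self.q_e_nS < 0 or self.q_i_nS < 0:
            raise ValueError("quantal conductances must be non-negative")
        if self.tau_e_ms <= 0 or self.tau_i_ms <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.E_i_mV >= self.E_e_mV:
            raise ValueError("E_i must lie below E_e")


@dataclass
class NetworkSpec:
    n_total: int = 10000
    frac_excitatory: float = 0.8
    p_connect: float = 0.05
    sheet_extent_mm: tuple = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.frac_excitatory < 1.0:
            raise ValueError("frac_excitatory must be in (0, 1)")
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("p_connect must be in [0, 1]")
        if self.n_total < 2:
            raise ValueError("need at least two neurons")

    @property
    def n_excitatory(self) -> int:
        return int(np.ceil(self.n_total * self.frac_excitatory))

    @property
    def n_inhibitory(self) -> int:
        return self.n_total - self.n_excitatory


@dataclass
class TwoCompartmentParams:
    """Excitatory soma+dendrite cell; the soma carries the AdEx spiking and
    adaptation machinery, the dendrite is passive.

    Spike detection/reset uses its own thresholds (``V_detect``, ``V_reset``),
    distinct from the exponential slope point ``V_T``. ``p_e1/p_e2`` and
    ``p_i1/p_i2`` are the fractions of excitatory/inhibitory synapses placed
    on the soma (1) versus the dendrite (2).
    """

    C_S_pF: float = 200.0
    C_D_pF: float = 10.0
    g_LS_nS: float = 10.0
    g_LD_nS: float = 2.0
    g_A_nS: float = 400.0
    E_L_mV: float = -63.0
    V_T_mV: float = -50.0
    Delta_T_mV: float = 2.0
    a_nS: float = 0.0
    b_pA: float = 60.0
    tau_w_ms: float = 500.0
    V_detect_mV: float = -40.0
    V_reset_mV: float = -55.0
    t_ref_ms: float = 5.0
    p_e1: float = 0.3
    p_e2: float = 0.7
    p_i1: float = 0.6
    p_i2: float = 0.4

    def __post_init__(self):
        if self.g_A_nS < 0:
            raise ValueError("g_A must be non-negative")
        if not np.isclose(self.p_e1 + self.p_e2, 1.0):
            raise ValueError("p_e1 + p_e2 must equal 1")
        if not np.isclose(self.p_i1 + self.p_i2, 1.0):
            raise ValueError("p_i1 + p_i2 must equal 1")

    def soma_point_params(self) -> AdExNeuronParams:
        return AdExNeuronParams(
            C_pF=self.C_S_pF,
            g_L_nS=self.g_LS_nS,
            E_L_mV=self.E_L_mV,
            V_T_mV=self.V_T_mV,
            Delta_T_mV=self.Delta_T_mV,
            a_nS=self.a_nS,
            b_pA=self.b_pA,
            tau_w_ms=self.tau_w_ms,
            V_reset_mV=self.V_reset_mV,
            V_spike_cut_mV=self.V_detect_mV,
            t_ref_ms=self.t_ref_ms,
        )


@dataclass
class ExternalDrive:
    """Independent external excitatory Poisson input to every neuron.

    Each neuron receives ``n_ext`` afferents firing at ``rate_hz`` (the total
    rate ``n_ext * rate_hz`` is what matters), acting through the same
    quantal ``q_e`` synapses as recurrent input. ``rate_hz`` may be an array
    (per neuron). Optional per-neuron inhibitory Poisson input and constant
    injected current support single-neuron characterization runs.
    """

    rate_hz: object = 2.0
    n_ext: int = 400
    inh_rate_hz: object = 0.0
    inh_n_ext: int = 1
    I_const_pA: object = 0.0
    #: relative SD of a global Ornstein-Uhlenbeck modulation of the drive
    #: rate (shared by all neurons; 0 disables it)
    ou_sigma_rel: float = 0.0
    ou_tau_ms: float = 300.0

    def exc_rate_per_ms(self, n: int) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.rate_hz, dtype=float) * self.n_ext * 1e-3, (n,)
        ).copy()

    def inh_rate_per_ms(self, n: int) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.inh_rate_hz, dtype=float) * self.inh_n_ext * 1e-3, (n,)
        ).copy()


@dataclass
class ConnectivityRealization:
    spec: NetworkSpec
    adjacency: sparse.csr_matrix  # row = presynaptic neuron -> target columns
    positions_mm: np.ndarray  # (n, 2)
    is_excitatory: np.ndarray  # (n,) bool; first ceil(n*frac) neurons are E

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class SpikeRecord:
    """Spike times, neuron positions and E/I labels for one simulation."""

    n_neurons: int
    spike_ids: np.ndarray
    spike_times_ms: np.ndarray
    positions_mm: np.ndarray
    is_excitatory: np.ndarray
    duration_ms: float = 0.0

    def spike_trains(self) -> list:
        """Per-neuron ordered spike-time arrays."""
        trains = [[] for _ in range(self.n_neurons)]
        for i, t in zip(self.spike_ids, self.spike_times_ms):
            trains[i].append(t)
        return [np.asarray(tr) for tr in trains]

    def min_isi_ms(self) -> float:
        """Smallest inter-spike interval over all neurons (inf if none)."""
        best = np.inf
        order = np.lexsort((self.spike_times_ms, self.spike_ids))
        ids = self.spike_ids[order]
        ts = self.spike_times_ms[order]
        same = ids[1:] == ids[:-1]
        if np.any(same):
            best = float(np.min(np.diff(ts)[same]))
        return best


@dataclass
class RateTrace:
    times_ms: np.ndarray
    nu_e_Hz: np.ndarray
    nu_i_Hz: np.ndarray


@dataclass
class AxialCurrentTrace:
    times_ms: np.ndarray
    mean_I_A_pA: np.ndarray
    per_neuron_pA: np.ndarray | None = None


def build_network(spec: NetworkSpec, seed: int | None = None) -> ConnectivityRealization:
    """Erdos-Renyi directed connectivity (independent Bernoulli per ordered
    pair, no self-connections), uniform positions on the sheet, E labels on
    the first ``ceil(n * frac_excitatory)`` neurons."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_total
    indptr = [0]
    indices = []
    block = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        mask = rng.random((stop - start, n)) < spec.p_connect
        mask[np.arange(stop - start), np.arange(start, stop)] = False
        for row in mask:
            tgt = np.nonzero(row)[0]
            indices.append(tgt)
            indptr.append(indptr[-1] + tgt.size)
    indices = (
        np.concatenate(indices).astype(np.int32) if indices else np.empty(0, np.int32)
    )
    adjacency = sparse.csr_matrix(
        (np.ones(indices.size, dtype=np.int8), indices, np.array(indptr)),
        shape=(n, n),
    )
    positions = rng.random((n, 2)) * np.asarray(spec.sheet_extent_mm)
    is_exc = np.zeros(n, dtype=bool)
    is_exc[: spec.n_excitatory] = True
    return ConnectivityRealization(spec, adjacency, positions, is_exc)


def _check_dt(dt_ms: float):
    if not 0.0 < dt_ms <= 0.1:
        raise ValueError("dt must be positive and at most 0.1 ms")


def _param_arrays(conn, params_e, params_i, fields):
    is_exc = conn.is_excitatory
    out = []
    for f in fields:
        arr = np.where(is_exc, getattr(params_e, f), getattr(params_i, f))
        out.append(arr.astype(float))
    return out


def simulate_point_network(
    conn: ConnectivityRealization,
    params_e: AdExNeuronParams,
    params_i: AdExNeuronParams,
    syn: SynapseParams,
    drive: ExternalDrive,
    duration_ms: float,
    dt_ms: float = 0.1,
    seed: int = 0,
    record_states: int = 0,
    synaptic_delay_ms: float = 0.0,
):
    """Forward-Euler simulation of the point AdEx network.

    ``synaptic_delay_ms`` is a uniform conduction/synaptic latency applied to
    recurrent (not external) spikes. Returns ``(SpikeRecord, states)`` where
    ``states`` is a dict of state traces for the first ``record_states``
    neurons (empty dict otherwise). Raises ``FloatingPointError`` if the
    state diverges.
    """
    _check_dt(dt_ms)
    rng = np.random.default_rng(seed)
    n = conn.n
    is_exc = conn.is_excitatory
    C, gL, EL, VT, DT, a, b, tauw, Vr, Vcut, tref = _param_arrays(
        conn,
        params_e,
        params_i,
        [
            "C_pF",
            "g_L_nS",
            "E_L_mV",
            "V_T_mV",
            "Delta_T_mV",
            "a_nS",
            "b_pA",
            "tau_w_ms",
            "V_reset_mV",
            "V_spike_cut_mV",
            "t_ref_ms",
        ],
    )
    V = EL.copy()
    w = np.zeros(n)
    Ge = np.zeros(n)
    Gi = np.zeros(n)
    ref_until = np.full(n, -np.inf)
    lam_e = drive.exc_rate_per_ms(n) * dt_ms
    lam_i = drive.inh_rate_per_ms(n) * dt_ms
    I0 = np.broadcast_to(np.asarray(drive.I_const_pA, dtype=float), (n,))
    decay_e = np.exp(-dt_ms / syn.tau_e_ms)
    decay_i = np.exp(-dt_ms / syn.tau_i_ms)
    arg_max = (Vcut - VT) / DT
    indptr, indices = conn.adjacency.indptr, conn.adjacency.indices
    any_edges = indices.size > 0
    has_inh_drive = np.any(lam_i > 0)
    delay_steps = int(round(synaptic_delay_ms / dt_ms))
    queue_Ge = np.zeros((delay_steps + 1, n))
    queue_Gi = np.zeros((delay_steps + 1, n))
    ou = 0.0
    ou_sq = np.sqrt(2.0 * dt_ms / drive.ou_tau_ms)

    spike_ids, spike_times = [], []
    n_steps = int(round(duration_ms / dt_ms))
    rec = {k: [] for k in ("t", "V", "w", "Ge", "Gi")} if record_states else {}
    for step in range(n_steps):
        t = step * dt_ms
        ptr = step % (delay_steps + 1)
        if delay_steps:
            Ge += queue_Ge[ptr]
            Gi += queue_Gi[ptr]
            queue_Ge[ptr] = 0.0
            queue_Gi[ptr] = 0.0
        if drive.ou_sigma_rel > 0:
            ou += (-ou * dt_ms / drive.ou_tau_ms
                   + drive.ou_sigma_rel * ou_sq * rng.standard_normal())
            mod = max(1.0 + ou, 0.0)
        else:
            mod = 1.0
        if np.any(lam_e > 0):
            Ge += syn.q_e_nS * rng.poisson(lam_e * mod)
        if has_inh_drive:
            Gi += syn.q_i_nS * rng.poisson(lam_i * mod)
        Iexp = gL * DT * np.exp(np.minimum((V - VT) / DT, arg_max))
        Isyn = Ge * (syn.E_e_mV - V) + Gi * (syn.E_i_mV - V)
        dV = (gL * (EL - V) + Iexp - w + Isyn + I0) * (dt_ms / C)
        refractory = t < ref_until
        V = np.where(refractory, Vr, V + dV)
        w += dt_ms * (a * (V - EL) - w) / tauw
        spiking = (V >= Vcut) & ~refractory
        if np.any(spiking):
            ids = np.nonzero(spiking)[0]
            spike_ids.append(ids)
            spike_times.append(np.full(ids.size, t + dt_ms))
            V[ids] = Vr[ids]
            ref_until[ids] = t + dt_ms + tref[ids]
            w[ids] += b[ids]
            if any_edges:
                dst = (step + delay_steps) % (delay_steps + 1)
                tgt_Ge = queue_Ge[dst] if delay_steps else Ge
                tgt_Gi = queue_Gi[dst] if delay_steps else Gi
                for j in ids:
                    tgt = indices[indptr[j] : indptr[j + 1]]
                    if is_exc[j]:
                        tgt_Ge[tgt] += syn.q_e_nS
                    else:
                        tgt_Gi[tgt] += syn.q_i_nS
        Ge *= decay_e
        Gi *= decay_i
        if record_states:
            rec["t"].append(t + dt_ms)
            rec["V"].append(V[:record_states].copy())
            rec["w"].append(w[:record_states].copy())
            rec["Ge"].append(Ge[:record_states].copy())
            rec["Gi"].append(Gi[:record_states].copy())
        if step % 1000 == 0 and not np.all(np.isfinite(V)):
            raise FloatingPointError(
                f"membrane potential diverged at t={t:.1f} ms; "
                "reduce dt or check parameters"
            )
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("membrane potential diverged; reduce dt")
    record = SpikeRecord(
        n_neurons=n,
        spike_ids=(
            np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=np.int64)
        ),
        spike_times_ms=(
            np.concatenate(spike_times) if spike_times else np.empty(0)
        ),
        positions_mm=conn.positions_mm,
        is_excitatory=is_exc,
        duration_ms=duration_ms,
    )
    states = {k: np.asarray(v) for k, v in rec.items()} if record_states else {}
    return record, states


def _split_edges_by_compartment(conn, tc: TwoCompartmentParams, rng):
    """Assign each synapse onto an excitatory target to soma or dendrite.

    Presynaptic-excitatory edges land on the soma with probability ``p_e1``
    (dendrite otherwise); inhibitory edges with ``p_i1``. Equivalent to
    per-compartment connection probabilities ``p_e1*p_o`` etc.
    """
    A = conn.adjacency
    is_exc = conn.is_excitatory
    pre = np.repeat(np.arange(conn.n), np.diff(A.indptr))
    p1 = np.where(is_exc[pre], tc.p_e1, tc.p_i1)
    return rng.random(A.indices.size) < p1  # True -> soma


def simulate_two_compartment_network(
    conn: ConnectivityRealization,
    tc: TwoCompartmentParams,
    params_i: AdExNeuronParams,
    syn: SynapseParams,
    drive: ExternalDrive,
    duration_ms: float,
    dt_ms: float = 0.1,
    seed: int = 0,
    record_per_neuron: bool = False,
    axial_subsample: int = 1,
    synaptic_delay_ms: float = 0.0,
):
    """Two-compartment excitatory cells + point inhibitory cells.

    The soma integrates the AdEx equation (Euler) with the axial current
    ``I_A = g_A (V_D - V_S)`` as extra input; the passive dendrite is advanced
    with an exact exponential update (it is stiff: ``C_D/(g_LD+g_A)`` is tens
    of microseconds). External excitatory drive is split across compartments
    with the same ``p_e1/p_e2`` fractions as recurrent synapses.

    Returns ``(SpikeRecord, AxialCurrentTrace)`` with the population-mean
    soma-ward axial current over excitatory cells recorded every
    ``axial_subsample`` steps.
    """
    _check_dt(dt_ms)
    rng = np.random.default_rng(seed)
    n = conn.n
    is_exc = conn.is_excitatory
    exc_idx = np.nonzero(is_exc)[0]
    inh_idx = np.nonzero(~is_exc)[0]
    n_e, n_i = exc_idx.size, inh_idx.size
    # map global id -> compartmental slot
    slot = np.empty(n, dtype=np.int64)
    slot[exc_idx] = np.arange(n_e)
    slot[inh_idx] = np.arange(n_i)

    on_soma = _split_edges_by_compartment(conn, tc, rng)
    indptr, indices = conn.adjacency.indptr, conn.adjacency.indices

    # excitatory (two-compartment) state
    VS = np.full(n_e, tc.E_L_mV)
    VD = np.full(n_e, tc.E_L_mV)
    wE = np.zeros(n_e)
    GeS = np.zeros(n_e)
    GiS = np.zeros(n_e)
    GeD = np.zeros(n_e)
    GiD = np.zeros(n_e)
    ref_until_E = np.full(n_e, -np.inf)
    # inhibitory point state
    Vi = np.full(n_i, params_i.E_L_mV)
    Gei = np.zeros(n_i)
    Gii = np.zeros(n_i)
    ref_until_I = np.full(n_i, -np.inf)

    lam_e = drive.exc_rate_per_ms(n) * dt_ms
    lam_E_soma = lam_e[exc_idx] * tc.p_e1
    lam_E_dend = lam_e[exc_idx] * tc.p_e2
    lam_I = lam_e[inh_idx]
    I0_all = np.broadcast_to(np.asarray(drive.I_const_pA, dtype=float), (n,))
    I0_E = I0_all[exc_idx]
    I0_I = I0_all[inh_idx]
    decay_e = np.exp(-dt_ms / syn.tau_e_ms)
    decay_i = np.exp(-dt_ms / syn.tau_i_ms)
    argmax_E = (tc.V_detect_mV - tc.V_T_mV) / tc.Delta_T_mV
    argmax_I = (params_i.V_spike_cut_mV - params_i.V_T_mV) / params_i.Delta_T_mV

    delay_steps = int(round(synaptic_delay_ms / dt_ms))
    queues = {
        name: np.zeros((delay_steps + 1, size))
        for name, size in (
            ("GeS", n_e), ("GeD", n_e), ("GiS", n_e), ("GiD", n_e),
            ("Gei", n_i), ("Gii", n_i),
        )
    }
    conduct = {"GeS": GeS, "GeD": GeD, "GiS": GiS, "GiD": GiD,
               "Gei": Gei, "Gii": Gii}
    ou = 0.0
    ou_sq = np.sqrt(2.0 * dt_ms / drive.ou_tau_ms)

    spike_ids, spike_times = [], []
    axial_t, axial_mean = [], []
    axial_all = [] if record_per_neuron else None
    n_steps = int(round(duration_ms / dt_ms))
    for step in range(n_steps):
        t = step * dt_ms
        if delay_steps:
            ptr = step % (delay_steps + 1)
            for name, G in conduct.items():
                G += queues[name][ptr]
                queues[name][ptr] = 0.0
        if drive.ou_sigma_rel > 0:
            ou += (-ou * dt_ms / drive.ou_tau_ms
                   + drive.ou_sigma_rel * ou_sq * rng.standard_normal())
            mod = max(1.0 + ou, 0.0)
        else:
            mod = 1.0
        GeS += syn.q_e_nS * rng.poisson(lam_E_soma * mod)
        GeD += syn.q_e_nS * rng.poisson(lam_E_dend * mod)
        Gei += syn.q_e_nS * rng.poisson(lam_I * mod)

        I_A = tc.g_A_nS * (VD - VS)
        # soma (Euler)
        Iexp = (
            tc.g_LS_nS
            * tc.Delta_T_mV
            * np.exp(np.minimum((VS - tc.V_T_mV) / tc.Delta_T_mV, argmax_E))
        )
        IsynS = GeS * (syn.E_e_mV - VS) + GiS * (syn.E_i_mV - VS)
        dVS = (
            tc.g_LS_nS * (tc.E_L_mV - VS) + Iexp - wE + I_A + IsynS + I0_E
        ) * (dt_ms / tc.C_S_pF)
        refE = t < ref_until_E
        VS_new = np.where(refE, tc.V_reset_mV, VS + dVS)
        # dendrite (exact exponential update, frozen conductances and V_S)
        Gtot = tc.g_LD_nS + tc.g_A_nS + GeD + GiD
        Vinf = (
            tc.g_LD_nS * tc.E_L_mV
            + tc.g_A_nS * VS
            + GeD * syn.E_e_mV
            + GiD * syn.E_i_mV
        ) / Gtot
        VD = Vinf + (VD - Vinf) * np.exp(-dt_ms * Gtot / tc.C_D_pF)
        VS = VS_new
        wE += dt_ms * (tc.a_nS * (VS - tc.E_L_mV) - wE) / tc.tau_w_ms
        # inhibitory point cells (Euler)
        IexpI = (
            params_i.g_L_nS
            * params_i.Delta_T_mV
            * np.exp(np.minimum((Vi - params_i.V_T_mV) / params_i.Delta_T_mV, argmax_I))
        )
        IsynI = Gei * (syn.E_e_mV - Vi) + Gii * (syn.E_i_mV - Vi)
        refI = t < ref_until_I
        Vi = np.where(
            refI,
            params_i.V_reset_mV,
            Vi + (params_i.g_L_nS * (params_i.E_L_mV - Vi) + IexpI + IsynI + I0_I)
            * (dt_ms / params_i.C_pF),
        )

        spikE = (VS >= tc.V_detect_mV) & ~refE
        spikI = (Vi >= params_i.V_spike_cut_mV) & ~refI
        fired = []
        if np.any(spikE):
            e_ids = exc_idx[np.nonzero(spikE)[0]]
            VS[spikE] = tc.V_reset_mV
            ref_until_E[spikE] = t + dt_ms + tc.t_ref_ms
            wE[spikE] += tc.b_pA
            fired.append(e_ids)
        if np.any(spikI):
            i_ids = inh_idx[np.nonzero(spikI)[0]]
            Vi[spikI] = params_i.V_reset_mV
            ref_until_I[spikI] = t + dt_ms + params_i.t_ref_ms
            fired.append(i_ids)
        if fired:
            ids = np.concatenate(fired)
            spike_ids.append(ids)
            spike_times.append(np.full(ids.size, t + dt_ms))
            if delay_steps:
                dst = (step + delay_steps) % (delay_steps + 1)
                sinks = {name: queues[name][dst] for name in queues}
            else:
                sinks = conduct
            for j in ids:
                tgt = indices[indptr[j] : indptr[j + 1]]
                soma_mask = on_soma[indptr[j] : indptr[j + 1]]
                tgt_exc = is_exc[tgt]
                q = syn.q_e_nS if is_exc[j] else syn.q_i_nS
                te = slot[tgt[tgt_exc & soma_mask]]
                td = slot[tgt[tgt_exc & ~soma_mask]]
                ti = slot[tgt[~tgt_exc]]
                if is_exc[j]:
                    np.add.at(sinks["GeS"], te, q)
                    np.add.at(sinks["GeD"], td, q)
                    np.add.at(sinks["Gei"], ti, q)
                else:
                    np.add.at(sinks["GiS"], te, q)
                    np.add.at(sinks["GiD"], td, q)
                    np.add.at(sinks["Gii"], ti, q)
        GeS *= decay_e
        GeD *= decay_e
        Gei *= decay_e
        GiS *= decay_i
        GiD *= decay_i
        Gii *= decay_i
        if step % axial_subsample == 0:
            ia = tc.g_A_nS * (VD - VS)
            axial_t.append(t + dt_ms)
            axial_mean.append(float(np.mean(ia)))
            if record_per_neuron:
                axial_all.append(ia.copy())
        if step % 1000 == 0 and not (
            np.all(np.isfinite(VS)) and np.all(np.isfinite(VD))
        ):
            raise FloatingPointError(f"state diverged at t={t:.1f} ms")
    record = SpikeRecord(
        n_neurons=n,
        spike_ids=(
            np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=np.int64)
        ),
        spike_times_ms=(
            np.concatenate(spike_times) if spike_times else np.empty(0)
        ),
        positions_mm=conn.positions_mm,
        is_excitatory=is_exc,
        duration_ms=duration_ms,
    )
    axial = AxialCurrentTrace(
        times_ms=np.asarray(axial_t),
        mean_I_A_pA=np.asarray(axial_mean),
        per_neuron_pA=np.asarray(axial_all) if record_per_neuron else None,
    )
    return record, axial


def population_rates(
    rec: SpikeRecord,
    bin_ms: float = 1.0,
    smoothing_sigma_ms: float = 0.0,
    duration_ms: float | None = None,
) -> RateTrace:
    """Per-population firing rate: spike counts per bin / (n_pop * bin width),
    in Hz, with optional Gaussian smoothing."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    T = duration_ms if duration_ms is not None else rec.duration_ms
    if T <= 0:
        T = float(rec.spike_times_ms.max()) if rec.spike_times_ms.size else bin_ms
    n_bins = int(np.ceil(T / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_e = int(np.sum(rec.is_excitatory))
    n_i = rec.n_neurons - n_e
    out = []
    for sel, n_pop in (
        (rec.is_excitatory[rec.spike_ids], n_e),
        (~rec.is_excitatory[rec.spike_ids], n_i),
    ):
        counts, _ = np.histogram(rec.spike_times_ms[sel], bins=edges)
        rate = counts / max(n_pop, 1) / (bin_ms * 1e-3)
        if smoothing_sigma_ms > 0:
            rate = ndimage.gaussian_filter1d(rate, smoothing_sigma_ms / bin_ms)
        out.append(rate)
    return RateTrace(times_ms=centers, nu_e_Hz=out[0], nu_i_Hz=out[1])
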