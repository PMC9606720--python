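"""First-order mean-field model of the AdEx network.

The population dynamics follow the Markovian rate description

    T dnu_p/dt = F_p(nu_e_bar, nu_i, W) - nu_p ,       p in {e, i}
    dW/dt      = -W/tau_w + b nu_e + a (mu_V - E_L)/tau_w ,

where ``F_p`` is the population transfer function: the stationary firing rate
of a single AdEx neuron bombarded by Poisson excitatory/inhibitory inputs at
rates ``nu_e_bar`` (recurrent + external drive) and ``nu_i`` under adaptation
current ``W``. ``F`` is the semi-analytic conductance-based form: subthreshold
voltage moments ``(mu_V, sigma_V, tau_V)`` computed from shot-noise theory,
then

    F = 1/(2 tau_V) * erfc( (V_eff - mu_V) / (sqrt(2) sigma_V) ),

with an effective threshold ``V_eff`` expressed as a second-order polynomial
in the normalized moments. The polynomial coefficients are not universal:
``fit_transfer_function`` regenerates them for any neuron/synapse parameter
set from single-neuron Poisson-bombardment simulations.

Units: ms, mV, nS, pF, pA; rates in Hz at the API surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import erfc, erfcinv

from .adex_spiking import (
    AdExNeuronParams,
    ConnectivityRealization,
    ExternalDrive,
    NetworkSpec,
    SynapseParams,
    simulate_point_network,
)
from scipy import sparse

__all__ = [
    "TransferFunctionCoeffs",
    "MeanFieldParams",
    "MeanFieldTrace",
    "OrnsteinUhlenbeckDrive",
    "subthreshold_moments",
    "transfer_function",
    "fit_transfer_function",
    "simulate_meanfield",
    "load_tf_coeffs",
    "save_tf_coeffs",
]

# normalization constants for the effective-threshold polynomial
_MU0, _DMU = -60.0, 10.0  # mV
_SIG0, _DSIG = 4.0, 6.0  # mV
_TAU0, _DTAU = 0.5, 1.0  # dimensionless tau_V g_L / C


@dataclass
class TransferFunctionCoeffs:
    """Second-order polynomial coefficients (mV) of the effective threshold.

    Basis order: 1, x_mu, x_sig, x_tau, x_mu^2, x_sig^2, x_tau^2,
    x_mu x_sig, x_mu x_tau, x_sig x_tau, with x_* the normalized moments.
    """

    P: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (10,):
            raise ValueError("expected 10 polynomial coefficients")
        if not np.all(np.isfinite(self.P)):
            raise ValueError("coefficients must be finite")


@dataclass
class MeanFieldParams:
    neuron_e: AdExNeuronParams
    neuron_i: AdExNeuronParams
    syn: SynapseParams
    coeffs_e: TransferFunctionCoeffs
    coeffs_i: TransferFunctionCoeffs
    n_e: int = 8000
    n_i: int = 2000
    p_connect: float = 0.05
    T_ms: float = 5.0

    def __post_init__(self):
        if self.T_ms <= 0:
            raise ValueError("population response time T must be positive")

    @property
    def K_e(self) -> float:
        return self.n_e * self.p_connect

    @property
    def K_i(self) -> float:
        return self.n_i * self.p_connect


@dataclass
class MeanFieldTrace:
    times_ms: np.ndarray
    nu_e_Hz: np.ndarray
    nu_i_Hz: np.ndarray
    W_pA: np.ndarray


@dataclass
class OrnsteinUhlenbeckDrive:
    """External excitatory drive rate: constant mean plus optional OU noise.

    ``rate_hz`` is the population rate of the external afferent pool as seen
    through ``K_ext`` synapses per neuron (default: same in-degree as the
    recurrent excitatory connectivity).
    """

    rate_hz: float = 0.5
    sigma_hz: float = 0.0
    tau_ms: float = 100.0
    K_ext: float | None = None
    #: fraction of the external drive seen by the inhibitory population
    #: (1 = both populations fully driven, 0 = excitatory-only drive)
    i_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.i_fraction <= 1.0:
            raise ValueError("i_fraction must lie in [0, 1]")


def subthreshold_moments(
    nu_e_total_Hz,
    nu_i_total_Hz,
    W_pA,
    neuron: AdExNeuronParams,
    syn: SynapseParams,
    K_e: float,
    K_i: float,
):
    """Voltage moments (mu_V, sigma_V mV; tau_V ms) under Poisson bombardment.

    ``nu_*_total`` are presynaptic population rates; the per-neuron input
    rates are ``K_e nu_e`` and ``K_i nu_i``. Shot-noise (Campbell) formulas
    for exponential conductance PSPs filtered by the effective membrane time
    ``tau_m = C / mu_G``.
    """
    fe = K_e * np.maximum(np.asarray(nu_e_total_Hz, dtype=float), 0.0) * 1e-3  # /ms
    fi = K_i * np.maximum(np.asarray(nu_i_total_Hz, dtype=float), 0.0) * 1e-3
    W = np.asarray(W_pA, dtype=float)
    mu_Ge = fe * syn.tau_e_ms * syn.q_e_nS
    mu_Gi = fi * syn.tau_i_ms * syn.q_i_nS
    mu_G = neuron.g_L_nS + mu_Ge + mu_Gi
    mu_V = (
        mu_Ge * syn.E_e_mV + mu_Gi * syn.E_i_mV + neuron.g_L_nS * neuron.E_L_mV - W
    ) / mu_G
    tau_m = neuron.C_pF / mu_G
    U_e = syn.q_e_nS / mu_G * (syn.E_e_mV - mu_V)
    U_i = syn.q_i_nS / mu_G * (syn.E_i_mV - mu_V)
    se = fe * (U_e * syn.tau_e_ms) ** 2
    si = fi * (U_i * syn.tau_i_ms) ** 2
    var = se / (2.0 * (tau_m + syn.tau_e_ms)) + si / (2.0 * (tau_m + syn.tau_i_ms))
    sigma_V = np.sqrt(np.maximum(var, 1e-12))
    num = se + si
    den = se / (tau_m + syn.tau_e_ms) + si / (tau_m + syn.tau_i_ms)
    tau_V = np.where(den > 0, num / np.maximum(den, 1e-30), tau_m + syn.tau_e_ms)
    return mu_V, sigma_V, tau_V


def _threshold_basis(mu_V, sigma_V, tau_V, neuron):
    x_mu = (mu_V - _MU0) / _DMU
    x_sig = (sigma_V - _SIG0) / _DSIG
    tau_N = tau_V * neuron.g_L_nS / neuron.C_pF
    x_tau = (tau_N - _TAU0) / _DTAU
    one = np.ones_like(np.asarray(mu_V, dtype=float))
    return np.stack(
        [
            one,
            x_mu,
            x_sig,
            x_tau,
            x_mu**2,
            x_sig**2,
            x_tau**2,
            x_mu * x_sig,
            x_mu * x_tau,
            x_sig * x_tau,
        ],
        axis=-1,
    )


def transfer_function(
    nu_e_total_Hz,
    nu_i_total_Hz,
    W_pA,
    coeffs: TransferFunctionCoeffs,
    neuron: AdExNeuronParams,
    syn: SynapseParams,
    K_e: float,
    K_i: float,
):
    """Population transfer function F (Hz), non-negative by construction."""
    if coeffs is None:
        raise ValueError(
            "transfer-function coefficients missing; fit them with "
            "fit_transfer_function or load a coefficient file"
        )
    mu_V, sigma_V, tau_V = subthreshold_moments(
        nu_e_total_Hz, nu_i_total_Hz, W_pA, neuron, syn, K_e, K_i
    )
    V_eff = _threshold_basis(mu_V, sigma_V, tau_V, neuron) @ coeffs.P
    arg = (V_eff - mu_V) / (np.sqrt(2.0) * sigma_V)
    nu_out = erfc(arg) / (2.0 * tau_V * 1e-3)  # Hz
    return np.maximum(nu_out, 0.0)


def _uncoupled_net(n: int) -> "ConnectivityRealization":
    spec = NetworkSpec(n_total=n + 1, frac_excitatory=n / (n + 1), p_connect=0.0)
    adj = sparse.csr_matrix((n + 1, n + 1), dtype=np.int8)
    pos = np.zeros((n + 1, 2))
    is_exc = np.zeros(n + 1, dtype=bool)
    is_exc[:n] = True
    return ConnectivityRealization(spec, adj, pos, is_exc)


def measure_single_neuron_rates(
    neuron: AdExNeuronParams,
    syn: SynapseParams,
    nu_e_Hz: np.ndarray,
    nu_i_Hz: np.ndarray,
    W_pA: np.ndarray,
    K_e: float,
    K_i: float,
    duration_ms: float = 5000.0,
    discard_ms: float = 500.0,
    dt_ms: float = 0.1,
    seed: int = 0,
):
    """Stationary output rate of independent AdEx neurons under Poisson
    bombardment, one neuron per (nu_e, nu_i, W) combination.

    Adaptation is frozen (a = b = 0) and W enters as a constant hyperpolarizing
    current, matching the quasi-static role of W in the transfer function.
    Returns rates in Hz and their Poisson standard errors.
    """
    nu_e = np.asarray(nu_e_Hz, dtype=float)
    nu_i = np.asarray(nu_i_Hz, dtype=float)
    W = np.asarray(W_pA, dtype=float)
    n = nu_e.size
    conn = _uncoupled_net(n)
    frozen = AdExNeuronParams(
        C_pF=neuron.C_pF,
        g_L_nS=neuron.g_L_nS,
        E_L_mV=neuron.E_L_mV,
        V_T_mV=neuron.V_T_mV,
        Delta_T_mV=neuron.Delta_T_mV,
        a_nS=0.0,
        b_pA=0.0,
        tau_w_ms=neuron.tau_w_ms,
        V_reset_mV=neuron.V_reset_mV,
        V_spike_cut_mV=neuron.V_spike_cut_mV,
        t_ref_ms=neuron.t_ref_ms,
    )
    drive = ExternalDrive(
        rate_hz=np.append(K_e * nu_e, 0.0),
        n_ext=1,
        inh_rate_hz=np.append(K_i * nu_i, 0.0),
        inh_n_ext=1,
        I_const_pA=np.append(-W, 0.0),
    )
    rec, _ = simulate_point_network(
        conn, frozen, frozen, syn, drive, duration_ms, dt_ms=dt_ms, seed=seed
    )
    keep = rec.spike_times_ms >= discard_ms
    counts = np.bincount(rec.spike_ids[keep], minlength=n + 1)[:n]
    T_s = (duration_ms - discard_ms) * 1e-3
    rates = counts / T_s
    se = np.sqrt(np.maximum(counts, 1.0)) / T_s
    return rates, se


def fit_transfer_function(
    neuron: AdExNeuronParams,
    syn: SynapseParams,
    K_e: float,
    K_i: float,
    nu_e_grid_Hz=None,
    nu_i_grid_Hz=None,
    W_grid_pA=(0.0, 30.0, 60.0, 120.0, 240.0, 480.0),
    duration_ms: float = 10000.0,
    dt_ms: float = 0.1,
    seed: int = 0,
) -> TransferFunctionCoeffs:
    """Fit the effective-threshold polynomial from simulated stationary rates.

    For every grid combination a single neuron is simulated under Poisson
    bombardment; combinations with measurable output are inverted through the
    erfc rate formula to an empirical effective threshold, which is regressed
    on the second-order moment polynomial (ordinary least squares).
    """
    if nu_e_grid_Hz is None:
        # dense at the low rates that control down states and ignition, but
        # covering the full balanced range so fixed points are interior
        nu_e_grid_Hz = np.array(
            [0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
             12.0, 16.0, 24.0, 36.0, 50.0]
        )
    if nu_i_grid_Hz is None:
        nu_i_grid_Hz = np.array(
            [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0, 26.0, 36.0, 50.0, 70.0]
        )
    NE, NI, WW = np.meshgrid(
        np.asarray(nu_e_grid_Hz, dtype=float),
        np.asarray(nu_i_grid_Hz, dtype=float),
        np.asarray(W_grid_pA, dtype=float),
        indexing="ij",
    )
    ne, ni, ww = NE.ravel(), NI.ravel(), WW.ravel()
    rates, se = measure_single_neuron_rates(
        neuron, syn, ne, ni, ww, K_e, K_i, duration_ms=duration_ms,
        dt_ms=dt_ms, seed=seed,
    )
    mu_V, sigma_V, tau_V = subthreshold_moments(ne, ni, ww, neuron, syn, K_e, K_i)
    # invert nu = erfc(x) / (2 tau_V) -> x; usable only for 0 < nu < 1/tau_V
    y = 2.0 * tau_V * 1e-3 * rates
    ok = (rates > 0.1) & (y < 1.8) & (sigma_V > 1e-3)
    if np.sum(ok) < 20:
        warnings.warn("transfer-function grid too sparse; fit may be poor")
    x = erfcinv(np.clip(y[ok], 1e-12, 1.999999))
    V_eff = mu_V[ok] + np.sqrt(2.0) * sigma_V[ok] * x
    basis = _threshold_basis(mu_V[ok], sigma_V[ok], tau_V[ok], neuron)
    P, *_ = np.linalg.lstsq(basis, V_eff, rcond=None)
    pred = transfer_function(
        ne, ni, ww, TransferFunctionCoeffs(P), neuron, syn, K_e, K_i
    )
    rms = float(np.sqrt(np.mean((pred[ok] - rates[ok]) ** 2)))
    meta = {
        "K_e": float(K_e),
        "K_i": float(K_i),
        "n_grid_points": int(ne.size),
        "n_fit_points": int(np.sum(ok)),
        "fit_rms_Hz": rms,
        "duration_ms": float(duration_ms),
        "seed": int(seed),
        "nu_e_grid_Hz": [float(v) for v in np.asarray(nu_e_grid_Hz)],
        "nu_i_grid_Hz": [float(v) for v in np.asarray(nu_i_grid_Hz)],
        "W_grid_pA": [float(v) for v in np.asarray(W_grid_pA)],
    }
    return TransferFunctionCoeffs(P, meta)


def simulate_meanfield(
    params: MeanFieldParams,
    duration_ms: float,
    dt_ms: float = 0.1,
    drive: OrnsteinUhlenbeckDrive | None = None,
    seed: int = 0,
    init=(1.0, 1.0, 0.0),
) -> MeanFieldTrace:
    """Euler(-Maruyama) integration of the 3-state mean-field system.

    The external drive rate (plus OU fluctuation, floored at zero) is added to
    the excitatory input ``nu_e_bar`` of both transfer functions. Rates are
    clipped at zero; inhibitory adaptation is absent. Raises
    ``FloatingPointError`` on divergence.
    """
    if dt_ms > params.T_ms / 10.0:
        raise ValueError("dt must be at most T/10 for a stable integration")
    drive = drive or OrnsteinUhlenbeckDrive()
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_ms / dt_ms))
    nu_e, nu_i, W = (float(v) for v in init)
    xi = 0.0
    K_ext = drive.K_ext if drive.K_ext is not None else params.K_e
    scale_ext = K_ext / params.K_e  # drive expressed in recurrent-synapse units
    ne_tr = np.empty(n_steps)
    ni_tr = np.empty(n_steps)
    w_tr = np.empty(n_steps)
    t_tr = (np.arange(n_steps) + 1) * dt_ms
    sq = np.sqrt(2.0 * dt_ms / drive.tau_ms) if drive.sigma_hz > 0 else 0.0
    b_e = params.neuron_e.b_pA
    a_e = params.neuron_e.a_nS
    tau_w = params.neuron_e.tau_w_ms
    for k in range(n_steps):
        if drive.sigma_hz > 0:
            xi += -xi * dt_ms / drive.tau_ms + drive.sigma_hz * sq * rng.standard_normal()
        ext = max(drive.rate_hz + xi, 0.0) * scale_ext
        nu_e_bar = nu_e + ext
        nu_e_bar_i = nu_e + ext * drive.i_fraction
        Fe = transfer_function(
            nu_e_bar, nu_i, W, params.coeffs_e, params.neuron_e, params.syn,
            params.K_e, params.K_i,
        )
        Fi = transfer_function(
            nu_e_bar_i, nu_i, 0.0, params.coeffs_i, params.neuron_i, params.syn,
            params.K_e, params.K_i,
        )
        mu_V, _, _ = subthreshold_moments(
            nu_e_bar, nu_i, W, params.neuron_e, params.syn, params.K_e, params.K_i
        )
        nu_e = max(nu_e + dt_ms / params.T_ms * (float(Fe) - nu_e), 0.0)
        nu_i = max(nu_i + dt_ms / params.T_ms * (float(Fi) - nu_i), 0.0)
        W = W + dt_ms * (
            -W / tau_w + b_e * nu_e * 1e-3 + a_e * (float(mu_V) - params.neuron_e.E_L_mV) / tau_w
        )
        if not (np.isfinite(nu_e) and np.isfinite(nu_i) and np.isfinite(W)):
            raise FloatingPointError(
                f"mean-field state diverged at t={(k + 1) * dt_ms:.1f} ms"
            )
        ne_tr[k], ni_tr[k], w_tr[k] = nu_e, nu_i, W
    return MeanFieldTrace(t_tr, ne_tr, ni_tr, w_tr)


def save_tf_coeffs(path, coeffs_e: TransferFunctionCoeffs, coeffs_i: TransferFunctionCoeffs):
    data = {
        "provenance": (
            "fitted by neuroforward.adex_meanfield.fit_transfer_function from "
            "single-neuron AdEx simulations under Poisson bombardment"
        ),
        "excitatory": {"P_mV": [float(v) for v in coeffs_e.P], "meta": coeffs_e.meta},
        "inhibitory": {"P_mV": [float(v) for v in coeffs_i.P], "meta": coeffs_i.meta},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_tf_coeffs(path):
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return (
        TransferFunctionCoeffs(
            np.asarray(data["excitatory"]["P_mV"]), data["excitatory"].get("meta", {})
        ),
        TransferFunctionCoeffs(
            np.asarray(data["inhibitory"]["P_mV"]), data["inhibitory"].get("meta", {})
        ),
    )
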