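"""Current-dipole and volume-conductor forward model for MEG-like signals.

The magnetic field far from a localized population is computed from its total
current-dipole moment under the quasi-static approximation,

    B(r) = (mu0 / 4 pi) * Q x (r - r0) / |r - r0|^3 ,

with two source terms:

* a primary (synaptic/axial) dipole ``Q_s = n_e * L * I_A`` carried by the
  soma-dendrite axial currents of the excitatory cells (action-potential
  currents largely cancel and are neglected), and
* a secondary (conduction) dipole from return currents in a piecewise-
  homogeneous conductor, ``Q_c = -sum_i (sigma_i' - sigma_i'') *
  surface_integral(Phi) * n_i`` over all conductivity-discontinuity surfaces,
  with ``Phi`` the extracellular potential (supplied here by the uLFP kernel
  model).

The mean axial current is obtained from the stationary two-compartment
voltages under synaptic bombardment: conductance moments
``mu_G = nu * tau * q`` define per-compartment synaptic currents, and the
steady state of the two coupled passive compartments is a 2x2 linear solve.

Units: conductances nS, currents pA, voltages mV, rates Hz, dipole moments
nA*m, distances mm (sensor geometry), fields fT, conductivities S/m,
potentials uV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HybridCompartmentParams",
    "DipoleParams",
    "ConductorPatch",
    "ConductorModel",
    "SensorSpec",
    "DipoleTimeSeries",
    "conductance_moments",
    "stationary_compartment_voltages",
    "mean_axial_current",
    "axial_current_closed_form",
    "synaptic_dipole",
    "conduction_dipole",
    "magnetic_field",
    "meg_from_meanfield",
    "meg_from_spiking",
    "apply_gain_matrix",
    "diagonal_gain_matrix",
]

MU0_OVER_4PI = 1e-7  # T*m/A


@dataclass
class HybridCompartmentParams:
    """Passive two-compartment description used for the stationary solve.

    Compartment 1 is the soma/perisomatic region (receives the adaptation
    current W), compartment 2 the apical dendrite. ``K_*j`` are synapse counts
    per compartment; ``R_A_MOhm = 1/g_A``.
    """

    g_L1_nS: float = 10.0
    g_L2_nS: float = 2.0
    E_L_mV: float = -63.0
    R_A_MOhm: float = 2.5  # g_A = 400 nS
    K_e1: float = 120.0  # n_e * p_o * 0.3
    K_e2: float = 280.0  # n_e * p_o * 0.7
    K_i1: float = 60.0  # n_i * p_o * 0.6
    K_i2: float = 40.0  # n_i * p_o * 0.4
    q_e_nS: float = 1.5
    q_i_nS: float = 5.0
    tau_e_ms: float = 5.0
    tau_i_ms: float = 5.0
    E_e_mV: float = 0.0
    E_i_mV: float = -80.0

    def __post_init__(self):
        if self.R_A_MOhm <= 0:
            raise ValueError("R_A must be positive")
        if min(self.K_e1, self.K_e2, self.K_i1, self.K_i2) < 0:
            raise ValueError("synaptic counts must be non-negative")

    @property
    def g_A_nS(self) -> float:
        return 1e3 / self.R_A_MOhm  # 1/MOhm = uS = 1e3 nS


@dataclass
class DipoleParams:
    n_e: int = 8000
    L_um: float = 200.0
    orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self):
        if self.L_um <= 0:
            raise ValueError("L must be positive")
        self.orientation = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(self.orientation)
        if nrm == 0:
            raise ValueError("orientation must be a nonzero vector")
        self.orientation = self.orientation / nrm


@dataclass
class ConductorPatch:
    """Planar conductivity interface at cortical depth ``z_um``.

    ``sigma_in`` is the conductivity on the inner (deeper) side, ``sigma_out``
    on the outer side. In the gyrus-wall geometry the cortical-depth axis is
    tangential to the scalp, so the outward normal of a depth interface is
    tangential (parallel to the pyramidal dipole axis) — the default ``+x``.
    A radially oriented interface (normal ``+z``) produces a radial secondary
    dipole, which a radial far-field sensor does not see.
    """

    sigma_in_S_per_m: float
    sigma_out_S_per_m: float
    z_um: float
    extent_mm: tuple = (1.0, 1.0)
    center_mm: tuple = (0.5, 0.5)
    grid: tuple = (21, 21)
    normal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    label: str = ""

    def __post_init__(self):
        if self.sigma_in_S_per_m <= 0 or self.sigma_out_S_per_m <= 0:
            raise ValueError("conductivities must be positive")
        if self.grid[0] < 2 or self.grid[1] < 2:
            raise ValueError("quadrature grid must be at least 2x2")
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal = self.normal / np.linalg.norm(self.normal)

    def quadrature_points(self):
        """Midpoint-rule nodes (x, y in mm) and the cell area (mm^2)."""
        nx, ny = self.grid
        wx, wy = self.extent_mm
        cx, cy = self.center_mm
        x = cx - wx / 2 + (np.arange(nx) + 0.5) * wx / nx
        y = cy - wy / 2 + (np.arange(ny) + 0.5) * wy / ny
        X, Y = np.meshgrid(x, y, indexing="ij")
        return X.ravel(), Y.ravel(), (wx / nx) * (wy / ny)


@dataclass
class ConductorModel:
    patches: list

    def __post_init__(self):
        self.patches = list(self.patches)


@dataclass
class SensorSpec:
    """Sensor position relative to the source center (mm)."""

    position_mm: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 30.0]))

    def __post_init__(self):
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        if np.linalg.norm(self.position_mm) == 0:
            raise ValueError("sensor cannot sit at the source center")


@dataclass
class DipoleTimeSeries:
    times_ms: np.ndarray
    Q_s_nAm: np.ndarray  # (n_t, 3)
    Q_c_nAm: np.ndarray  # (n_t, 3)
    B_total_fT: np.ndarray  # (n_t, 3)
    B_axial_fT: np.ndarray
    B_conduction_fT: np.ndarray
    Q_c_per_patch_nAm: np.ndarray | None = None  # (n_patches, n_t, 3)
    I_A_pA: np.ndarray | None = None


def conductance_moments(nu_e_Hz, nu_i_Hz, q_e_nS, q_i_nS, tau_e_ms, tau_i_ms):
    """Mean synaptic conductance per synapse under Poisson bombardment:
    ``mu_G = nu * tau * q`` (nS with nu in Hz, tau in ms)."""
    nu_e = np.asarray(nu_e_Hz, dtype=float)
    nu_i = np.asarray(nu_i_Hz, dtype=float)
    if np.any(nu_e < 0) or np.any(nu_i < 0):
        raise ValueError("rates must be non-negative")
    return nu_e * tau_e_ms * 1e-3 * q_e_nS, nu_i * tau_i_ms * 1e-3 * q_i_nS


def stationary_compartment_voltages(nu_e_Hz, nu_i_Hz, W_pA, hp: HybridCompartmentParams):
    """Stationary mean voltages (mu_V1, mu_V2) of the coupled compartments.

    Sets both time derivatives of the passive two-compartment system to zero
    with synaptic currents ``K_e^j mu_Ge (E_e - V_j) + K_i^j mu_Gi (E_i - V_j)``
    and the adaptation current W on compartment 1, and solves the resulting
    2x2 linear system exactly (vectorized over time points).
    """
    mu_Ge, mu_Gi = conductance_moments(
        nu_e_Hz, nu_i_Hz, hp.q_e_nS, hp.q_i_nS, hp.tau_e_ms, hp.tau_i_ms
    )
    W = np.asarray(W_pA, dtype=float)
    g_A = hp.g_A_nS
    G1 = hp.g_L1_nS + hp.K_e1 * mu_Ge + hp.K_i1 * mu_Gi + g_A
    G2 = hp.g_L2_nS + hp.K_e2 * mu_Ge + hp.K_i2 * mu_Gi + g_A
    D1 = (
        hp.g_L1_nS * hp.E_L_mV
        + hp.K_e1 * mu_Ge * hp.E_e_mV
        + hp.K_i1 * mu_Gi * hp.E_i_mV
        - W
    )
    D2 = (
        hp.g_L2_nS * hp.E_L_mV
        + hp.K_e2 * mu_Ge * hp.E_e_mV
        + hp.K_i2 * mu_Gi * hp.E_i_mV
    )
    det = G1 * G2 - g_A**2
    if np.any(np.abs(det) < 1e-12):
        raise np.linalg.LinAlgError("degenerate conductance matrix")
    mu_V1 = (G2 * D1 + g_A * D2) / det
    mu_V2 = (G1 * D2 + g_A * D1) / det
    return mu_V1, mu_V2


def mean_axial_current(mu_V1, mu_V2, R_A_MOhm: float):
    """Soma-ward axial current ``I_A = (mu_V2 - mu_V1) / R_A`` in pA.

    Positive when the dendrite is depolarized relative to the soma (current
    flows dendrite -> soma), matching ``I_A = g_A (V_D - V_S)``.
    """
    if R_A_MOhm <= 0:
        raise ValueError("R_A must be positive")
    return (np.asarray(mu_V2) - np.asarray(mu_V1)) / R_A_MOhm * 1e3  # mV/MOhm = nA


def axial_current_closed_form(nu_e_Hz, nu_i_Hz, W_pA, hp: HybridCompartmentParams):
    """Closed-form axial current for the equal-leak case ``g_L1 = g_L2``.

    ``mu_V1 - mu_V2 = (I_syn1 - I_syn2 - W) / (2/R_A + g_L)`` with the
    synaptic currents evaluated at the common stationary voltage obtained by
    summing the two compartment equations; kept as an algebraic cross-check of
    the general linear solve.
    """
    if not np.isclose(hp.g_L1_nS, hp.g_L2_nS):
        raise ValueError("closed form requires g_L1 == g_L2")
    mu_Ge, mu_Gi = conductance_moments(
        nu_e_Hz, nu_i_Hz, hp.q_e_nS, hp.q_i_nS, hp.tau_e_ms, hp.tau_i_ms
    )
    mu_V1, mu_V2 = stationary_compartment_voltages(nu_e_Hz, nu_i_Hz, W_pA, hp)
    I1 = hp.K_e1 * mu_Ge * (hp.E_e_mV - mu_V1) + hp.K_i1 * mu_Gi * (hp.E_i_mV - mu_V1)
    I2 = hp.K_e2 * mu_Ge * (hp.E_e_mV - mu_V2) + hp.K_i2 * mu_Gi * (hp.E_i_mV - mu_V2)
    # subtracting the two stationary equations (g_L1 = g_L2 = g_L):
    # V1 - V2 = (I_syn1 - I_syn2 - W) / (2/R_A + g_L)
    dV12 = (I1 - I2 - np.asarray(W_pA)) / (2.0 * hp.g_A_nS + hp.g_L1_nS)
    return -dV12 * hp.g_A_nS  # pA, soma-ward sign convention


def synaptic_dipole(I_A_pA, dp: DipoleParams):
    """Primary dipole ``Q_s = n_e * L * I_A`` along the orientation unit
    vector; returns nA*m (time on the first axis if ``I_A`` is an array)."""
    I_A = np.atleast_1d(np.asarray(I_A_pA, dtype=float))
    # pA * um = 1e-12 A * 1e-6 m = 1e-18 A*m = 1e-9 nA*m
    mag = dp.n_e * dp.L_um * I_A * 1e-9
    return mag[:, None] * dp.orientation[None, :]


def conduction_dipole(lfp_field, cm: ConductorModel, t_grid_ms, per_patch: bool = False):
    """Secondary (volume-conduction) dipole from surface integrals of the LFP.

    ``lfp_field(x_mm, y_mm, z_um, t_grid_ms)`` must return Phi in uV with
    shape ``(n_points, n_t)``. Midpoint-rule quadrature over each patch,
    scaled by ``-(sigma' - sigma'')`` and directed along the patch normal.
    Returns nA*m, shape ``(n_t, 3)`` (plus per-patch array if requested).
    """
    t = np.asarray(t_grid_ms, dtype=float)
    total = np.zeros((t.size, 3))
    contribs = []
    for patch in cm.patches:
        dsig = patch.sigma_in_S_per_m - patch.sigma_out_S_per_m
        if dsig == 0.0:
            contribs.append(np.zeros((t.size, 3)))
            continue
        X, Y, dA_mm2 = patch.quadrature_points()
        phi = np.asarray(lfp_field(X, Y, patch.z_um, t), dtype=float)
        if phi.shape != (X.size, t.size):
            raise ValueError("lfp_field must return shape (n_points, n_times)")
        if not np.all(np.isfinite(phi)):
            raise ValueError("non-finite potential on conductor patch")
        # uV * S/m * mm^2 = 1e-6 V * S/m * 1e-6 m^2 = 1e-12 A*m = 1e-3 nA*m
        integral = phi.sum(axis=0) * dA_mm2
        q = -dsig * integral * 1e-3
        contrib = q[:, None] * patch.normal[None, :]
        contribs.append(contrib)
        total += contrib
    if per_patch:
        return total, np.array(contribs)
    return total


def magnetic_field(Q_nAm, sensor: SensorSpec, source_center_mm=(0.0, 0.0, 0.0)):
    """Far-field dipole formula ``B = (mu0/4pi) Q x r / |r|^3`` in fT.

    ``Q_nAm`` may be a single vector or ``(n_t, 3)``.
    """
    Q = np.atleast_2d(np.asarray(Q_nAm, dtype=float))
    r = (sensor.position_mm - np.asarray(source_center_mm, dtype=float)) * 1e-3  # m
    dist = np.linalg.norm(r)
    if dist == 0:
        raise ValueError("sensor coincides with the source")
    B_T = MU0_OVER_4PI * np.cross(Q * 1e-9, r[None, :]) / dist**3
    B = B_T * 1e15
    return B[0] if np.asarray(Q_nAm).ndim == 1 else B


def _warn_far_field(sensor: SensorSpec, source_extent_mm: float):
    if np.linalg.norm(sensor.position_mm) < 5.0 * source_extent_mm:
        warnings.warn(
            "sensor distance is not large compared to the source extent; "
            "far-field dipole approximation may be inaccurate",
            stacklevel=3,
        )


def meg_from_meanfield(
    trace,
    hp: HybridCompartmentParams,
    dp: DipoleParams,
    sensor: SensorSpec,
    cm: ConductorModel | None = None,
    lfp_field=None,
    source_extent_mm: float = 1.0,
) -> DipoleTimeSeries:
    """Full MEG forward chain from a mean-field trace.

    Per time point: stationary compartment voltages -> mean axial current ->
    primary dipole; kernel LFP over the conductor interfaces -> secondary
    dipole; both fields at the sensor. With no conductor (homogeneous medium)
    the secondary dipole is identically zero.
    """
    _warn_far_field(sensor, source_extent_mm)
    mu_V1, mu_V2 = stationary_compartment_voltages(
        trace.nu_e_Hz, trace.nu_i_Hz, trace.W_pA, hp
    )
    I_A = mean_axial_current(mu_V1, mu_V2, hp.R_A_MOhm)
    Q_s = synaptic_dipole(I_A, dp)
    t = trace.times_ms
    if cm is not None and lfp_field is not None:
        Q_c, Q_c_patches = conduction_dipole(lfp_field, cm, t, per_patch=True)
    else:
        Q_c = np.zeros((t.size, 3))
        Q_c_patches = np.zeros((0, t.size, 3))
    B_axial = magnetic_field(Q_s, sensor)
    B_cond = magnetic_field(Q_c, sensor) if np.any(Q_c) else np.zeros_like(B_axial)
    return DipoleTimeSeries(
        times_ms=t,
        Q_s_nAm=Q_s,
        Q_c_nAm=Q_c,
        B_total_fT=B_axial + B_cond,
        B_axial_fT=B_axial,
        B_conduction_fT=B_cond,
        Q_c_per_patch_nAm=Q_c_patches,
        I_A_pA=I_A,
    )


def meg_from_spiking(
    axial, dp: DipoleParams, sensor: SensorSpec, source_extent_mm: float = 1.0
) -> DipoleTimeSeries:
    """MEG from a spiking two-compartment run: ``Q_s = n_e L <I_A>(t)``,
    far-field dipole formula, no conduction term (homogeneous medium)."""
    _warn_far_field(sensor, source_extent_mm)
    Q_s = synaptic_dipole(axial.mean_I_A_pA, dp)
    t = axial.times_ms
    B = magnetic_field(Q_s, sensor)
    zeros = np.zeros((t.size, 3))
    return DipoleTimeSeries(
        times_ms=t,
        Q_s_nAm=Q_s,
        Q_c_nAm=zeros,
        B_total_fT=B,
        B_axial_fT=B,
        B_conduction_fT=zeros,
        I_A_pA=np.asarray(axial.mean_I_A_pA, dtype=float),
    )


def diagonal_gain_matrix(n_regions: int, distance_mm: float = 30.0) -> np.ndarray:
    """Per-region scalar gain ``mu0/(4 pi d^2)``: one radial sensor per
    region, each seeing only its own region's tangential dipole.

    Maps |Q| in nA*m to B in fT.
    """
    g = MU0_OVER_4PI / (distance_mm * 1e-3) ** 2 * 1e-9 * 1e15
    return g * np.eye(n_regions)


def apply_gain_matrix(Q_magnitudes, G: np.ndarray):
    """Sensor fields ``B = G Q`` (matrix product; fT with the diagonal gain).

    ``Q_magnitudes``: (n_regions,) or (n_t, n_regions).
    """
    Q = np.asarray(Q_magnitudes, dtype=float)
    G = np.asarray(G, dtype=float)
    if Q.shape[-1] != G.shape[1]:
        raise ValueError(
            f"shape mismatch: gain is {G.shape}, sources are {Q.shape}"
        )
    return Q @ G.T
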