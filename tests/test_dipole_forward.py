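"""Dipole and volume-conductor forward model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neuroforward.dipole_forward import (
    ConductorModel,
    ConductorPatch,
    DipoleParams,
    HybridCompartmentParams,
    SensorSpec,
    apply_gain_matrix,
    axial_current_closed_form,
    conductance_moments,
    conduction_dipole,
    diagonal_gain_matrix,
    magnetic_field,
    mean_axial_current,
    meg_from_spiking,
    stationary_compartment_voltages,
    synaptic_dipole,
)
from neuroforward.adex_spiking import AxialCurrentTrace


class TestConductanceMoments:
    def test_printed_parameter_product(self):
        # nu*tau*q: 10 Hz * 5 ms * 1.5 nS
        mu_e, mu_i = conductance_moments(10.0, 0.0, 1.5, 5.0, 5.0, 5.0)
        assert mu_e == pytest.approx(0.075)
        assert mu_i == 0.0

    def test_linearity_in_rate(self):
        a, _ = conductance_moments(7.0, 0.0, 1.5, 5.0, 5.0, 5.0)
        b, _ = conductance_moments(14.0, 0.0, 1.5, 5.0, 5.0, 5.0)
        assert b == pytest.approx(2 * a)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            conductance_moments(-1.0, 0.0, 1.5, 5.0, 5.0, 5.0)


class TestStationaryVoltages:
    def test_leak_only_equilibrium(self):
        hp = HybridCompartmentParams()
        v1, v2 = stationary_compartment_voltages(0.0, 0.0, 0.0, hp)
        assert v1 == pytest.approx(hp.E_L_mV)
        assert v2 == pytest.approx(hp.E_L_mV)
        assert mean_axial_current(v1, v2, hp.R_A_MOhm) == pytest.approx(0.0)

    def test_symmetric_compartments_equal_voltage(self):
        hp = HybridCompartmentParams(
            g_L1_nS=10.0, g_L2_nS=10.0, K_e1=200.0, K_e2=200.0,
            K_i1=50.0, K_i2=50.0,
        )
        v1, v2 = stationary_compartment_voltages(5.0, 10.0, 0.0, hp)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_ode_relaxation_oracle_sweep(self):
        """The linear solve equals the long-time limit of integrating the
        two-compartment ODEs, over a random parameter sweep."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            hp = HybridCompartmentParams(
                g_L1_nS=rng.uniform(2, 20),
                g_L2_nS=rng.uniform(1, 20),
                R_A_MOhm=rng.uniform(0.5, 10),
                K_e1=rng.uniform(0, 300),
                K_e2=rng.uniform(0, 300),
                K_i1=rng.uniform(0, 100),
                K_i2=rng.uniform(0, 100),
            )
            nu_e, nu_i, W = rng.uniform(0, 20), rng.uniform(0, 40), rng.uniform(0, 300)
            v1, v2 = stationary_compartment_voltages(nu_e, nu_i, W, hp)
            mu_Ge, mu_Gi = conductance_moments(
                nu_e, nu_i, hp.q_e_nS, hp.q_i_nS, hp.tau_e_ms, hp.tau_i_ms
            )
            C1, C2 = 200.0, 10.0

            def rhs(_t, y):
                V1, V2 = y
                g_A = hp.g_A_nS
                i1 = (
                    hp.g_L1_nS * (hp.E_L_mV - V1)
                    + hp.K_e1 * mu_Ge * (hp.E_e_mV - V1)
                    + hp.K_i1 * mu_Gi * (hp.E_i_mV - V1)
                    - W + g_A * (V2 - V1)
                )
                i2 = (
                    hp.g_L2_nS * (hp.E_L_mV - V2)
                    + hp.K_e2 * mu_Ge * (hp.E_e_mV - V2)
                    + hp.K_i2 * mu_Gi * (hp.E_i_mV - V2)
                    - g_A * (V2 - V1)
                )
                return [i1 / C1, i2 / C2]

            sol = solve_ivp(rhs, (0.0, 500.0), [hp.E_L_mV, hp.E_L_mV],
                            rtol=1e-10, atol=1e-10)
            assert abs(sol.y[0, -1] - v1) < 1e-6
            assert abs(sol.y[1, -1] - v2) < 1e-6

    def test_closed_form_matches_solve_for_equal_leak(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            gL = rng.uniform(2, 20)
            hp = HybridCompartmentParams(
                g_L1_nS=gL, g_L2_nS=gL,
                K_e1=rng.uniform(0, 300), K_e2=rng.uniform(0, 300),
                K_i1=rng.uniform(0, 100), K_i2=rng.uniform(0, 100),
            )
            nu_e, nu_i, W = rng.uniform(0, 20), rng.uniform(0, 40), rng.uniform(0, 300)
            v1, v2 = stationary_compartment_voltages(nu_e, nu_i, W, hp)
            ia = mean_axial_current(v1, v2, hp.R_A_MOhm)
            ia_closed = axial_current_closed_form(nu_e, nu_i, W, hp)
            assert ia == pytest.approx(ia_closed, abs=1e-9)

    def test_ohmic_identity(self):
        # 2 mV across R_A = 2.5 MOhm (g_A = 400 nS) drives 800 pA
        assert mean_axial_current(-55.0, -53.0, 2.5) == pytest.approx(800.0)


class TestSynapticDipole:
    def test_printed_magnitude(self):
        dp = DipoleParams(n_e=8000, L_um=200.0)
        q = synaptic_dipole(1.0, dp)
        assert np.linalg.norm(q) == pytest.approx(1.6e-3)  # nA*m

    def test_zero_current_zero_dipole(self):
        assert np.all(synaptic_dipole(0.0, DipoleParams()) == 0)

    def test_linearity_in_population_size(self):
        q1 = synaptic_dipole(3.0, DipoleParams(n_e=4000))
        q2 = synaptic_dipole(3.0, DipoleParams(n_e=8000))
        np.testing.assert_allclose(q2, 2 * q1)


class TestConductionDipole:
    def _patch(self, **kw):
        defaults = dict(sigma_in_S_per_m=0.3, sigma_out_S_per_m=2.1, z_um=800.0)
        defaults.update(kw)
        return ConductorPatch(**defaults)

    def test_homogeneous_medium_zero(self):
        cm = ConductorModel([self._patch(sigma_out_S_per_m=0.3)])
        t = np.arange(10.0)
        qc = conduction_dipole(lambda x, y, z, tt: np.ones((x.size, tt.size)), cm, t)
        assert np.all(qc == 0)

    def test_constant_potential_closed_form(self):
        phi0, area = 150.0, 1.0  # uV, mm^2
        cm = ConductorModel([self._patch()])
        t = np.arange(5.0)
        qc = conduction_dipole(
            lambda x, y, z, tt: np.full((x.size, tt.size), phi0), cm, t
        )
        expected = abs(0.3 - 2.1) * phi0 * area * 1e-3  # nA*m
        assert np.linalg.norm(qc[0]) == pytest.approx(expected, rel=1e-12)

    def test_gaussian_profile_quadrature_convergence(self):
        def phi(x, y, z, tt):
            g = 100.0 * np.exp(-(((x - 0.5) ** 2 + (y - 0.5) ** 2) / 0.02))
            return np.repeat(g[:, None], tt.size, axis=1)

        t = np.arange(3.0)
        coarse = conduction_dipole(phi, ConductorModel([self._patch(grid=(21, 21))]), t)
        fine = conduction_dipole(phi, ConductorModel([self._patch(grid=(201, 201))]), t)
        assert np.linalg.norm(coarse[0]) == pytest.approx(
            np.linalg.norm(fine[0]), rel=1e-3
        )

    def test_non_finite_potential_rejected(self):
        cm = ConductorModel([self._patch()])
        with pytest.raises(ValueError, match="non-finite"):
            conduction_dipole(
                lambda x, y, z, tt: np.full((x.size, tt.size), np.nan),
                cm, np.arange(3.0),
            )


class TestMagneticField:
    def test_radial_dipole_null(self):
        s = SensorSpec(np.array([0.0, 0.0, 30.0]))
        B = magnetic_field(np.array([0.0, 0.0, 2.0]), s)
        np.testing.assert_allclose(B, 0.0)

    def test_tangential_unit_dipole_at_3cm(self):
        s = SensorSpec(np.array([0.0, 0.0, 30.0]))
        B = magnetic_field(np.array([1.0, 0.0, 0.0]), s)
        assert np.linalg.norm(B) == pytest.approx(111.11, rel=1e-3)  # fT

    def test_inverse_square_scaling(self):
        q = np.array([1.0, 0.5, 0.0])
        B1 = magnetic_field(q, SensorSpec(np.array([0.0, 0.0, 30.0])))
        B2 = magnetic_field(q, SensorSpec(np.array([0.0, 0.0, 60.0])))
        np.testing.assert_allclose(np.linalg.norm(B1), 4 * np.linalg.norm(B2))

    def test_linearity_in_dipole(self):
        s = SensorSpec(np.array([5.0, 7.0, 30.0]))
        q = np.array([0.3, -0.4, 0.1])
        np.testing.assert_allclose(
            magnetic_field(3.0 * q, s), 3.0 * magnetic_field(q, s), rtol=1e-12
        )

    def test_zero_distance_error(self):
        with pytest.raises(ValueError):
            magnetic_field(np.array([1.0, 0, 0]), SensorSpec(np.array([1.0, 0, 0])),
                           source_center_mm=(1.0, 0, 0))


class TestMegFromSpiking:
    def test_constant_axial_current_chain(self):
        # 1 pA mean axial current, 8000 cells, L=200 um, sensor at 3 cm
        t = np.arange(0.0, 100.0, 1.0)
        axial = AxialCurrentTrace(t, np.ones_like(t))
        ts = meg_from_spiking(
            axial, DipoleParams(n_e=8000, L_um=200.0),
            SensorSpec(np.array([0.0, 0.0, 30.0])),
        )
        assert np.linalg.norm(ts.B_total_fT[0]) == pytest.approx(
            111.11 * 1.6e-3, rel=1e-3
        )
        assert np.all(ts.B_conduction_fT == 0)

    def test_zero_current_zero_field(self):
        t = np.arange(0.0, 10.0, 1.0)
        ts = meg_from_spiking(
            AxialCurrentTrace(t, np.zeros_like(t)),
            DipoleParams(), SensorSpec(np.array([0.0, 0.0, 30.0])),
        )
        assert np.all(ts.B_total_fT == 0)


class TestGainMatrix:
    def test_single_source_matches_direct_field(self):
        G = diagonal_gain_matrix(1, distance_mm=30.0)
        B = apply_gain_matrix(np.array([1.0]), G)
        direct = magnetic_field(
            np.array([1.0, 0.0, 0.0]), SensorSpec(np.array([0.0, 0.0, 30.0]))
        )
        assert B[0] == pytest.approx(np.linalg.norm(direct), rel=1e-12)

    def test_zero_sources(self):
        G = diagonal_gain_matrix(4)
        assert np.all(apply_gain_matrix(np.zeros(4), G) == 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_gain_matrix(np.zeros(3), diagonal_gain_matrix(4))

    def test_diagonal_gain_proportional(self):
        G = diagonal_gain_matrix(3, distance_mm=30.0)
        q = np.array([1.0, 2.0, -0.5])
        B = apply_gain_matrix(q, G)
        np.testing.assert_allclose(B, 111.11 * q, rtol=1e-3)
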