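"""Spiking AdEx network simulators."""

import numpy as np
import pytest

from neuroforward.adex_spiking import (
    AdExNeuronParams,
    ExternalDrive,
    NetworkSpec,
    SynapseParams,
    TwoCompartmentParams,
    build_network,
    population_rates,
    simulate_point_network,
    simulate_two_compartment_network,
)
from neuroforward.fixtures import make_poisson_fixture


class TestBuildNetwork:
    def test_empty_at_zero_probability(self):
        conn = build_network(NetworkSpec(n_total=50, p_connect=0.0, seed=0))
        assert conn.adjacency.nnz == 0

    def test_labels_and_counts(self):
        spec = NetworkSpec(n_total=1000, frac_excitatory=0.8, p_connect=0.02, seed=1)
        conn = build_network(spec)
        assert conn.is_excitatory.sum() == 800
        assert np.all(conn.is_excitatory[:800])
        assert conn.positions_mm.shape == (1000, 2)
        assert conn.positions_mm.min() >= 0
        assert conn.positions_mm.max() <= 1.0

    def test_no_self_connections(self):
        conn = build_network(NetworkSpec(n_total=200, p_connect=0.5, seed=3))
        assert conn.adjacency.diagonal().sum() == 0

    def test_connection_fraction_binomial_oracle(self):
        """Empirical connection fraction over many seeds stays within 3
        binomial SD of p."""
        n, p, n_seeds = 100, 0.05, 200
        total_pairs = n * (n - 1) * n_seeds
        edges = sum(
            build_network(NetworkSpec(n_total=n, p_connect=p, seed=s)).adjacency.nnz
            for s in range(n_seeds)
        )
        sd = np.sqrt(total_pairs * p * (1 - p))
        assert abs(edges - total_pairs * p) < 3 * sd

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(n_total=10, p_connect=1.5)


class TestPointNetwork:
    def test_quiescent_neuron_stays_at_rest(self, small_network, neuron_e, neuron_i, syn):
        rec, states = simulate_point_network(
            small_network, neuron_e, neuron_i, syn,
            ExternalDrive(rate_hz=0.0), 200.0, seed=0, record_states=3,
        )
        assert rec.spike_ids.size == 0
        # rest sits a few microvolts above E_L (exponential term at rest)
        np.testing.assert_allclose(states["V"], neuron_e.E_L_mV, atol=0.01)

    def test_suprathreshold_step_matches_refined_dt(self, syn):
        """Spike count under a constant current step agrees with a dt/10
        reference integration within one spike."""
        conn = build_network(NetworkSpec(n_total=2, p_connect=0.0, seed=0))
        pe = AdExNeuronParams(b_pA=60.0)
        drive = ExternalDrive(rate_hz=0.0, I_const_pA=500.0)
        rec1, _ = simulate_point_network(conn, pe, pe, syn, drive, 1000.0,
                                         dt_ms=0.1, seed=0)
        rec2, _ = simulate_point_network(conn, pe, pe, syn, drive, 1000.0,
                                         dt_ms=0.01, seed=0)
        n1 = (rec1.spike_ids == 0).sum()
        n2 = (rec2.spike_ids == 0).sum()
        assert n1 > 5
        assert abs(int(n1) - int(n2)) <= 1

    def test_refractory_contract(self, small_network, neuron_e, neuron_i, syn):
        rec, _ = simulate_point_network(
            small_network, neuron_e, neuron_i, syn,
            ExternalDrive(rate_hz=5.0, n_ext=100), 1000.0, seed=2,
        )
        assert rec.spike_ids.size > 0
        assert rec.min_isi_ms() >= neuron_e.t_ref_ms

    def test_conductance_positivity(self, small_network, neuron_e, neuron_i, syn):
        _, states = simulate_point_network(
            small_network, neuron_e, neuron_i, syn,
            ExternalDrive(rate_hz=3.0, n_ext=100), 500.0, seed=3, record_states=5,
        )
        assert np.all(states["Ge"] >= 0)
        assert np.all(states["Gi"] >= 0)

    def test_dt_convergence_of_rates(self, small_network, neuron_e, neuron_i, syn):
        """Halving dt leaves the population rate statistically unchanged.

        The Poisson drive realization differs between step sizes, so the
        comparison is on the stationary mean rate (finite-size SE ~2%),
        not sample-by-sample.
        """
        means = {}
        for dt in (0.1, 0.05):
            rec, _ = simulate_point_network(
                small_network, neuron_e, neuron_i, syn,
                ExternalDrive(rate_hz=4.0, n_ext=100), 2000.0, dt_ms=dt, seed=4,
            )
            rt = population_rates(rec, bin_ms=10.0, duration_ms=2000.0)
            means[dt] = rt.nu_e_Hz[rt.times_ms > 500].mean()
        assert means[0.1] > 0.5
        assert abs(means[0.1] - means[0.05]) < 0.08 * means[0.1]

    def test_dt_upper_bound_enforced(self, small_network, neuron_e, neuron_i, syn):
        with pytest.raises(ValueError, match="dt"):
            simulate_point_network(
                small_network, neuron_e, neuron_i, syn,
                ExternalDrive(), 10.0, dt_ms=0.5,
            )

    def test_synaptic_delay_shifts_arrival(self, syn):
        """An excitatory spike reaches its target exactly delay later."""
        spec = NetworkSpec(n_total=2, frac_excitatory=0.5, p_connect=0.0, seed=0)
        conn = build_network(spec)
        from scipy import sparse

        conn.adjacency = sparse.csr_matrix(
            np.array([[0, 1], [0, 0]], dtype=np.int8)
        )
        pe = AdExNeuronParams()
        drive = ExternalDrive(rate_hz=0.0, I_const_pA=np.array([800.0, 0.0]))
        for delay in (0.0, 2.0):
            _, states = simulate_point_network(
                conn, pe, pe, syn, drive, 50.0, seed=0, record_states=2,
                synaptic_delay_ms=delay,
            )
            ge_target = states["Ge"][:, 1]
            onset = states["t"][np.argmax(ge_target > 0)]
            if delay == 0.0:
                t0 = onset
        assert onset - t0 == pytest.approx(2.0, abs=0.11)


class TestPopulationRates:
    def test_counting_identity(self):
        rec = make_poisson_fixture(100, 25, 0.0, 10.0, seed=0)
        rec.spike_ids = np.arange(100)
        rec.spike_times_ms = np.full(100, 5.0)
        rt = population_rates(rec, bin_ms=10.0)
        # 100 neurons each spiking once in one 10 ms bin -> 100 Hz
        assert rt.nu_e_Hz[0] == pytest.approx(100.0)

    def test_poisson_oracle(self):
        rec = make_poisson_fixture(1000, 250, 10.0, 10000.0, seed=5)
        rt = population_rates(rec, bin_ms=10.0)
        mean = rt.nu_e_Hz.mean()
        se = 10.0 / np.sqrt(1000 * 10.0 * 10.0)  # rate / sqrt(total spikes)
        assert abs(mean - 10.0) < 3 * se

    def test_empty_record(self):
        rec = make_poisson_fixture(10, 5, 0.0, 100.0, seed=0)
        rt = population_rates(rec, bin_ms=10.0)
        assert np.all(rt.nu_e_Hz == 0) and np.all(rt.nu_i_Hz == 0)

    def test_invalid_bin(self):
        rec = make_poisson_fixture(5, 5, 1.0, 100.0, seed=0)
        with pytest.raises(ValueError):
            population_rates(rec, bin_ms=0.0)


class TestTwoCompartment:
    def test_rest_zero_axial_current(self, syn):
        conn = build_network(NetworkSpec(n_total=20, p_connect=0.0, seed=0))
        tc = TwoCompartmentParams()
        pi = AdExNeuronParams(Delta_T_mV=0.5, V_spike_cut_mV=-47.5, V_reset_mV=-65.0)
        _, axial = simulate_two_compartment_network(
            conn, tc, pi, syn, ExternalDrive(rate_hz=0.0), 100.0, seed=0,
        )
        # the somatic exponential term at rest leaves a sub-pA residual
        np.testing.assert_allclose(axial.mean_I_A_pA, 0.0, atol=0.1)

    def test_ohmic_identity(self):
        tc = TwoCompartmentParams()
        assert tc.g_A_nS * 1.0 == pytest.approx(400.0)  # 1 mV -> 400 pA

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            TwoCompartmentParams(p_e1=0.4, p_e2=0.4)

    def test_zero_coupling_reproduces_point_soma(self, syn):
        """With g_A = 0, all synapses on the soma and a deterministic current
        drive, the soma trajectory equals the point model's."""
        conn = build_network(NetworkSpec(n_total=10, frac_excitatory=0.5,
                                         p_connect=0.0, seed=0))
        tc = TwoCompartmentParams(g_A_nS=1e-9, p_e1=1.0, p_e2=0.0,
                                  p_i1=1.0, p_i2=0.0)
        pi = AdExNeuronParams(Delta_T_mV=0.5, V_spike_cut_mV=-47.5, V_reset_mV=-65.0)
        drive = ExternalDrive(rate_hz=0.0, I_const_pA=420.0)
        rec2c, _ = simulate_two_compartment_network(
            conn, tc, pi, syn, drive, 500.0, seed=1,
        )
        point = tc.soma_point_params()
        recp, _ = simulate_point_network(conn, point, pi, syn, drive, 500.0, seed=1)
        # same drive current is suprathreshold only for excitatory cells
        t2c = rec2c.spike_times_ms[rec2c.is_excitatory[rec2c.spike_ids]]
        tp = recp.spike_times_ms[recp.is_excitatory[recp.spike_ids]]
        np.testing.assert_allclose(np.sort(t2c), np.sort(tp), atol=1e-9)

    def test_axial_trace_uniform_grid(self, syn):
        conn = build_network(NetworkSpec(n_total=20, p_connect=0.1, seed=2))
        tc = TwoCompartmentParams()
        pi = AdExNeuronParams(Delta_T_mV=0.5, V_spike_cut_mV=-47.5, V_reset_mV=-65.0)
        _, axial = simulate_two_compartment_network(
            conn, tc, pi, syn, ExternalDrive(rate_hz=2.0, n_ext=100), 200.0,
            seed=3, axial_subsample=5,
        )
        assert np.allclose(np.diff(axial.times_ms), 0.5)
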