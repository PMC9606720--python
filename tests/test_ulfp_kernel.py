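"""uLFP kernel construction and LFP synthesis."""

import numpy as np
import pytest

from neuroforward.adex_spiking import SpikeRecord
from neuroforward.fixtures import make_poisson_fixture
from neuroforward.ulfp_kernel import (
    ElectrodeSpec,
    disk_average_factor,
    disk_average_factor_quadrature,
    evaluate_kernel,
    lfp_from_rates,
    lfp_from_spikes,
    population_kernel,
    rate_lfp_field,
    resolve_depth,
)


class TestDiskAverage:
    def test_closed_form_value(self):
        # mean of exp(-r/lambda) over a disk of radius 2*lambda
        assert disk_average_factor() == pytest.approx(0.5 * (1 - 3 * np.exp(-2)))
        assert disk_average_factor() == pytest.approx(0.297, abs=5e-4)

    def test_quadrature_matches_closed_form(self):
        assert disk_average_factor_quadrature(200.0, n=20000) == pytest.approx(
            disk_average_factor(), abs=1e-6
        )

    @pytest.mark.parametrize("lam", [200.0, 250.0])
    def test_lambda_independence(self, lam):
        assert disk_average_factor_quadrature(lam) == pytest.approx(
            disk_average_factor_quadrature(225.0), abs=1e-9
        )

    def test_2d_grid_quadrature_oracle(self):
        # independent 2-D cartesian quadrature over the disk
        lam = 220.0
        R = 2 * lam
        n = 4001
        x = np.linspace(-R, R, n)
        X, Y = np.meshgrid(x, x)
        r = np.hypot(X, Y)
        inside = r <= R
        val = np.exp(-r[inside] / lam).sum() / inside.sum()
        assert val == pytest.approx(disk_average_factor(), abs=1e-3)


class TestEvaluateKernel:
    def test_peak_amplitude_at_source(self, kernel_e):
        el = ElectrodeSpec(0.3, 0.4, "surface")
        t = np.arange(0.0, 60.0, 0.1)
        k = evaluate_kernel(kernel_e, el, (0.3, 0.4), t0_ms=5.0, t_grid_ms=t)
        ipk = np.argmax(np.abs(k))
        assert t[ipk] == pytest.approx(5.0 + kernel_e.d_ms, abs=0.11)
        assert k[ipk] == pytest.approx(kernel_e.A0("surface"))

    def test_amplitude_at_lambda(self, kernel_e):
        el = ElectrodeSpec(0.0, 0.0, "soma")
        t = np.arange(0.0, 80.0, 0.05)
        k = evaluate_kernel(kernel_e, el, (kernel_e.lambda_um * 1e-3, 0.0), 0.0, t)
        peak = k[np.argmax(np.abs(k))]
        assert peak == pytest.approx(kernel_e.A0("soma") * np.exp(-1), rel=1e-6)

    def test_axonal_delay_one_mm(self, kernel_e):
        el = ElectrodeSpec(0.0, 0.0, "surface")
        t = np.arange(0.0, 80.0, 0.05)
        k = evaluate_kernel(kernel_e, el, (1.0, 0.0), 0.0, t)
        # 1 mm at 200 mm/s adds 5 ms to the constant delay
        assert t[np.argmax(np.abs(k))] == pytest.approx(kernel_e.d_ms + 5.0, abs=0.06)

    def test_depth_clamp_warns(self, kernel_e):
        with pytest.warns(UserWarning, match="clamp"):
            kernel_e.A0(1200.0)

    def test_unknown_depth_label(self):
        with pytest.raises(ValueError, match="unknown depth label"):
            resolve_depth("mid")


def _single_spike_record(x=0.5, y=0.5, t=20.0):
    return SpikeRecord(
        n_neurons=1,
        spike_ids=np.array([0]),
        spike_times_ms=np.array([t]),
        positions_mm=np.array([[x, y]]),
        is_excitatory=np.array([True]),
        duration_ms=100.0,
    )


class TestLfpFromSpikes:
    def test_single_spike_gaussian_pulse(self, kernel_e, kernel_i):
        rec = _single_spike_record()
        t = np.arange(0.0, 100.0, 0.1)
        lfp = lfp_from_spikes(rec, [ElectrodeSpec(0.5, 0.5, "surface")],
                              kernel_e, kernel_i, t)
        v = lfp.V_uV[0]
        ipk = np.argmax(np.abs(v))
        assert v[ipk] == pytest.approx(kernel_e.A0("surface"), rel=1e-6)
        assert t[ipk] == pytest.approx(20.0 + kernel_e.d_ms, abs=0.11)
        # Gaussian width check at half maximum
        width = (np.abs(v) > abs(v[ipk]) / 2).sum() * 0.1
        assert width == pytest.approx(2.355 * kernel_e.sigma_ms, rel=0.05)

    def test_superposition_linearity(self, kernel_e, kernel_i, rng):
        rec = make_poisson_fixture(20, 5, 20.0, 500.0, seed=5)
        doubled = SpikeRecord(
            rec.n_neurons,
            np.concatenate([rec.spike_ids] * 2),
            np.concatenate([rec.spike_times_ms] * 2),
            rec.positions_mm,
            rec.is_excitatory,
            rec.duration_ms,
        )
        t = np.arange(0.0, 500.0, 0.5)
        el = [ElectrodeSpec(0.5, 0.5, "surface")]
        v1 = lfp_from_spikes(rec, el, kernel_e, kernel_i, t).V_uV
        v2 = lfp_from_spikes(doubled, el, kernel_e, kernel_i, t).V_uV
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-10, atol=1e-12)

    def test_empty_record_zero(self, kernel_e, kernel_i):
        rec = make_poisson_fixture(10, 2, 0.0, 100.0, seed=1)
        t = np.arange(0.0, 100.0, 1.0)
        lfp = lfp_from_spikes(rec, [ElectrodeSpec(0, 0, "soma")], kernel_e, kernel_i, t)
        assert np.all(lfp.V_uV == 0)

    def test_radial_decay_recovers_lambda(self, kernel_e, kernel_i):
        # point source, electrodes at increasing radius: fit exp decay
        rec = _single_spike_record(x=0.0, y=0.0)
        radii = np.array([0.05, 0.1, 0.2, 0.3, 0.4])
        els = [ElectrodeSpec(r, 0.0, "surface") for r in radii]
        t = np.arange(0.0, 100.0, 0.1)
        lfp = lfp_from_spikes(rec, els, kernel_e, kernel_i, t)
        peaks = np.max(np.abs(lfp.V_uV), axis=1)
        lam_fit = -1.0 / np.polyfit(radii * 1e3, np.log(peaks), 1)[0]
        assert lam_fit == pytest.approx(kernel_e.lambda_um, rel=0.02)


class TestLfpFromRates:
    def test_zero_rates_zero_lfp(self, kernel_e, kernel_i):
        t = np.arange(0.0, 1000.0, 1.0)
        z = np.zeros_like(t)
        lfp = lfp_from_rates(t, z, z, 8000, 2000,
                             [ElectrodeSpec(0.5, 0.5, "surface")], kernel_e, kernel_i)
        assert np.all(lfp.V_uV == 0)

    def test_constant_rate_closed_form(self, kernel_e, kernel_i):
        t = np.arange(0.0, 2000.0, 1.0)
        nu_e = np.full_like(t, 10.0)
        lfp = lfp_from_rates(t, nu_e, np.zeros_like(t), 8000, 2000,
                             [ElectrodeSpec(0.5, 0.5, "surface")], kernel_e, kernel_i)
        expected = (
            8000 * 10.0 * 1e-3 * disk_average_factor() * kernel_e.A0("surface")
            * kernel_e.sigma_ms * np.sqrt(2 * np.pi)
        )
        assert lfp.V_uV[0, 500:1500].mean() == pytest.approx(expected, rel=1e-3)
        assert lfp.V_uV[0, 500:1500].std() < 1e-6 * abs(expected)

    def test_step_response_delayed_by_d(self, kernel_e, kernel_i):
        t = np.arange(0.0, 600.0, 0.5)
        nu_e = np.where(t >= 300.0, 20.0, 0.0)
        lfp = lfp_from_rates(t, nu_e, np.zeros_like(t), 1000, 0,
                             [ElectrodeSpec(0.5, 0.5, "surface")], kernel_e, kernel_i)
        v = lfp.V_uV[0]
        half = v[t > 500].mean() / 2
        t_half = t[np.argmax(v > half)]
        assert t_half == pytest.approx(300.0 + kernel_e.d_ms, abs=1.0)

    def test_population_kernel_amplitude(self, kernel_e):
        amp, sigma, d = population_kernel(kernel_e, "soma")
        assert amp == pytest.approx(kernel_e.A0("soma") * disk_average_factor())
        assert sigma == kernel_e.sigma_ms and d == kernel_e.d_ms


class TestSpikeRateEquivalence:
    def test_poisson_population_matches_rate_prediction(self, kernel_e, kernel_i):
        """Spike-based LFP of a large Poisson population agrees with the
        rate-based (disk-averaged kernel) prediction within Monte-Carlo error.

        The population kernel averages the radial decay over a disk of radius
        ``2 lambda`` around the electrode, so the comparison population is
        distributed uniformly over that disk (on a square sheet the remoter
        neurons make the true average smaller than the disk factor).
        """
        n_e, n_i, rate_e, rate_i, T = 4000, 1000, 8.0, 16.0, 4000.0
        rec = make_poisson_fixture(n_e, n_i, (rate_e, rate_i), T, seed=77)
        rng = np.random.default_rng(123)
        R = 2 * kernel_e.lambda_um * 1e-3  # mm
        r = R * np.sqrt(rng.random(rec.n_neurons))
        th = 2 * np.pi * rng.random(rec.n_neurons)
        rec.positions_mm = np.column_stack([r * np.cos(th), r * np.sin(th)])
        t = np.arange(0.0, T, 1.0)
        el = [ElectrodeSpec(0.0, 0.0, "surface")]
        spike_lfp = lfp_from_spikes(rec, el, kernel_e, kernel_i, t).V_uV[0]
        rate_lfp = lfp_from_rates(
            t, np.full_like(t, rate_e), np.full_like(t, rate_i),
            n_e, n_i, el, kernel_e, kernel_i,
        ).V_uV[0]
        # compare time-averaged levels away from burn-in
        sl = slice(200, -200)
        mean_spike = spike_lfp[sl].mean()
        mean_rate = rate_lfp[sl].mean()
        # Monte-Carlo SE of the time-averaged spike-based LFP
        se = spike_lfp[sl].std() / np.sqrt(T / 1000.0)  # ~independent per ~1 s
        assert abs(mean_spike - mean_rate) < 3 * max(se, 0.02 * abs(mean_rate))


class TestRateLfpField:
    def test_center_matches_lfp_from_rates_shape(self, kernel_e, kernel_i):
        t = np.arange(0.0, 500.0, 1.0)
        nu_e = np.where((t > 100) & (t < 300), 10.0, 0.0)
        field = rate_lfp_field(t, nu_e, np.zeros_like(t), 8000, 2000,
                               kernel_e, kernel_i)
        phi = field(np.array([0.5]), np.array([0.5]), 800.0, t)
        assert phi.shape == (1, t.size)
        # temporal profile proportional to the rate-based LFP at the center
        lfp = lfp_from_rates(t, nu_e, np.zeros_like(t), 8000, 2000,
                             [ElectrodeSpec(0.5, 0.5, "surface")],
                             kernel_e, kernel_i).V_uV[0]
        c = np.corrcoef(phi[0], lfp)[0, 1]
        assert c > 0.999

    def test_wrong_grid_raises(self, kernel_e, kernel_i):
        t = np.arange(0.0, 100.0, 1.0)
        field = rate_lfp_field(t, np.zeros_like(t), np.zeros_like(t), 10, 10,
                               kernel_e, kernel_i)
        with pytest.raises(ValueError, match="time grid"):
            field(np.array([0.5]), np.array([0.5]), 0.0, t[:-1])
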