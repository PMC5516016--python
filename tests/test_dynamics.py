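"""Bilinear neuronal dynamics and the balloon/Windkessel observation model."""

import numpy as np
import pytest

from visdcm.design import InputSeries
from visdcm.dynamics import (BatchedForward, effective_connectivity,
                             hemodynamic_bold, integrate_neuronal, is_stable,
                             neuronal_drift, simulate_bold, StateTrajectory)
from visdcm.network import DCMParams, HemoParams, NetworkSpec, params_to_vector


def single_node_spec():
    return NetworkSpec(nodes=("X",), inputs=("u",),
                       a_mask=np.ones((1, 1), bool),
                       b_masks={"u": np.zeros((1, 1), bool)},
                       c_mask=np.ones((1, 1), bool))


def two_node_spec():
    return NetworkSpec(nodes=("X", "Y"), inputs=("u",),
                       a_mask=np.ones((2, 2), bool),
                       b_masks={"u": np.zeros((2, 2), bool)},
                       c_mask=np.array([[True], [False]]))


class TestDrift:
    def test_rest_is_a_fixed_point(self, spec):
        p = DCMParams.zeros(spec)
        out = neuronal_drift(np.zeros(4), np.zeros(3), p)
        np.testing.assert_array_equal(out, np.zeros(4))

    def test_pure_self_decay(self, spec):
        p = DCMParams.zeros(spec)   # self_log = 0 -> diagonal -0.5 Hz
        e1 = np.eye(4)[0]
        np.testing.assert_allclose(neuronal_drift(e1, np.zeros(3), p), -0.5 * e1)

    def test_perception_modulation_totals_printed_coupling(self, spec):
        """Baseline 0.05 Hz plus 0.89 Hz modulation = 0.94 Hz OCC->IPS."""
        p = DCMParams.zeros(spec)
        occ, ips = spec.node_index("OCC"), spec.node_index("IPS")
        p.A[ips, occ] = 0.05
        p.B["perception"][ips, occ] = 0.89
        on = effective_connectivity(p, [1.0, 0.0, 0.0])
        off = effective_connectivity(p, [0.0, 0.0, 0.0])
        assert on[ips, occ] == pytest.approx(0.94)
        assert off[ips, occ] == pytest.approx(0.05)

    def test_baseline_diagonal_is_scaled_decay(self, spec):
        p = DCMParams.zeros(spec)
        p.self_log[:] = np.log(2.0)
        E = effective_connectivity(p, np.zeros(3))
        np.testing.assert_allclose(np.diag(E), -1.0)

    def test_dimension_mismatch_rejected(self, spec):
        p = DCMParams.zeros(spec)
        with pytest.raises(ValueError):
            neuronal_drift(np.zeros(3), np.zeros(3), p)
        with pytest.raises(ValueError):
            effective_connectivity(p, np.zeros(2))


class TestNeuronalIntegration:
    def test_zero_inputs_stay_at_rest(self, spec):
        p = DCMParams.zeros(spec)
        u = InputSeries(names=list(spec.inputs), u=np.zeros((200, 3)), dt=0.1)
        traj = integrate_neuronal(p, u)
        np.testing.assert_array_equal(traj.z, 0.0)

    def test_single_node_matches_closed_form(self):
        """dz/dt = a z + c u, constant u: z(t) = (c u / a)(e^{a t} - 1)."""
        sp = single_node_spec()
        p = DCMParams.zeros(sp)
        a, c = -0.5, 0.8   # a from the self-connection at self_log = 0
        p.C[0, 0] = c
        u = InputSeries(names=["u"], u=np.ones((500, 1)), dt=0.01)
        traj = integrate_neuronal(p, u)
        t = np.arange(500) * 0.01
        expected = (c / a) * (np.exp(a * t) - 1.0)
        np.testing.assert_allclose(traj.z[:, 0], expected, atol=1e-10)

    def test_two_node_matches_fine_euler(self):
        sp = two_node_spec()
        p = DCMParams.zeros(sp)
        p.A[1, 0] = 0.4
        p.C[0, 0] = 0.5
        n_bins = 60
        u_series = InputSeries(names=["u"],
                               u=(np.arange(n_bins) % 20 < 8)[:, None].astype(float),
                               dt=0.1)
        traj = integrate_neuronal(p, u_series)
        # brute-force Euler at dt = 1e-4
        fine = 1000
        z = np.zeros(2)
        zs = np.zeros((n_bins, 2))
        for k in range(n_bins):
            zs[k] = z
            E = effective_connectivity(p, u_series.u[k])
            cu = p.C @ u_series.u[k]
            for _ in range(fine):
                z = z + (E @ z + cu) * (0.1 / fine)
        scale = max(np.abs(zs).max(), 1.0)
        assert np.abs(traj.z - zs).max() / scale < 1e-3  # Euler's own error floor

    def test_exactness_under_step_refinement(self):
        """The propagator is exact for piecewise-constant input, so halving
        the bin width (holding the input pattern) reproduces the same states
        at shared times to machine precision."""
        sp = two_node_spec()
        p = DCMParams.zeros(sp)
        p.A[1, 0] = 0.3
        p.C[0, 0] = 0.5
        pattern = (np.arange(40) % 10 < 4).astype(float)
        coarse = InputSeries(names=["u"], u=pattern[:, None], dt=0.1)
        fine = InputSeries(names=["u"], u=np.repeat(pattern, 2)[:, None], dt=0.05)
        zc = integrate_neuronal(p, coarse).z
        zf = integrate_neuronal(p, fine).z
        np.testing.assert_allclose(zc, zf[::2], atol=1e-12)

    def test_linearity_in_driving_input(self):
        sp = two_node_spec()
        p = DCMParams.zeros(sp)
        p.A[1, 0] = 0.3
        p.C[0, 0] = 0.4
        u = InputSeries(names=["u"],
                        u=(np.arange(80) % 30 < 10)[:, None].astype(float), dt=0.1)
        z1 = integrate_neuronal(p, u).z
        p2 = p.copy()
        p2.C *= 2.0
        z2 = integrate_neuronal(p2, u).z
        np.testing.assert_allclose(z2, 2.0 * z1, atol=1e-12)

    def test_unstable_system_refused_in_strict_mode(self):
        sp = two_node_spec()
        p = DCMParams.zeros(sp)
        p.A[0, 1] = 2.0
        p.A[1, 0] = 2.0   # coupling overwhelms the -0.5 self-decay
        assert not is_stable(p)
        u = InputSeries(names=["u"], u=np.ones((50, 1)), dt=0.1)
        with pytest.raises(ValueError):
            integrate_neuronal(p, u, strict=True)
        with pytest.warns(RuntimeWarning):
            integrate_neuronal(p, u, strict=False)


class TestHemodynamics:
    def test_rest_gives_zero_bold(self):
        traj = StateTrajectory(z=np.zeros((300, 2)), dt=0.1)
        bold = hemodynamic_bold(traj, HemoParams.canonical(2))
        np.testing.assert_allclose(bold, 0.0, atol=1e-12)

    def test_burst_response_peaks_at_haemodynamic_delay(self):
        z = np.zeros((400, 1))
        z[10:20, 0] = 1.0   # 1 s neuronal burst at t = 1 s
        bold = hemodynamic_bold(StateTrajectory(z=z, dt=0.1), HemoParams.canonical(1))
        peak_t = np.argmax(bold[:, 0]) * 0.1
        burst_t = 1.5
        assert 3.0 <= peak_t - burst_t <= 7.0
        assert bold[:, 0].min() < 0  # post-peak undershoot

    def test_peak_amplitude_monotone_in_efficacy(self):
        z = np.zeros((300, 1))
        z[10:20, 0] = 1.0
        peaks = []
        for eff in (1.0, 0.5, 0.25):
            hemo = HemoParams.canonical(1)
            hemo.efficacy[:] = eff
            bold = hemodynamic_bold(StateTrajectory(z=z, dt=0.1), hemo)
            peaks.append(bold.max())
        assert peaks[0] > peaks[1] > peaks[2] > 0

    def test_nonphysical_parameters_rejected(self):
        hemo = HemoParams.canonical(1)
        hemo.transit[:] = -1.0
        with pytest.raises(ValueError):
            hemodynamic_bold(StateTrajectory(z=np.zeros((10, 1)), dt=0.1), hemo)


class TestSimulateBold:
    def _params(self, spec):
        p = DCMParams.zeros(spec)
        p.C[0, 0] = 0.4
        return p

    def test_deterministic_given_seed(self, spec, micro_inputs):
        _, inputs = micro_inputs
        p = self._params(spec)
        p.noise_sd = 0.5
        a = simulate_bold(spec, p, inputs, tr=2.0, seed=42)
        b = simulate_bold(spec, p, inputs, tr=2.0, seed=42)
        np.testing.assert_array_equal(a.y, b.y)
        c = simulate_bold(spec, p, inputs, tr=2.0, seed=43)
        assert np.any(a.y != c.y)

    def test_scan_count(self, spec):
        p = self._params(spec)
        inputs = InputSeries(names=list(spec.inputs), u=np.zeros((6000, 3)), dt=0.1)
        out = simulate_bold(spec, p, inputs, tr=2.0, seed=0)   # 600 s of data
        assert out.n_scans == 300

    def test_noise_sd_calibrated(self, spec):
        """Residual sd of simulated minus noiseless matches the requested sd."""
        p = self._params(spec)
        inputs = InputSeries(names=list(spec.inputs),
                             u=np.zeros((50000, 3)), dt=0.1)  # 2500 scans x 4 nodes
        clean = simulate_bold(spec, p, inputs, tr=2.0, seed=0)
        p.noise_sd = 0.7
        noisy = simulate_bold(spec, p, inputs, tr=2.0, seed=1)
        resid = noisy.y - clean.y
        assert resid.size >= 10_000
        assert abs(resid.std() - 0.7) / 0.7 < 0.05

    def test_tr_shorter_than_microtime_rejected(self, spec, micro_inputs):
        _, inputs = micro_inputs
        with pytest.raises(ValueError):
            simulate_bold(spec, self._params(spec), inputs, tr=0.01, seed=0)

    def test_slice_offset_shifts_sampling(self, spec, micro_inputs):
        _, inputs = micro_inputs
        p = self._params(spec)
        mid = simulate_bold(spec, p, inputs, tr=2.0, seed=0, slice_offset=0.5)
        start = simulate_bold(spec, p, inputs, tr=2.0, seed=0, slice_offset=0.0)
        assert np.any(mid.y != start.y)


class TestBatchedForward:
    def test_matches_unbatched_simulation(self, spec, micro_inputs):
        _, inputs = micro_inputs
        p = DCMParams.zeros(spec)
        p.C[0, 0] = 0.4
        p.A[2, 0] = 0.05
        fw = BatchedForward(spec, inputs, tr=2.0, slice_offset=0.5)
        theta = params_to_vector(p, spec)
        pred = fw.predict(theta[None])[0]
        ref = simulate_bold(spec, p, inputs, tr=2.0, seed=0)
        np.testing.assert_allclose(pred, ref.y, atol=1e-12)

    def test_batch_rows_are_independent(self, spec, micro_inputs):
        _, inputs = micro_inputs
        p = DCMParams.zeros(spec)
        p.C[0, 0] = 0.4
        fw = BatchedForward(spec, inputs, tr=2.0)
        t1 = params_to_vector(p, spec)
        p.C[0, 0] = 0.2
        t2 = params_to_vector(p, spec)
        batch = fw.predict(np.vstack([t1, t2]))
        np.testing.assert_allclose(batch[0], fw.predict(t1[None])[0], atol=1e-12)
        np.testing.assert_allclose(batch[1], fw.predict(t2[None])[0], atol=1e-12)
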