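"""Trace and burst generators plus the pressure-series ground truth."""

import numpy as np
import pytest

import hpfret as hp
from hpfret.scheme import BAR_TO_PA, CM3_TO_M3, R_GAS
from hpfret.simulate import DONOR_ONLY, BURST_FLOOR


class TestRenderTrace:
    def test_zero_brightness_zero_background_is_all_zero(self, neat_scheme):
        cfg = hp.AcquisitionConfig(
            brightness=0.0, background_d=0.0, background_a=0.0,
            contaminant_fractions=(0, 0),
        )
        traj = hp.simulate_state_path(neat_scheme, 1.0, seed=0)
        trace = hp.render_trace(traj, neat_scheme, cfg, seed=0)
        assert trace.donor.sum() == 0 and trace.acceptor.sum() == 0

    def test_bright_single_state_recovers_e_mean(self):
        # E estimator on noiseless emission: nA/(nA+nD) -> 0.80 at gamma 1.
        scheme = hp.KineticScheme(
            states=(hp.StateSpec("closed", 0.8, 0.0),), rates=np.zeros((1, 1))
        )
        cfg = hp.AcquisitionConfig(
            brightness=1e4, background_d=0.0, background_a=0.0, gamma=1.0,
            contaminant_fractions=(0, 0),
        )
        traj = hp.simulate_state_path(scheme, 1.0, seed=1)
        trace = hp.render_trace(traj, scheme, cfg, seed=1)
        e = trace.acceptor / (trace.acceptor + trace.donor)
        assert abs(e.mean() - 0.80) < 0.01

    @pytest.mark.parametrize("gamma", [0.7, 0.88, 1.0, 1.3])
    def test_gamma_corrected_estimator_recovers_e(self, gamma):
        # The estimator E = nA/(nA + gamma nD) undoes the gamma distortion
        # applied to the donor channel, for any gamma.
        scheme = hp.KineticScheme(
            states=(hp.StateSpec("s", 0.6, 0.0),), rates=np.zeros((1, 1))
        )
        cfg = hp.AcquisitionConfig(
            brightness=5e3, background_d=0.0, background_a=0.0, gamma=gamma,
            contaminant_fractions=(0, 0),
        )
        traj = hp.simulate_state_path(scheme, 0.5, seed=2)
        trace = hp.render_trace(traj, scheme, cfg, seed=2)
        e = trace.acceptor / (trace.acceptor + gamma * trace.donor)
        assert abs(e.mean() - 0.6) < 0.01

    def test_seed_determinism(self, neat_scheme, quiet_acq):
        traj = hp.simulate_state_path(neat_scheme, 2.0, seed=5)
        t1 = hp.render_trace(traj, neat_scheme, quiet_acq, seed=9)
        t2 = hp.render_trace(traj, neat_scheme, quiet_acq, seed=9)
        np.testing.assert_array_equal(t1.donor, t2.donor)
        np.testing.assert_array_equal(t1.acceptor, t2.acceptor)


class TestSimulateBursts:
    def test_single_state_bursts_cluster_at_state_e(self, quiet_acq):
        scheme = hp.KineticScheme(
            states=(hp.StateSpec("closed", 0.8, 0.02),), rates=np.zeros((1, 1))
        )
        bursts = hp.simulate_bursts([1.0], scheme, 2000, 200.0, quiet_acq, seed=3)
        e = bursts.n_a / (bursts.n_a + quiet_acq.gamma * bursts.n_d)
        assert abs(np.median(e) - 0.8) < 0.02

    def test_burst_sizes_respect_detection_floor(self, symmetric_bursts):
        dual = symmetric_bursts.true_state >= 0
        totals = symmetric_bursts.n_a[dual] + np.rint(
            symmetric_bursts.n_d[dual] * symmetric_bursts.gamma
        )
        assert totals.min() >= BURST_FLOOR - 1  # gamma rounding slack

    def test_equal_weights_give_half_closed_fraction(self, symmetric_bursts):
        hist = hp.filter_and_histogram(symmetric_bursts)
        fit = hp.fit_mixture(hist, 2, seed=0)
        fr = hp.assign_and_fractions(fit)
        assert abs(fr.f_closed - 0.50) < 0.02

    def test_empty_weights_raise(self, neat_scheme, quiet_acq):
        with pytest.raises(ValueError, match="no populated states"):
            hp.simulate_bursts([0.0, 0.0], neat_scheme, 10, 100.0, quiet_acq, seed=0)

    def test_contaminants_are_labeled_and_injected(self, neat_scheme):
        cfg = hp.AcquisitionConfig(contaminant_fractions=(0.2, 0.1))
        bursts = hp.simulate_bursts(
            [0.5, 0.5], neat_scheme, 5000, 100.0, cfg, seed=4
        )
        f_donly = np.mean(bursts.true_state == DONOR_ONLY)
        assert abs(f_donly - 0.2) < 0.02


class TestPressureSeries:
    def test_reference_pressure_reproduces_keq_ref(self):
        truth = hp.ThermoGroundTruth(delta_v=-17.7, keq_ref=0.42)
        (p, fo, fc), *_ = hp.pressure_series(truth, [1.0])
        assert fo / fc == pytest.approx(0.42, abs=1e-12)

    def test_keq_pressure_ratio_closed_form(self):
        # dV = -17.7 cm3/mol over 1000 bar at 298.15 K: ratio exp(0.714) = 2.04
        truth = hp.ThermoGroundTruth(delta_v=-17.7, keq_ref=1.0)
        ratio = truth.keq(1001.0) / truth.keq(1.0)
        expected = np.exp(17.7 * CM3_TO_M3 * 1000 * BAR_TO_PA / (R_GAS * 298.15))
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert ratio == pytest.approx(2.04, abs=0.01)

    def test_zero_delta_v_is_pressure_independent(self):
        truth = hp.ThermoGroundTruth(delta_v=0.0, keq_ref=0.7)
        pts = hp.pressure_series(truth, [1, 500, 1000, 2000])
        assert all(pt.f_open == pts[0].f_open for pt in pts)

    def test_log_linearity_is_exact(self):
        # Regressing ln Keq on p returns the input dV to machine precision.
        truth = hp.ThermoGroundTruth(delta_v=-29.5, keq_ref=0.42)
        pressures = [1, 200, 400, 600, 800, 1000]
        pts = [
            hp.pressure_point(p, hp.StateFractions(fo, fc))
            for p, fo, fc in hp.pressure_series(truth, pressures)
        ]
        vfit = hp.fit_volume(pts, temperature=truth.temperature)
        assert vfit.delta_v == pytest.approx(-29.5, abs=1e-9)

    def test_sub_ambient_pressure_rejected(self):
        truth = hp.ThermoGroundTruth(delta_v=-17.7, keq_ref=0.42)
        with pytest.raises(ValueError, match=">= 1 bar"):
            hp.pressure_series(truth, [0.5])
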