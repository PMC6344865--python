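"""HMM idealization, dwell-time extraction and rate-constant estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hpfret as hp
from hpfret.kinetics import DwellSet, _runs


def _series(e, bw=1e-3):
    return hp.FretSeries(e=np.asarray(e, float), bin_width=bw)


class TestFretSeries:
    def test_constant_counts_give_printed_estimator_value(self):
        trace = hp.BinnedDualTrace(
            bin_width=1e-3,
            donor=np.full(100, 20), acceptor=np.full(100, 80),
            acceptor_direct=np.zeros(100, int),
        )
        s = hp.fret_series(trace, gamma=0.88)
        assert np.allclose(s.e, 80 / (80 + 0.88 * 20))  # 0.8197

    def test_gamma_one_balanced_counts_give_half(self):
        trace = hp.BinnedDualTrace(
            bin_width=1e-3,
            donor=np.full(50, 30), acceptor=np.full(50, 30),
            acceptor_direct=np.zeros(50, int),
        )
        assert np.allclose(hp.fret_series(trace, gamma=1.0).e, 0.5)

    def test_zero_bins_carry_previous_value_and_flag(self):
        donor = np.full(20, 10)
        donor[5] = 0
        acceptor = np.full(20, 30)
        acceptor[5] = 0
        trace = hp.BinnedDualTrace(
            bin_width=1e-3, donor=donor, acceptor=acceptor,
            acceptor_direct=np.zeros(20, int),
        )
        s = hp.fret_series(trace, gamma=1.0)
        assert s.e[5] == s.e[4]
        assert s.flagged[5] and not s.flagged[4]

    def test_dim_trace_rejected(self):
        donor = np.zeros(100, int)
        donor[:70] = 10
        trace = hp.BinnedDualTrace(
            bin_width=1e-3, donor=donor, acceptor=np.zeros(100, int),
            acceptor_direct=np.zeros(100, int),
        )
        with pytest.raises(ValueError, match="too dim"):
            hp.fret_series(trace)


class TestFitHmm:
    def test_noiseless_two_level_series_is_exact(self):
        e = np.tile([0.2] * 25 + [0.8] * 25, 40)
        model = hp.fit_hmm(_series(e), k_range=(1, 2, 3), seed=0)
        assert model.k == 2
        np.testing.assert_allclose(model.means, [0.2, 0.8], atol=1e-6)

    def test_bic_never_overfits_noiseless_data(self):
        e = np.tile([0.2] * 10 + [0.8] * 15, 80)
        model = hp.fit_hmm(_series(e), k_range=(1, 2, 3, 4), seed=1)
        assert model.k == 2

    def test_two_state_recovery_with_noise(self, neat_scheme, quiet_acq):
        cfg = hp.AcquisitionConfig(
            brightness=500, background_d=2, background_a=2,
            contaminant_fractions=(0, 0),
        )
        series = []
        for i in range(6):
            traj = hp.simulate_state_path(neat_scheme, 60.0, seed=50 + i)
            trace = hp.render_trace(traj, neat_scheme, cfg, seed=150 + i)
            series.append(hp.fret_series(trace))
        model = hp.fit_hmm(series, seed=0)
        assert model.k == 2
        np.testing.assert_allclose(model.means, [0.3, 0.8], atol=0.02)

    def test_agrees_with_hmmlearn_reference(self):
        # Independent cross-check of the Baum-Welch implementation.
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        trans = np.array([[0.97, 0.03], [0.05, 0.95]])
        means = np.array([0.25, 0.75])
        path = [0]
        for _ in range(20_000 - 1):
            path.append(rng.choice(2, p=trans[path[-1]]))
        path = np.array(path)
        e = rng.normal(means[path], 0.07)
        model = hp.fit_hmm(_series(e), k_range=(2,), seed=0)
        ref = hmmlearn.GaussianHMM(
            n_components=2, covariance_type="diag", n_iter=100, random_state=0
        )
        ref.fit(e.reshape(-1, 1))
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(model.means, ref.means_.ravel()[order], atol=0.01)
        np.testing.assert_allclose(
            model.trans, ref.transmat_[np.ix_(order, order)], atol=0.01
        )


class TestViterbiDwells:
    @pytest.fixture()
    def crisp_model(self):
        return hp.StateModel(
            k=2, means=np.array([0.2, 0.8]), sds=np.array([0.05, 0.05]),
            trans=np.array([[0.99, 0.01], [0.01, 0.99]]),
            initial=np.array([0.5, 0.5]),
            log_likelihood=0.0, bic=0.0, n_obs=6,
        )

    def test_interior_dwell_and_censoring_flags(self, crisp_model):
        # Path O,O,O,C,C,O: one interior closed dwell of 2 ms, both open
        # runs censored.
        s = _series([0.2, 0.2, 0.2, 0.8, 0.8, 0.2, 0.2, 0.2, 0.2, 0.2])
        dwells = hp.viterbi_dwells(crisp_model, s)
        assert list(dwells.uncensored(1)) == [pytest.approx(2e-3)]
        assert dwells.censored[0].all()  # both open runs touch the edges
        assert dwells.transitions[0, 1] == 1 and dwells.transitions[1, 0] == 1

    def test_single_state_model_yields_no_transitions(self):
        model = hp.StateModel(
            k=1, means=np.array([0.5]), sds=np.array([0.1]),
            trans=np.ones((1, 1)), initial=np.ones(1),
            log_likelihood=0.0, bic=0.0, n_obs=10,
        )
        dwells = hp.viterbi_dwells(model, _series([0.5] * 20))
        assert dwells.transitions.sum() == 0
        assert len(dwells.durations[0]) == 1 and dwells.censored[0][0]

    def test_decoding_accuracy_on_rendered_traces(self, neat_scheme):
        cfg = hp.AcquisitionConfig(
            brightness=500, background_d=2, background_a=2,
            contaminant_fractions=(0, 0),
        )
        traj = hp.simulate_state_path(neat_scheme, 60.0, seed=21)
        trace = hp.render_trace(traj, neat_scheme, cfg, seed=22)
        s = hp.fret_series(trace)
        model = hp.fit_hmm(s, k_range=(2,), seed=0)
        path = hp.viterbi_path(model, s)
        true_path = np.argmax(traj.bin_occupancy(1e-3, 2), axis=1)
        accuracy = np.mean(path == true_path)
        assert accuracy > 0.95

    def test_run_length_encoding(self):
        states, lengths = _runs(np.array([0, 0, 1, 1, 1, 0]))
        np.testing.assert_array_equal(states, [0, 1, 0])
        np.testing.assert_array_equal(lengths, [2, 3, 1])


class TestCumulativeExponentialFit:
    def test_recovers_exponential_mean(self, rng):
        dwells = rng.exponential(0.100, 2000)
        tau, tau_se = hp.cumulative_exponential_fit(dwells)
        assert tau == pytest.approx(0.100, abs=0.005)
        assert tau_se > 0

    def test_identical_dwells_flagged_nonexponential(self):
        with pytest.warns(UserWarning, match="not be exponential"):
            hp.cumulative_exponential_fit(np.full(50, 0.1))

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError, match="insufficient events"):
            hp.cumulative_exponential_fit(np.array([0.1] * 3))

    def test_censoring_removal_restores_exponential_mean(self, neat_scheme):
        # The last run of every trace is truncated by the window, so the
        # all-dwell mean underestimates 1/k; the uncensored subset does not.
        kf = 7.5
        all_d, unc_d = [], []
        for seed in range(60):
            traj = hp.simulate_state_path(neat_scheme, 20.0, seed=seed)
            dw = traj.dwell_times()
            states = traj.states
            interior = np.zeros(len(dw), bool)
            interior[1:-1] = True
            all_d.extend(dw[states == 0])
            unc_d.extend(dw[(states == 0) & interior])
        assert len(unc_d) > 2000
        assert abs(np.mean(unc_d) - 1 / kf) < 0.05 / kf
        # With a window comparable to the mean dwell, keeping the truncated
        # edge runs biases the estimate well below 1/k.
        short = []
        for seed in range(2000):
            traj = hp.simulate_state_path(neat_scheme, 0.2, seed=seed)
            short.extend(traj.dwell_times()[traj.states == 0])
        assert np.mean(short) < 0.8 / kf


class TestViscosityCorrect:
    def test_rate_and_dwell_directions(self):
        # 4 M TMAO: k = 5.9 1/s at eta = 3.50 mPa s -> 23.2 1/s corrected;
        # 2 M TMAO: t1 = 69.8 ms at eta = 1.65 -> 37.6 ms.
        assert hp.viscosity_correct(5.9, 3.50, 0.89, "rate") == pytest.approx(
            23.2, abs=0.05
        )
        assert hp.viscosity_correct(69.8, 1.65, 0.89, "dwell") == pytest.approx(
            37.6, abs=0.05
        )

    def test_matched_viscosity_is_identity(self):
        assert hp.viscosity_correct(7.5, 0.89, 0.89, "rate") == 7.5

    @settings(max_examples=50, deadline=None)
    @given(
        k=st.floats(0.01, 100),
        eta_s=st.floats(0.1, 10),
        eta_b=st.floats(0.1, 10),
    )
    def test_product_k_tau_is_invariant(self, k, eta_s, eta_b):
        tau = 1.0 / k
        k_corr = hp.viscosity_correct(k, eta_s, eta_b, "rate")
        tau_corr = hp.viscosity_correct(tau, eta_s, eta_b, "dwell")
        assert k_corr * tau_corr == pytest.approx(k * tau, rel=1e-12)


class TestRatesFromDwells:
    def _dwellset(self, rng, taus):
        durations = [rng.exponential(t, 500) for t in taus]
        n = len(taus)
        transitions = np.full((n, n), 100, int)
        np.fill_diagonal(transitions, 0)  # runs alternate, never self-transit
        return DwellSet(
            durations=durations,
            censored=[np.zeros(500, bool) for _ in taus],
            transitions=transitions,
            bin_width=1e-3,
        )

    def test_two_state_labels_map_to_folding_and_unfolding(self, rng):
        ds = self._dwellset(rng, [1 / 7.5, 1 / 3.13])
        rt = hp.rates_from_dwells(ds, ("open", "closed"))
        assert rt.rate("open") == pytest.approx(7.5, rel=0.1)
        assert rt.rate("closed") == pytest.approx(3.13, rel=0.1)

    def test_viscosity_columns_obey_ratio(self, rng):
        ds = self._dwellset(rng, [0.1, 0.3])
        rt = hp.rates_from_dwells(ds, ("open", "closed"), eta_sample=1.65)
        ratio = rt.rate_corr("open") / rt.rate("open")
        assert ratio == pytest.approx(1.65 / 0.89, rel=1e-9)

    def test_transition_breakdown_sums_to_exit_rate(self, rng):
        ds = self._dwellset(rng, [0.1, 0.05, 0.08])
        rt = hp.rates_from_dwells(ds, ("state1", "state2", "state3"))
        for label in ("state1", "state2", "state3"):
            k_split = rt.transition_rates.query("`from` == @label")["k_per_s"].sum()
            assert k_split == pytest.approx(rt.rate(label), rel=1e-9)

    def test_unlabeled_state_rejected(self, rng):
        ds = self._dwellset(rng, [0.1, 0.3])
        with pytest.raises(ValueError, match="every state"):
            hp.rates_from_dwells(ds, ("open",))
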