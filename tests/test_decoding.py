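"""Decoder tests: trial extraction, accuracy contracts, controls, cell types."""

import numpy as np
import pytest

from striadec import decoding
from striadec.events import ActionEvent


def _cfg(**kw):
    base = dict(n_repeats=10, n_subfolds=5, regularization_grid=(0.1, 1.0, 10.0),
                seed=0)
    base.update(kw)
    return decoding.DecoderConfig(**base)


def make_trials(rng, n_per=40, n_neurons=30, separation=0.0, n_informative=6):
    """Gaussian trial vectors; the first ``n_informative`` neurons separate."""
    X = rng.normal(0, 1, (2 * n_per, n_neurons))
    y = np.array(["push"] * n_per + ["pull"] * n_per)
    X[:n_per, :n_informative] += separation
    return decoding.TrialMatrix(vectors=X, labels=y, lag_s=0.0, alignment="peak",
                                neuron_ids=np.arange(n_neurons))


def frame_events(times, identities):
    return [ActionEvent(identity=i, onset_s=t - 0.2, offset_s=t + 0.2,
                        cross3g_s=t - 0.1, peak_s=t, peak_force_g=7.0,
                        is_task_action=True, pre_isolated=True, post_isolated=True)
            for t, i in zip(times, identities)]


class TestExtractTrialVectors:
    frame_times = np.arange(300) / 30.0

    def test_constant_activity_gives_identical_vectors(self):
        dff = np.full((5, 300), 2.0)
        tm = decoding.extract_trial_vectors(dff, self.frame_times,
                                            frame_events([3.0, 5.0], ["push", "pull"]),
                                            lag_s=0.0)
        np.testing.assert_allclose(tm.vectors, 2.0)

    def test_impulse_at_peak_frame_average(self):
        dff = np.zeros((1, 300))
        dff[0, 90] = 1.0  # impulse exactly at the 3.0 s peak frame
        tm = decoding.extract_trial_vectors(dff, self.frame_times,
                                            frame_events([3.0], ["push"]), lag_s=0.0)
        assert tm.vectors[0, 0] == pytest.approx(1 / 5)

    def test_single_frame_window(self):
        dff = np.zeros((1, 300))
        dff[0, 90] = 1.0
        tm = decoding.extract_trial_vectors(dff, self.frame_times,
                                            frame_events([3.0], ["push"]),
                                            lag_s=0.0, window_frames=1)
        assert tm.vectors[0, 0] == pytest.approx(1.0)

    def test_out_of_session_trials_dropped(self):
        dff = np.zeros((1, 300))
        tm = decoding.extract_trial_vectors(
            dff, self.frame_times,
            frame_events([0.01, 5.0], ["push", "pull"]), lag_s=0.0)
        assert tm.vectors.shape[0] == 1
        with pytest.raises(ValueError):
            decoding.extract_trial_vectors(dff, self.frame_times,
                                           frame_events([0.01], ["push"]), lag_s=0.0)


class TestFitActionDecoder:
    def test_perfectly_separable_reaches_full_accuracy(self):
        # one neuron active only on push trials, the rest near-silent
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.1, (80, 10))
        X[:40, 0] += 5.0
        trials = decoding.TrialMatrix(X, np.array(["push"] * 40 + ["pull"] * 40),
                                      0.0, "peak", np.arange(10))
        dec = decoding.fit_action_decoder(trials, _cfg())
        assert dec.accuracy_mean == pytest.approx(1.0)
        # the push-active neuron carries the largest positive weight
        assert np.argmax(dec.weights) == 0

    def test_pure_noise_accuracy_at_chance(self):
        rng = np.random.default_rng(1)
        trials = make_trials(rng, separation=0.0)
        dec = decoding.fit_action_decoder(trials, _cfg())
        lo, hi = decoding.binomial_band(trials.vectors.shape[0], 0.95)
        assert lo <= dec.accuracy_mean <= hi

    def test_shuffle_control_at_chance_despite_signal(self):
        rng = np.random.default_rng(2)
        trials = make_trials(rng, separation=3.0)
        dec = decoding.fit_action_decoder(trials, _cfg(), shuffle=True)
        lo, hi = decoding.binomial_band(trials.vectors.shape[0], 0.99)
        assert lo <= dec.accuracy_mean <= hi

    def test_too_few_trials_raises(self):
        rng = np.random.default_rng(3)
        trials = make_trials(rng, n_per=40)
        trials.vectors = trials.vectors[25:]
        trials.labels = trials.labels[25:]  # 15 push / 40 pull
        with pytest.raises(ValueError, match="trials per action"):
            decoding.fit_action_decoder(trials, _cfg())

    def test_single_class_raises(self):
        rng = np.random.default_rng(4)
        trials = make_trials(rng)
        trials.labels = np.array(["push"] * trials.labels.size)
        with pytest.raises(ValueError):
            decoding.fit_action_decoder(trials, _cfg())

    def test_per_action_accuracies_average_to_overall(self):
        rng = np.random.default_rng(5)
        trials = make_trials(rng, separation=1.0)
        dec = decoding.fit_action_decoder(trials, _cfg())
        weighted = sum(dec.accuracy_per_action[c] * dec.test_counts_per_action[c]
                       for c in dec.accuracy_per_action)
        total = sum(dec.test_counts_per_action.values())
        assert weighted / total == pytest.approx(dec.accuracy_mean, abs=1e-9)

    def test_accuracy_invariant_to_neuron_order_and_affine_rescale(self):
        rng = np.random.default_rng(6)
        trials = make_trials(rng, separation=2.0)
        dec = decoding.fit_action_decoder(trials, _cfg())
        perm = np.random.default_rng(0).permutation(trials.vectors.shape[1])
        permuted = decoding.TrialMatrix(trials.vectors[:, perm], trials.labels,
                                        0.0, "peak", trials.neuron_ids[perm])
        dec_p = decoding.fit_action_decoder(permuted, _cfg())
        assert dec_p.accuracy_mean == pytest.approx(dec.accuracy_mean, abs=0.02)
        scaled = decoding.TrialMatrix(trials.vectors * 2.0 + 1.0, trials.labels,
                                      0.0, "peak", trials.neuron_ids)
        dec_s = decoding.fit_action_decoder(scaled, _cfg())
        assert dec_s.accuracy_mean == pytest.approx(dec.accuracy_mean, abs=0.02)

    def test_weights_oriented_push_positive(self):
        rng = np.random.default_rng(7)
        trials = make_trials(rng, separation=4.0, n_informative=3)
        dec = decoding.fit_action_decoder(trials, _cfg())
        assert dec.weights[:3].mean() > 0  # push-active neurons weigh positive

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        trials = make_trials(rng, separation=1.0)
        a = decoding.fit_action_decoder(trials, _cfg())
        b = decoding.fit_action_decoder(trials, _cfg())
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.accuracy_mean == b.accuracy_mean


class TestDecodeTimeCourse:
    def test_missing_lags_reported_not_fabricated(self):
        rng = np.random.default_rng(9)
        dff = rng.normal(0, 1, (12, 600))
        frame_times = np.arange(600) / 30.0
        evs = frame_events(np.linspace(2, 18, 30), ["push", "pull"] * 15)
        out = decoding.decode_time_course(dff, frame_times, evs, lags=[0.0],
                                          config=_cfg(min_trials_per_class=10),
                                          with_shuffle=False)
        assert out[0.0]["accuracy"] is not None
        out2 = decoding.decode_time_course(dff, frame_times, evs, lags=[0.0],
                                           config=_cfg(), with_shuffle=False)
        assert out2[0.0]["accuracy"] is None  # <20 per class: missing, no value

    def test_requires_isolation_flags(self):
        evs = frame_events([2.0], ["push"])
        evs[0].pre_isolated = None
        with pytest.raises(ValueError, match="isolation"):
            decoding.decode_time_course(np.zeros((12, 600)), np.arange(600) / 30.0,
                                        evs, lags=[0.0], config=_cfg())


class TestMatchedCelltype:
    def test_equal_counts_use_all_neurons(self):
        rng = np.random.default_rng(10)
        trials = make_trials(rng, n_neurons=24, separation=2.0, n_informative=24)
        labels = np.array(["D1", "D2"] * 12)
        out = decoding.matched_celltype_decoding(trials, labels, _cfg(n_repeats=5))
        assert out["D1"]["n_neurons_used"] == 12
        assert out["D2"]["n_neurons_used"] == 12

    def test_information_in_one_celltype_only(self):
        rng = np.random.default_rng(11)
        trials = make_trials(rng, n_neurons=30, separation=3.0, n_informative=10)
        labels = np.array(["D1"] * 10 + ["D2"] * 20)  # signal in D1 neurons only
        out = decoding.matched_celltype_decoding(trials, labels, _cfg(n_repeats=8))
        assert out["D1"]["accuracy_mean"] > out["D2"]["accuracy_mean"] + 0.2

    def test_symmetric_information_gives_similar_accuracy(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (80, 20))
        X[:40, :5] += 2.0   # D1 half of the signal
        X[:40, 10:15] += 2.0  # D2 half of the signal
        trials = decoding.TrialMatrix(X, np.array(["push"] * 40 + ["pull"] * 40),
                                      0.0, "peak", np.arange(20))
        labels = np.array(["D1"] * 10 + ["D2"] * 10)
        out = decoding.matched_celltype_decoding(trials, labels, _cfg(n_repeats=8))
        assert abs(out["D1"]["accuracy_mean"] - out["D2"]["accuracy_mean"]) < 0.15

    def test_absent_celltype_raises(self):
        rng = np.random.default_rng(13)
        trials = make_trials(rng)
        with pytest.raises(ValueError):
            decoding.matched_celltype_decoding(trials, np.array(["D1"] * 30), _cfg())
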