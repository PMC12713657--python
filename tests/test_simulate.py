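"""Generator tests: determinism, planted-event recovery, task rules."""

import dataclasses

import numpy as np
import pytest

from striadec import events, simulate
from striadec.geometry import EnsembleSelection


def small_config(**kw):
    base = dict(duration_s=120.0, n_neurons=20, n_push_exec=4, n_pull_exec=4,
                action_rate_per_min=4.0, seed=0)
    base.update(kw)
    return simulate.SimConfig(**base)


class TestBehaviorSession:
    def test_zero_rate_gives_pure_baseline(self):
        session, truth = simulate.simulate_behavior_session(
            small_config(action_rate_per_min=0.0))
        assert truth.planted_events == []
        assert np.abs(session.force).max() < 3.0
        assert session.force.std() <= 0.5

    def test_identical_seeds_identical_sessions(self):
        cfg = small_config()
        s1, t1 = simulate.simulate_behavior_session(cfg, seed=7)
        s2, t2 = simulate.simulate_behavior_session(cfg, seed=7)
        np.testing.assert_array_equal(s1.force, s2.force)
        np.testing.assert_array_equal(s1.emg, s2.emg)
        np.testing.assert_array_equal(s1.lick_times, s2.lick_times)
        assert t1.planted_events == t2.planted_events
        assert t1.ensemble_membership == t2.ensemble_membership

    def test_planted_events_recovered_by_detector(self):
        cfg = small_config(duration_s=300.0, action_rate_per_min=4.0,
                           force_peak_range_g=(6.0, 12.0), seed=3)
        session, truth = simulate.simulate_behavior_session(cfg)
        detected = events.detect_3g_cross_actions(session.force, session.touch)
        assert len(detected) == len(truth.planted_events)
        for det, planted in zip(detected, truth.planted_events):
            assert det.identity == planted.identity
            assert abs(det.cross3g_s - planted.cross3g_s) <= 1e-3
            assert abs(det.peak_s - planted.peak_s) <= 1e-3
            assert det.peak_force_g == pytest.approx(planted.peak_force_g)

    def test_touch_leads_every_crossing(self):
        session, truth = simulate.simulate_behavior_session(small_config(seed=5))
        for ev in truth.planted_events:
            c = int(round(ev.cross3g_s * 1000))
            assert session.touch[c - 100:c].all()

    def test_lick_bouts_follow_events(self):
        session, truth = simulate.simulate_behavior_session(small_config(seed=6))
        assert len(session.lick_times) == 6 * len(truth.planted_events)
        first_bout = session.lick_times[:6]
        assert np.all(np.diff(first_bout) < 0.5)

    def test_overly_fast_rate_rejected(self):
        with pytest.raises(ValueError, match="too high"):
            simulate.simulate_behavior_session(small_config(action_rate_per_min=20.0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimConfig(n_neurons=4, n_push_exec=8).validate()
        with pytest.raises(ValueError):
            simulate.SimConfig(push_preference=1.5).validate()
        with pytest.raises(ValueError):
            simulate.SimConfig(n_push_prep=4, prep_lead_s=-0.1).validate()


class TestNeuralActivity:
    def test_identical_seeds_identical_fluorescence(self):
        cfg = small_config(seed=9)
        s, t = simulate.simulate_behavior_session(cfg)
        a = simulate.simulate_neural_activity(s, t, cfg)
        b = simulate.simulate_neural_activity(s, t, cfg)
        np.testing.assert_array_equal(a.fluorescence_raw, b.fluorescence_raw)
        np.testing.assert_array_equal(a.fluorescence_neuropil, b.fluorescence_neuropil)

    def test_exec_neurons_prefer_their_action(self):
        cfg = small_config(duration_s=300.0, exec_effect=2.0, seed=10)
        s, t = simulate.simulate_behavior_session(cfg)
        s = simulate.simulate_neural_activity(s, t, cfg)
        from striadec.signals import compute_dff

        dff = compute_dff(s.fluorescence_raw, s.fluorescence_neuropil).dff_z
        push_members = t.members("push-exec")

        def mean_at(identity):
            vals = []
            for ev in t.planted_events:
                if ev.identity != identity:
                    continue
                i = int(round(ev.peak_s * cfg.frame_rate))
                vals.append(dff[push_members, i - 2:i + 3].mean())
            return np.mean(vals)

        assert mean_at("push") > mean_at("pull") + 0.5

    def test_prep_neurons_lead_the_cross(self):
        cfg = small_config(duration_s=300.0, n_push_prep=4, n_pull_prep=4,
                           n_neurons=24, seed=11)
        s, t = simulate.simulate_behavior_session(cfg)
        s = simulate.simulate_neural_activity(s, t, cfg)
        from striadec.signals import compute_dff

        dff = compute_dff(s.fluorescence_raw, s.fluorescence_neuropil).dff_z
        prep = t.members("push-prep")
        lead = np.mean([t.timing_offsets[i] for i in prep])
        assert 0.1 < lead < 0.55  # leads tile around prep_lead_s = 0.3
        before, after = [], []
        for ev in t.planted_events:
            if ev.identity != "push":
                continue
            c = int(round(ev.cross3g_s * cfg.frame_rate))
            before.append(dff[prep, c - 11:c - 2].mean())
            after.append(dff[prep, c + 6:c + 15].mean())
        assert np.mean(before) > np.mean(after)


class TestStimSession:
    def _ensembles(self):
        return EnsembleSelection(push_members=np.arange(4),
                                 pull_members=np.arange(4, 8), k=4,
                                 ensemble_frac=1.0, member_weights={})

    def test_schedule_counts_and_order(self):
        session, truth = simulate.simulate_stim_session(
            small_config(n_neurons=12, n_push_exec=0, n_pull_exec=0),
            self._ensembles(), n_blocks=4, seed=1)
        log = session.stim_log
        assert len(log) == 24
        patterns = [r.pattern for r in log[:6]]
        assert patterns == ["none", "push", "none", "none", "pull", "none"]
        assert sum(r.pattern != "none" and r.trigger_identity == "push"
                   for r in log) == 4
        assert sum(r.pattern != "none" and r.trigger_identity == "pull"
                   for r in log) == 4
        assert sum(r.pattern == "none" for r in log) == 16

    def test_stim_onset_follows_cross_by_latency(self):
        session, _ = simulate.simulate_stim_session(
            small_config(n_neurons=12, n_push_exec=0, n_pull_exec=0),
            self._ensembles(), n_blocks=2, seed=2)
        for r in session.stim_log:
            if r.pattern != "none":
                assert r.stim_onset_s == pytest.approx(r.cross3g_s + 0.002)
            else:
                assert r.stim_onset_s is None

    def test_deterministic(self):
        cfg = small_config(n_neurons=12, n_push_exec=0, n_pull_exec=0,
                           stim_effect_g=1.5, stim_neural_effect=1.0)
        a, _ = simulate.simulate_stim_session(cfg, self._ensembles(), 2, seed=3)
        b, _ = simulate.simulate_stim_session(cfg, self._ensembles(), 2, seed=3)
        np.testing.assert_array_equal(a.force, b.force)
        np.testing.assert_array_equal(a.fluorescence_raw, b.fluorescence_raw)

    def test_out_of_range_ensembles_rejected(self):
        bad = EnsembleSelection(push_members=np.array([50]),
                                pull_members=np.array([2]), k=1,
                                ensemble_frac=1.0, member_weights={})
        with pytest.raises(ValueError, match="outside"):
            simulate.simulate_stim_session(small_config(n_neurons=12), bad, 2)


class TestAdaptivePolicy:
    @pytest.mark.parametrize("push,pull,expected", [
        (8, 2, (False, True)),   # push over 70%: push unrewarded
        (2, 8, (True, False)),
        (5, 5, (True, True)),
        (7, 3, (True, True)),    # exactly 0.70 is not "exceeded": both rewarded
    ])
    def test_window_proportions(self, push, pull, expected):
        history = ["push"] * push + ["pull"] * pull
        assert simulate.adaptive_reinforcement_policy(history) == expected

    def test_empty_history_reinforces_both(self):
        assert simulate.adaptive_reinforcement_policy([]) == (True, True)

    def test_overlong_history_rejected(self):
        with pytest.raises(ValueError):
            simulate.adaptive_reinforcement_policy(["push"] * 11)
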