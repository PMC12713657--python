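"""Event-detection tests, including brute-force per-sample reference scans."""

import math

import numpy as np
import pytest

from striadec import events


def brute_threshold_scan(force, threshold, min_duration_s, direction, fs=1000.0):
    """Independent per-sample reference scan for threshold events."""
    sign = 1.0 if direction == "push" else -1.0
    x = sign * np.asarray(force)
    min_samples = max(1, int(math.ceil(min_duration_s * fs)))
    out, start = [], None
    for i in range(len(x) + 1):
        above = i < len(x) and x[i] > threshold
        if above and start is None:
            start = i
        elif not above and start is not None:
            if i - start >= min_samples:
                seg = x[start:i]
                pk = start + int(np.argmax(seg))
                out.append((start, i, pk))
            start = None
    return out


def brute_3g_scan(force, touch, fs=1000.0, fr=30.0):
    """Independent frame-window reference scan for 3 g cross actions."""
    force = np.asarray(force)
    out = []
    n_frames = int(math.ceil(len(force) * fr / fs))
    edges = [int(math.floor(k * fs / fr)) for k in range(n_frames)] + [len(force)]
    for direction, sign in (("push", 1.0), ("pull", -1.0)):
        x = sign * force
        means = [np.mean(x[edges[k]:edges[k + 1]]) for k in range(n_frames)]
        k = 0
        while k < n_frames:
            if means[k] >= 3.0:
                j = k
                while j < n_frames and means[j] >= 3.0:
                    j += 1
                if j - k >= 2:
                    s0, s1 = edges[k], edges[j]
                    if np.max(x[s0:s1]) >= 3.0:
                        pk = s0 + int(np.argmax(x[s0:s1]))
                        cross = pk
                        while cross > 0 and x[cross - 1] >= 3.0:
                            cross -= 1
                        end = pk + 1
                        while end < len(force) and x[end] >= 3.0:
                            end += 1
                        lead = int(round(0.1 * fs))
                        if cross >= lead and all(touch[cross - lead:cross]):
                            out.append((direction, cross, end, pk))
                k = j
            else:
                k += 1
    return sorted(out, key=lambda e: e[1])


def random_trace(rng, duration_s=60.0, fs=1000.0):
    n = int(duration_s * fs)
    force = rng.normal(0, 0.3, n)
    from scipy.ndimage import gaussian_filter1d

    force = gaussian_filter1d(force, 30)
    touch = np.zeros(n, dtype=bool)
    for _ in range(rng.integers(3, 10)):
        t0 = rng.integers(1000, n - 2000)
        width = rng.integers(120, 700)
        peak = rng.uniform(2.0, 12.0) * rng.choice([-1.0, 1.0])
        tt = np.arange(width)
        force[t0:t0 + width] += peak * np.sin(np.pi * tt / width) ** 2
        if rng.random() < 0.85:  # most bumps have touch; some violate the lead
            touch[t0 - rng.integers(100, 400):t0 + width + 100] = True
    return force, touch


class TestThresholdDetector:
    def test_zero_force_gives_no_events(self):
        assert events.detect_threshold_actions(np.zeros(5000), 3.0, 0.05, "push") == []

    def test_constructed_bump_onset_and_duration(self):
        force = np.zeros(5000)
        force[2000:2120] = 6.5  # >6 g for 120 ms at t = 2.000 s
        out = events.detect_threshold_actions(force, 6.0, 0.05, "push")
        assert len(out) == 1
        assert out[0].onset_s == pytest.approx(2.000)
        assert out[0].peak_force_g == pytest.approx(6.5)
        assert out[0].is_6g

    def test_short_bump_rejected_by_duration_filter(self):
        force = np.zeros(5000)
        force[2000:2010] = 8.0  # 10 ms < 50 ms minimum
        assert events.detect_threshold_actions(force, 6.0, 0.05, "push") == []

    def test_nonfinite_raises(self):
        force = np.zeros(100)
        force[10] = np.nan
        with pytest.raises(ValueError):
            events.detect_threshold_actions(force, 3.0, 0.05, "push")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_scan_on_random_traces(self, seed):
        rng = np.random.default_rng(100 + seed)
        force, _ = random_trace(rng, duration_s=30.0)
        for direction in ("push", "pull"):
            got = events.detect_threshold_actions(force, 3.0, 0.066, direction)
            want = brute_threshold_scan(force, 3.0, 0.066, direction)
            assert [(round(e.onset_s * 1000), round(e.offset_s * 1000),
                     round(e.peak_s * 1000)) for e in got] == want


class TestCrossDetector:
    def make_bump(self, force, t0, width, peak, touch=None, lead=400):
        tt = np.arange(width)
        force[t0:t0 + width] += peak * np.sin(np.pi * tt / width) ** 2
        if touch is not None:
            touch[t0 - lead:t0 + width + 100] = True

    def test_touch_lead_violation_rejected(self):
        force = np.zeros(10000)
        touch = np.zeros(10000, dtype=bool)
        self.make_bump(force, 4000, 400, 8.0)
        cross = 4000 + np.flatnonzero(force[4000:] >= 3.0)[0]
        touch[cross - 50:cross + 600] = True  # touch begins only 50 ms before
        assert events.detect_3g_cross_actions(force, touch) == []
        touch[cross - 150:cross + 600] = True
        assert len(events.detect_3g_cross_actions(force, touch)) == 1

    def test_6g_flag_boundary(self):
        for peak, expect in ((6.5, True), (5.9, False)):
            force = np.zeros(10000)
            touch = np.zeros(10000, dtype=bool)
            self.make_bump(force, 4000, 500, peak, touch)
            out = events.detect_3g_cross_actions(force, touch)
            assert len(out) == 1 and out[0].is_6g is expect

    def test_missing_touch_raises(self):
        with pytest.raises(ValueError):
            events.detect_3g_cross_actions(np.zeros(1000), None)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_frame_scan(self, seed):
        rng = np.random.default_rng(200 + seed)
        force, touch = random_trace(rng, duration_s=30.0)
        got = events.detect_3g_cross_actions(force, touch)
        want = brute_3g_scan(force, touch)
        assert [(e.identity, round(e.cross3g_s * 1000),
                 round(e.offset_s * 1000), round(e.peak_s * 1000))
                for e in got] == want


class TestIsolation:
    def _mk(self, t, ident="push"):
        return events.ActionEvent(identity=ident, onset_s=t - 0.1, offset_s=t + 0.1,
                                  cross3g_s=t - 0.05, peak_s=t, peak_force_g=8.0,
                                  is_task_action=True)

    def test_lone_event_is_isolated_both_ways(self):
        out = events.flag_isolation([self._mk(1.0)])
        assert out[0].pre_isolated and out[0].post_isolated

    def test_three_event_pattern(self):
        out = events.flag_isolation([self._mk(1.0), self._mk(1.3), self._mk(2.5)])
        flags = [(e.pre_isolated, e.post_isolated) for e in out]
        assert flags == [(True, False), (False, True), (True, True)]

    def test_zero_window_flags_everything(self):
        out = events.flag_isolation([self._mk(1.0), self._mk(1.01)], window_s=0.0)
        assert all(e.pre_isolated and e.post_isolated for e in out)

    def test_idempotent_and_order_independent(self):
        evs = [self._mk(t) for t in (0.8, 1.2, 3.0, 3.3)]
        once = events.flag_isolation(evs)
        twice = events.flag_isolation(once)
        assert [(e.pre_isolated, e.post_isolated) for e in once] == \
            [(e.pre_isolated, e.post_isolated) for e in twice]
        rev = events.flag_isolation(evs[::-1])
        assert {e.peak_s: (e.pre_isolated, e.post_isolated) for e in rev} == \
            {e.peak_s: (e.pre_isolated, e.post_isolated) for e in once}

    def test_cross_reference_option(self):
        out = events.flag_isolation([self._mk(1.0), self._mk(1.3)], reference="cross")
        assert out[0].pre_isolated and not out[0].post_isolated


class TestTouchAndLicks:
    def test_low_force_contact_is_touch_event(self):
        touch = np.zeros(5000, dtype=bool)
        touch[1000:3100] = True
        force = np.full(5000, 0.5)
        out = events.detect_touch_and_lick_events(touch, force, [], [])
        assert len(out) == 1 and out[0].identity == "touch"
        assert out[0].peak_s == pytest.approx(2.05, abs=0.01)  # midpoint

    def test_high_force_contact_rejected(self):
        touch = np.zeros(5000, dtype=bool)
        touch[1000:3100] = True
        force = np.full(5000, 2.5)
        assert events.detect_touch_and_lick_events(touch, force, [], []) == []

    def test_lick_bout_count_threshold(self):
        force = np.zeros(5000)
        touch = np.zeros(5000, dtype=bool)
        four = [1.0, 1.2, 1.4, 1.6]
        assert events.detect_touch_and_lick_events(touch, force, four, []) == []
        five = four + [1.8]
        out = events.detect_touch_and_lick_events(touch, force, five, [])
        assert len(out) == 1 and out[0].identity == "lick"

    def test_bout_overlapping_push_excluded(self):
        force = np.zeros(5000)
        touch = np.zeros(5000, dtype=bool)
        licks = [1.0 + 0.2 * i for i in range(6)]
        push = events.ActionEvent(identity="push", onset_s=1.5, offset_s=1.9,
                                  cross3g_s=1.5, peak_s=1.7, peak_force_g=7.0)
        assert events.detect_touch_and_lick_events(touch, force, licks, [push]) == []
        far = events.ActionEvent(identity="push", onset_s=4.0, offset_s=4.4,
                                 cross3g_s=4.0, peak_s=4.2, peak_force_g=7.0)
        assert len(events.detect_touch_and_lick_events(touch, force, licks, [far])) == 1

    def test_unsorted_licks_raise(self):
        with pytest.raises(ValueError):
            events.detect_touch_and_lick_events(np.zeros(100, bool), np.zeros(100),
                                                [2.0, 1.0], [])


class TestSummary:
    def _mk(self, ident, t):
        return events.ActionEvent(identity=ident, onset_s=t, offset_s=t + 0.2,
                                  peak_s=t + 0.1, peak_force_g=7.0)

    def test_rates_and_proportions(self):
        evs = [self._mk("push", i) for i in range(30)] + \
            [self._mk("pull", 100 + i) for i in range(10)]
        out = events.summarize_behavior(evs, 20 * 60.0)
        assert out["rates_per_min"]["push"] == pytest.approx(1.5)
        assert out["proportions"]["push"] == pytest.approx(0.75)
        assert out["proportions_defined"]

    def test_empty_session_flags_proportions_undefined(self):
        out = events.summarize_behavior([], 600.0)
        assert out["rates_per_min"]["push"] == 0
        assert not out["proportions_defined"]
        assert math.isnan(out["proportions"]["push"])

    def test_random_table_matches_recount(self):
        rng = np.random.default_rng(9)
        idents = rng.choice(["push", "pull", "touch", "lick"], 50)
        evs = [self._mk(i, k) for k, i in enumerate(idents)]
        out = events.summarize_behavior(evs, 300.0)
        for ident in ("push", "pull", "touch", "lick"):
            assert out["counts"][ident] == int(np.sum(idents == ident))
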