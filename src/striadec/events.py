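"""Behavioral event detection from force, touch and lick streams.

The task's behavioral unit is an isometric force event on an immobile
joystick: push (positive force) or pull (negative force). Detectors here
reproduce the analysis definitions: hardware-style threshold events on the
1 kHz trace, "3 g cross" actions on a 30 Hz downsampled trace (>=2
consecutive frames above 3 g with joystick touch for the full 100 ms before
the crossing), 6 g-peaking subsets, isolation flags, joystick-touch and
lick-bout events, and per-session behavioral summaries.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActionEvent",
    "detect_threshold_actions",
    "detect_3g_cross_actions",
    "flag_isolation",
    "detect_touch_and_lick_events",
    "summarize_behavior",
]

FORCE_IDENTITIES = ("push", "pull")


@dataclass
class ActionEvent:
    """One detected behavioral event.

    For force actions, ``cross3g_s`` is the time of the first 1 kHz sample of
    the contiguous suprathreshold region and ``peak_s``/``peak_force_g`` give
    the (signed) force extremum. Touch and lick events use the interval
    midpoint as ``peak_s`` for alignment.
    """

    identity: str
    onset_s: float
    offset_s: float
    cross3g_s: float = math.nan
    peak_s: float = math.nan
    peak_force_g: float = math.nan
    is_task_action: bool = False
    is_6g: bool = False
    pre_isolated: bool | None = None
    post_isolated: bool | None = None

    @property
    def is_force_action(self) -> bool:
        return self.identity in FORCE_IDENTITIES


def _runs(mask: np.ndarray):
    """Start/stop (half-open) indices of True runs in a boolean vector."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    rises = np.flatnonzero(~m[:-1] & m[1:]) + 1
    falls = np.flatnonzero(m[:-1] & ~m[1:]) + 1
    starts = np.concatenate(([0], rises)) if m[0] else rises
    stops = np.concatenate((falls, [m.size])) if m[-1] else falls
    return list(zip(starts.tolist(), stops.tolist()))


def detect_threshold_actions(force, threshold_g, min_duration_s, direction, fs_hz=1000.0):
    """Hardware-style threshold events on the signed 1 kHz force trace.

    Maximal intervals where the force exceeds ``threshold_g`` in the given
    direction for at least ``min_duration_s``. Onset/offset are the threshold
    rise and fall times; the peak is the largest-magnitude sample (earliest
    sample on ties).
    """
    force = np.asarray(force, dtype=float)
    if not np.isfinite(force).all():
        raise ValueError("force trace contains non-finite samples")
    if threshold_g <= 0:
        raise ValueError("threshold must be positive")
    if direction not in FORCE_IDENTITIES:
        raise ValueError(f"direction must be one of {FORCE_IDENTITIES}")
    sign = 1.0 if direction == "push" else -1.0
    x = sign * force
    min_samples = max(1, int(np.ceil(min_duration_s * fs_hz)))
    events = []
    for start, stop in _runs(x > threshold_g):
        if stop - start < min_samples:
            continue
        seg = x[start:stop]
        pk = start + int(np.argmax(seg))
        events.append(
            ActionEvent(
                identity=direction,
                onset_s=start / fs_hz,
                offset_s=stop / fs_hz,
                cross3g_s=start / fs_hz,
                peak_s=pk / fs_hz,
                peak_force_g=float(force[pk]),
                is_task_action=True,
                is_6g=bool(abs(force[pk]) > 6.0),
            )
        )
    return events


def _frame_means(force: np.ndarray, fs_hz: float, frame_rate_hz: float):
    """Block-average a 1 kHz trace into imaging frames.

    Frame k spans samples [floor(k*fs/fr), floor((k+1)*fs/fr)); a trailing
    partial frame is averaged over the samples it has.
    """
    n = force.size
    n_frames = int(np.ceil(n * frame_rate_hz / fs_hz))
    edges = np.floor(np.arange(n_frames) * fs_hz / frame_rate_hz).astype(int)
    sums = np.add.reduceat(force, edges)
    counts = np.diff(np.append(edges, n))
    return sums / counts, edges, counts


def detect_3g_cross_actions(force, touch, fs_hz=1000.0, frame_rate_hz=30.0,
                            threshold_g=3.0, min_frames=2, touch_lead_s=0.1):
    """Detect 3 g cross actions on the 30 Hz downsampled force trace.

    An action is >=``min_frames`` consecutive frames whose block-averaged
    force exceeds 3 g in one direction, with joystick touch active for the
    full 100 ms before the 1 kHz crossing (isometric guarantee). The crossing
    and peak are located back on the 1 kHz trace within the contiguous
    suprathreshold region; ``is_6g`` marks peaks above 6 g.
    """
    force = np.asarray(force, dtype=float)
    if touch is None:
        raise ValueError("touch stream is required for 3g-cross detection")
    touch = np.asarray(touch, dtype=bool)
    if touch.shape != force.shape:
        raise ValueError("force and touch must be co-registered (same length)")
    if not np.isfinite(force).all():
        raise ValueError("force trace contains non-finite samples")

    lead = int(round(touch_lead_s * fs_hz))
    events = []
    for direction, sign in (("push", 1.0), ("pull", -1.0)):
        x = sign * force
        fmeans, edges, counts = _frame_means(x, fs_hz, frame_rate_hz)
        all_edges = np.append(edges, force.size)
        for fstart, fstop in _runs(fmeans >= threshold_g):
            if fstop - fstart < min_frames:
                continue
            s0, s1 = all_edges[fstart], all_edges[fstop]
            if np.max(x[s0:s1]) < threshold_g:
                continue  # frame means above threshold but no single sample is
            # anchor at the contiguous suprathreshold segment holding the peak
            pk = s0 + int(np.argmax(x[s0:s1]))
            cross = pk
            while cross > 0 and x[cross - 1] >= threshold_g:
                cross -= 1
            end = pk + 1
            while end < force.size and x[end] >= threshold_g:
                end += 1
            if cross < lead or not touch[cross - lead:cross].all():
                continue
            events.append(
                ActionEvent(
                    identity=direction,
                    onset_s=cross / fs_hz,
                    offset_s=end / fs_hz,
                    cross3g_s=cross / fs_hz,
                    peak_s=pk / fs_hz,
                    peak_force_g=float(force[pk]),
                    is_task_action=True,
                    is_6g=bool(abs(force[pk]) > 6.0),
                )
            )
    events.sort(key=lambda e: e.onset_s)
    return events


def flag_isolation(events, window_s=0.5, reference="peak"):
    """Flag force actions with no neighboring force action within ``window_s``.

    ``pre_isolated`` is true iff no other force action's reference time lies
    in the open interval (ref - window, ref); ``post_isolated`` symmetric.
    Non-force events pass through unchanged. Idempotent and order-independent.
    """
    if reference not in ("peak", "cross"):
        raise ValueError("reference must be 'peak' or 'cross'")
    attr = "peak_s" if reference == "peak" else "cross3g_s"
    refs = np.array([getattr(e, attr) for e in events if e.is_force_action])
    out = []
    for e in events:
        if not e.is_force_action:
            out.append(dataclasses.replace(e))
            continue
        r = getattr(e, attr)
        others = refs[refs != r]
        pre = not np.any((others > r - window_s) & (others < r))
        post = not np.any((others > r) & (others < r + window_s))
        out.append(dataclasses.replace(e, pre_isolated=bool(pre), post_isolated=bool(post)))
    return out


def detect_touch_and_lick_events(touch, force, lick_times, cross_events,
                                 fs_hz=1000.0, max_touch_force_g=2.0,
                                 min_touch_s=1.0, max_ili_s=0.5, min_licks=5):
    """Detect low-force joystick-touch events and lick bouts.

    Touch events are contact intervals with |force| < 2 g throughout lasting
    more than 1 s. Lick bouts are maximal runs of >=5 licks with inter-lick
    interval < 0.5 s, discarded when they overlap any 3 g cross interval.
    Both use the interval midpoint as the alignment time.
    """
    touch = np.asarray(touch, dtype=bool)
    force = np.asarray(force, dtype=float)
    lick_times = np.asarray(lick_times, dtype=float)
    if lick_times.size and np.any(np.diff(lick_times) < 0):
        raise ValueError("lick_times must be sorted")
    events = []
    min_samples = int(np.ceil(min_touch_s * fs_hz))
    for start, stop in _runs(touch):
        if stop - start <= min_samples:
            continue
        seg = force[start:stop]
        if np.max(np.abs(seg)) >= max_touch_force_g:
            continue
        mid = 0.5 * (start + stop) / fs_hz
        events.append(
            ActionEvent(identity="touch", onset_s=start / fs_hz, offset_s=stop / fs_hz,
                        peak_s=mid, peak_force_g=float(seg[np.argmax(np.abs(seg))]))
        )
    # lick bouts: split where the inter-lick interval reaches 0.5 s
    if lick_times.size:
        breaks = np.flatnonzero(np.diff(lick_times) >= max_ili_s) + 1
        for run in np.split(np.arange(lick_times.size), breaks):
            if run.size < min_licks:
                continue
            t0, t1 = lick_times[run[0]], lick_times[run[-1]]
            if any(e.onset_s < t1 and t0 < e.offset_s for e in cross_events):
                continue
            events.append(
                ActionEvent(identity="lick", onset_s=t0, offset_s=t1, peak_s=0.5 * (t0 + t1))
            )
    events.sort(key=lambda e: e.onset_s)
    return events


def summarize_behavior(events, session_duration_s):
    """Per-identity event rates (per minute) and force-action proportions."""
    if session_duration_s <= 0:
        raise ValueError("session duration must be positive")
    identities = sorted({e.identity for e in events} | set(FORCE_IDENTITIES))
    counts = {ident: sum(e.identity == ident for e in events) for ident in identities}
    rates = {ident: counts[ident] / (session_duration_s / 60.0) for ident in identities}
    n_force = sum(counts[i] for i in FORCE_IDENTITIES)
    defined = n_force > 0
    proportions = {
        i: (counts[i] / n_force if defined else math.nan) for i in FORCE_IDENTITIES
    }
    return {
        "counts": counts,
        "rates_per_min": rates,
        "proportions": proportions,
        "proportions_defined": defined,
    }
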