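"""Closed-loop stimulation analysis: pairing, alignment, force perturbation.

Stimulation trials are compared against preceding no-stimulation trials of
the same triggering action. Because stimulation onset follows the 3 g
crossing with variable latency, each no-stim trial is time-shifted so that
its candidate alignment point matches the stim trial's state at stimulation
onset — instantaneous (30 Hz low-passed) force and mean force over the
preceding 100 ms. The force perturbation is the trial-averaged stim force
minus the trial-averaged aligned no-stim force, pooled into congruent
(push-triggered push-ensemble, pull-triggered pull-ensemble) and
non-congruent conditions, with the convention that a perturbation
increasing the ongoing action's force magnitude is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import lowpass_filter_force
from .simulate import StimTrialRecord, schedule_stim_trials  # noqa: F401 (re-export)

__all__ = [
    "AlignedPair",
    "PerturbationResult",
    "schedule_stim_trials",
    "align_nostim_trials",
    "compute_force_perturbation",
    "assess_stim_specificity",
]


@dataclass
class AlignedPair:
    stim: StimTrialRecord
    nostim: StimTrialRecord
    align_time_s: float  # point on the no-stim trace matched to stim onset
    distance: float


@dataclass
class PerturbationResult:
    """Stim-minus-aligned-no-stim force difference for one condition."""

    condition: str
    time_lags_s: np.ndarray
    delta_force: np.ndarray  # grams, action-direction-positive
    delta_sem: np.ndarray
    end_of_stim_g: float
    n_pairs: int


def _trial_reference(rec: StimTrialRecord, latency_s: float) -> float:
    """Stim onset, or the pseudo-onset (cross + latency) for no-stim trials."""
    if rec.stim_onset_s is not None:
        return rec.stim_onset_s
    return rec.cross3g_s + latency_s


def _features(filtered: np.ndarray, idx: int, fs: float):
    pre = int(round(0.1 * fs))
    if idx - pre < 0 or idx >= filtered.size:
        return None
    return np.array([filtered[idx], filtered[idx - pre:idx].mean()])


def align_nostim_trials(session, stim_trials, nostim_trials, match_window_s=0.1,
                        filtered_force=None, on_missing="raise"):
    """Pair each (pseudo-)stim trial with its best-matching no-stim trial.

    Eligible no-stim trials precede the stim trial, share its triggering
    action, and are not closer in time to the previous stimulation than to
    the next. Candidate alignment points span the no-stim trial's action
    interval ±100 ms; the candidate minimizing the Euclidean distance between
    (instantaneous force, preceding-100 ms mean force) at stimulation onset
    and at the candidate is chosen, earliest candidate on ties.

    Raises when a stim trial has no eligible no-stim trial.
    """
    fs = session.force_rate
    if filtered_force is None:
        filtered_force = lowpass_filter_force(session.force, fs_hz=fs)
    stim_times = sorted(r.stim_onset_s for r in (session.stim_log or [])
                        if r.stim_onset_s is not None)
    if not stim_times:
        stim_times = sorted(r.stim_onset_s for r in stim_trials
                            if r.stim_onset_s is not None)
    stim_times = np.asarray(stim_times)

    def proximity_ok(t):
        prev = stim_times[stim_times <= t]
        nxt = stim_times[stim_times > t]
        if prev.size == 0 or nxt.size == 0:
            return nxt.size > 0  # before first stim: keep; after last: drop
        return (t - prev.max()) >= (nxt.min() - t)

    pairs = []
    win = int(round(match_window_s * fs))
    for st in stim_trials:
        t_ref = _trial_reference(st, 0.002)
        idx_ref = int(round(t_ref * fs))
        target = _features(filtered_force, idx_ref, fs)
        if target is None:
            continue
        eligible = [ns for ns in nostim_trials
                    if ns is not st
                    and ns.cross3g_s < st.cross3g_s
                    and ns.trigger_identity == st.trigger_identity
                    and proximity_ok(ns.cross3g_s)]
        if not eligible:
            if on_missing == "skip":
                continue
            raise ValueError(
                f"no eligible no-stim trial precedes stim trial {st.trial_index}")
        best = None
        for ns in eligible:
            c0 = int(round(ns.onset_s * fs)) - win
            c1 = int(round(ns.offset_s * fs)) + win
            for c in range(max(win, c0), min(filtered_force.size - 1, c1) + 1):
                feats = _features(filtered_force, c, fs)
                if feats is None:
                    continue
                d = float(np.linalg.norm(feats - target))
                if best is None or d < best[0] - 1e-12:
                    best = (d, ns, c)
        d, ns, c = best
        pairs.append(AlignedPair(stim=st, nostim=ns, align_time_s=c / fs, distance=d))
    return pairs


def _condition(rec: StimTrialRecord) -> str:
    if rec.pattern == "none":
        return "none"
    return "congruent" if rec.pattern == rec.trigger_identity else "non_congruent"


def compute_force_perturbation(session, pairs, pre_s=0.1, post_s=0.3,
                               end_window_s=0.02, filtered_force=None):
    """Per-condition force perturbation around stimulation onset.

    delta(lag) = mean over stim trials - mean over aligned no-stim trials of
    the 30 Hz-filtered force, each trial signed by its triggering action
    (+push / -pull) so that increased action force is positive for both
    actions. ``end_of_stim_g`` averages delta over the final ``end_window_s``
    of the 100 ms stimulation window.

    Returns a dict condition -> PerturbationResult.
    """
    fs = session.force_rate
    if filtered_force is None:
        filtered_force = lowpass_filter_force(session.force, fs_hz=fs)
    lags = np.arange(-int(round(pre_s * fs)), int(round(post_s * fs)) + 1)
    grouped = {}
    for p in pairs:
        grouped.setdefault(_condition(p.stim), []).append(p)

    out = {}
    for cond, members in grouped.items():
        deltas = []
        for p in members:
            sign = 1.0 if p.stim.trigger_identity == "push" else -1.0
            i_stim = int(round(_trial_reference(p.stim, 0.002) * fs))
            i_ns = int(round(p.align_time_s * fs))
            if (i_stim + lags[0] < 0 or i_stim + lags[-1] >= filtered_force.size
                    or i_ns + lags[0] < 0 or i_ns + lags[-1] >= filtered_force.size):
                continue
            deltas.append(sign * (filtered_force[i_stim + lags]
                                  - filtered_force[i_ns + lags]))
        if not deltas:
            continue
        stack = np.asarray(deltas)
        mean = stack.mean(axis=0)
        sem = (stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
               if stack.shape[0] > 1 else np.zeros(mean.size))
        lag_s = lags / fs
        end_sel = (lag_s >= 0.1 - end_window_s) & (lag_s <= 0.1)
        out[cond] = PerturbationResult(
            condition=cond, time_lags_s=lag_s, delta_force=mean, delta_sem=sem,
            end_of_stim_g=float(mean[end_sel].mean()), n_pairs=stack.shape[0],
        )
    return out


def assess_stim_specificity(dff_z, frame_times, ensembles, stim_records, dim,
                            window_s=0.1):
    """Targeted vs non-targeted responses and pre/post projection change.

    For each stimulation pattern: mean z-scored activity of the targeted
    ensemble, the opposite ensemble, and all non-targeted neurons in the
    100 ms after stimulation onset, plus the population projection on the
    decoder dimension averaged over the 100 ms before vs after stimulation.
    """
    dff_z = np.asarray(dff_z, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    frame_rate = 1.0 / np.median(np.diff(frame_times))
    w = int(round(window_s * frame_rate))
    n_frames = dff_z.shape[1]
    proj = dim.unit_weights @ dff_z
    groups = {
        "push": np.asarray(ensembles.push_members, dtype=int),
        "pull": np.asarray(ensembles.pull_members, dtype=int),
    }
    non_targeted = np.setdiff1d(np.arange(dff_z.shape[0]),
                                np.concatenate(list(groups.values())))
    out = {}
    for pattern in ("push", "pull", "none"):
        recs = [r for r in stim_records if r.pattern == pattern]
        if not recs:
            continue
        post_acts = {"targeted": [], "opposite": [], "non_targeted": []}
        pre_proj, post_proj = [], []
        for r in recs:
            t = _trial_reference(r, 0.002)
            f = int(round((t - frame_times[0]) * frame_rate))
            if f - w < 0 or f + w >= n_frames:
                raise ValueError("stimulation event outside the imaged session")
            post = slice(f, f + w + 1)
            pre = slice(f - w, f)
            if pattern == "none":
                tgt, opp = groups["push"], groups["pull"]  # nominal split
            else:
                tgt = groups[pattern]
                opp = groups["pull" if pattern == "push" else "push"]
            post_acts["targeted"].append(dff_z[tgt, post].mean())
            post_acts["opposite"].append(dff_z[opp, post].mean())
            post_acts["non_targeted"].append(dff_z[non_targeted, post].mean())
            pre_proj.append(proj[pre].mean())
            post_proj.append(proj[post].mean())
        out[pattern] = {
            "post_activity": {k: float(np.mean(v)) for k, v in post_acts.items()},
            "projection_pre": float(np.mean(pre_proj)),
            "projection_post": float(np.mean(post_proj)),
            "n_trials": len(recs),
        }
    return out
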