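"""Synthetic two-action isometric sessions with planted ground truth.

Generates sessions with the statistical structure the analysis pipeline
assumes: self-paced push/pull force bumps on a 1 kHz joystick trace, touch
and lick streams, Poisson-spiking neurons with exponential calcium
transients (raw + neuropil fluorescence at 30 Hz), correlated 4-channel EMG
envelopes, and closed-loop stimulation sessions with scheduled trigger/
pattern conditions and planted congruent force effects.

Every planted quantity (ensemble memberships, per-neuron preparation leads,
event onset/cross/peak times measured on the composed force trace, and
stimulation effect amplitudes) is returned as GroundTruth so that each
downstream analysis can be tested as a parameter-recovery problem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SimConfig",
    "PlantedEvent",
    "GroundTruth",
    "SessionData",
    "simulate_behavior_session",
    "simulate_neural_activity",
    "simulate_stim_session",
    "adaptive_reinforcement_policy",
]

ROLES = ("push-exec", "pull-exec", "push-prep", "pull-prep")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one synthetic session.

    Ensemble counts partition the population into execution- and
    preparation-specific neurons (the remainder are unmodulated).
    ``exec_effect`` scales the added event rate of execution neurons at
    their action's force peak; with the default baseline rate and noise it
    corresponds to roughly one session-z unit of evoked ΔF/F0 per unit.
    Preparation neurons lead the 3 g cross by per-neuron times jittered
    around ``prep_lead_s`` (recorded in GroundTruth.timing_offsets).
    """

    duration_s: float = 480.0
    frame_rate: float = 30.0
    force_rate: float = 1000.0
    n_neurons: int = 120
    n_push_exec: int = 8
    n_pull_exec: int = 8
    n_push_prep: int = 0
    n_pull_prep: int = 0
    exec_effect: float = 1.5
    prep_effect: float | None = None  # None -> same as exec_effect
    prep_lead_s: float = 0.3
    prep_lead_jitter: float = 0.85  # fractional spread of per-neuron leads
    action_rate_per_min: float = 5.0  # events per minute per action
    push_preference: float = 0.5
    force_peak_range_g: tuple = (6.0, 12.0)
    bump_rise_range_s: tuple = (0.09, 0.18)
    bump_decay_range_s: tuple = (0.11, 0.25)
    calcium_decay_s: float = 0.2
    base_rate_hz: float = 0.2
    transient_amp: float = 1.0
    noise_sd: float = 0.1  # fluorescence noise as a fraction of baseline F
    force_noise_sd_g: float = 0.25
    reward_delay_s: float = 0.5
    touch_lead_s: float = 0.15
    touch_event_rate_per_min: float = 1.0
    emg_shared_gain: float = 3.0
    emg_diff_gain: float = 1.0
    emg_noise_sd: float = 0.3
    stim_effect_g: float = 0.0
    stim_neural_effect: float = 0.0
    stim_latency_s: float = 0.002
    seed: int = 0

    def ensemble_sizes(self):
        return (self.n_push_exec, self.n_pull_exec, self.n_push_prep, self.n_pull_prep)

    def validate(self):
        if any(n < 0 for n in self.ensemble_sizes()):
            raise ValueError("ensemble sizes must be non-negative")
        if sum(self.ensemble_sizes()) > self.n_neurons:
            raise ValueError("ensemble sizes must sum to at most n_neurons")
        if not (0.0 <= self.push_preference <= 1.0):
            raise ValueError("push_preference must lie in [0, 1]")
        if (self.n_push_prep or self.n_pull_prep) and self.prep_lead_s <= 0:
            raise ValueError("prep_lead_s must be positive when preparation neurons are planted")
        if self.duration_s <= 0 or self.frame_rate <= 0 or self.force_rate <= 0:
            raise ValueError("duration and rates must be positive")


@dataclass(frozen=True)
class PlantedEvent:
    """One planted action with times measured on the composed force trace."""

    identity: str
    onset_s: float
    cross3g_s: float
    peak_s: float
    peak_force_g: float


@dataclass
class GroundTruth:
    """Planted simulation parameters for parameter-recovery tests."""

    ensemble_membership: dict  # neuron index -> role or 'none'
    celltype: np.ndarray  # per neuron, 'D1' or 'D2'
    planted_events: list
    timing_offsets: dict = field(default_factory=dict)  # prep neuron -> lead (s)
    stim_effect_g: float | None = None
    stim_neural_effect: float | None = None
    emg_shared_drive: np.ndarray | None = None  # planted common-drive trace (1 kHz)
    emg_diff_drive: np.ndarray | None = None

    def members(self, role: str) -> np.ndarray:
        return np.array(sorted(i for i, r in self.ensemble_membership.items() if r == role),
                        dtype=int)


@dataclass
class StimTrialRecord:
    """One scheduled trial of a stimulation session."""

    trial_index: int
    block: int
    trigger_identity: str  # 'push' | 'pull' (the action performed)
    pattern: str  # 'push' | 'pull' | 'none' (stimulated ensemble)
    stim_onset_s: float | None  # None when pattern == 'none'
    stim_duration_s: float = 0.1
    cross3g_s: float = float("nan")
    onset_s: float = float("nan")
    offset_s: float = float("nan")
    force_snippet: np.ndarray | None = None


@dataclass
class SessionData:
    """Synchronized session container; all streams share one time origin."""

    force: np.ndarray  # 1 kHz, grams, push positive / pull negative
    force_lateral: np.ndarray
    touch: np.ndarray  # binary 1 kHz
    lick_times: np.ndarray  # seconds
    emg: np.ndarray  # 4 x samples, 1 kHz envelopes
    frame_times: np.ndarray
    force_rate: float
    frame_rate: float
    duration_s: float
    fluorescence_raw: np.ndarray | None = None
    fluorescence_neuropil: np.ndarray | None = None
    celltype_labels: np.ndarray | None = None
    stim_log: list | None = None


# ---------------------------------------------------------------------------
# force / behavior


def _raised_cosine_bump(rise_s, decay_s, peak_g, fs):
    nr = max(2, int(round(rise_s * fs)))
    nd = max(2, int(round(decay_s * fs)))
    rise = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, nr + 1) / nr))
    decay = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, nd + 1) / nd))
    return peak_g * np.concatenate([rise, decay])


def _smooth_noise(rng, n, sd, fs, corr_s=0.03):
    x = gaussian_filter1d(rng.standard_normal(n), corr_s * fs)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _measure_event(force, onset_idx, stop_idx, sign, fs, threshold=3.0):
    """Measure cross/peak of a planted bump on the composed (noisy) trace.

    The crossing is the first sample of the contiguous suprathreshold segment
    that contains the force peak — the same convention the event detector
    uses, so planted times are the trace's own times, not the noise-free ones.
    """
    x = sign * force[onset_idx:stop_idx]
    pk_local = int(np.argmax(x))
    if x[pk_local] < threshold:
        return None
    cross = onset_idx + pk_local
    while cross > 0 and sign * force[cross - 1] >= threshold:
        cross -= 1
    return cross / fs, (onset_idx + pk_local) / fs, float(force[onset_idx + pk_local])


def _draw_event_times(rng, config):
    """Renewal process with a refractory gap enforcing the ITI quiescence rule."""
    rate_hz = 2.0 * config.action_rate_per_min / 60.0
    if rate_hz == 0:
        return []
    mean_gap = 1.0 / rate_hz
    min_gap = 2.0  # 1 s ITI quiescence + longest bump + margin
    if mean_gap < 1.25 * min_gap:
        raise ValueError(
            f"action rate {config.action_rate_per_min}/min per action is too high: "
            f"mean inter-event gap {mean_gap:.2f} s cannot respect the 1 s "
            "inter-trial quiescence around 0.2-0.6 s force bumps")
    times, t = [], 2.0 + rng.exponential(mean_gap - min_gap)
    while t < config.duration_s - 2.0:
        times.append(t)
        t += min_gap + rng.exponential(mean_gap - min_gap)
    return times


def _compose_emg(rng, n, events_for_emg, fs, config):
    """4-channel envelopes: shared co-contraction drive + signed differential."""
    shared = np.zeros(n)
    diff = np.zeros(n)
    for onset_idx, bump, sign in events_for_emg:
        shape = bump / np.max(np.abs(bump))
        stop = min(n, onset_idx + shape.size)
        shared[onset_idx:stop] += shape[: stop - onset_idx]
        diff[onset_idx:stop] += sign * shape[: stop - onset_idx]
    loadings_shared = np.array([1.0, 0.9, 1.1, 0.8]) * config.emg_shared_gain
    loadings_diff = np.array([0.7, -0.8, 0.5, -0.6]) * config.emg_diff_gain
    emg = (loadings_shared[:, None] * shared[None, :]
           + loadings_diff[:, None] * diff[None, :])
    for ch in range(4):
        emg[ch] += _smooth_noise(rng, n, config.emg_noise_sd, fs, corr_s=0.025)
    return emg + 1.0, shared, diff  # baseline offset keeps envelopes positive


def _assign_ground_truth(rng, config):
    membership = {i: "none" for i in range(config.n_neurons)}
    idx = 0
    for role, size in zip(ROLES, config.ensemble_sizes()):
        for _ in range(size):
            membership[idx] = role
            idx += 1
    celltype = np.where(rng.random(config.n_neurons) < 0.5, "D1", "D2")
    # preparation neurons tile a spectrum of lead times around prep_lead_s
    # (mean lead = prep_lead_s), with small per-neuron jitter
    offsets = {}
    j = config.prep_lead_jitter
    for role in ("push-prep", "pull-prep"):
        members = sorted(i for i, r in membership.items() if r == role)
        if not members:
            continue
        grid = np.linspace(1.0 - j, 1.0 + j, len(members)) if len(members) > 1 else [1.0]
        for i, g in zip(members, grid):
            offsets[i] = float(config.prep_lead_s * (g + rng.uniform(-0.05, 0.05)))
    return membership, celltype, offsets


def simulate_behavior_session(config: SimConfig, seed: int | None = None):
    """Generate the behavioral streams of one session plus ground truth.

    Self-paced push/pull events from a renewal process write raised-cosine
    force bumps (rise >= ~90 ms, total 0.2-0.43 s) whose signed peak is drawn
    from ``force_peak_range_g``; baseline force is smoothed zero-mean noise.
    Touch is active from before each onset through the bump; lick bouts
    (6 licks, 0.12 s spacing) follow each action after ``reward_delay_s``.
    Identical (config, seed) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.force_rate
    n = int(round(config.duration_s * fs))

    event_times = _draw_event_times(rng, config)
    force = _smooth_noise(rng, n, config.force_noise_sd_g, fs)
    touch = np.zeros(n, dtype=bool)
    lick_times = []
    emg_events = []
    planted_meta = []  # (identity, onset_idx, stop_idx, sign, bump)

    lo, hi = config.force_peak_range_g
    for t in event_times:
        identity = "push" if rng.random() < config.push_preference else "pull"
        sign = 1.0 if identity == "push" else -1.0
        rise = rng.uniform(*config.bump_rise_range_s)
        decay = rng.uniform(*config.bump_decay_range_s)
        peak = rng.uniform(lo, hi)
        bump = _raised_cosine_bump(rise, decay, peak, fs)
        onset_idx = int(round(t * fs))
        stop = min(n, onset_idx + bump.size)
        force[onset_idx:stop] += sign * bump[: stop - onset_idx]
        t0 = max(0, onset_idx - int(round(config.touch_lead_s * fs)))
        touch[t0: min(n, stop + int(round(0.2 * fs)))] = True
        emg_events.append((onset_idx, bump, sign))
        planted_meta.append((identity, onset_idx, stop, sign, bump))

    # low-force touch-only intervals in quiet gaps
    n_touch = rng.poisson(config.touch_event_rate_per_min * config.duration_s / 60.0)
    busy = [(idx / fs - 1.0, stop / fs + 1.0) for _, idx, stop, _, _ in planted_meta]
    for _ in range(n_touch):
        dur = rng.uniform(1.3, 2.5)
        t0 = rng.uniform(1.0, config.duration_s - dur - 1.0)
        if any(t0 < b1 and b0 < t0 + dur for b0, b1 in busy):
            continue
        i0 = int(round(t0 * fs))
        touch[i0: i0 + int(round(dur * fs))] = True

    # measure planted events on the composed trace
    planted = []
    for identity, onset_idx, stop, sign, bump in planted_meta:
        measured = _measure_event(force, onset_idx, stop, sign, fs)
        if measured is None:
            continue
        cross_s, peak_s, peak_g = measured
        planted.append(PlantedEvent(identity, onset_idx / fs, cross_s, peak_s, peak_g))
        bout_start = peak_s + config.reward_delay_s
        lick_times.extend(bout_start + 0.12 * np.arange(6))

    emg, shared_drive, diff_drive = _compose_emg(rng, n, emg_events, fs, config)
    membership, celltype, offsets = _assign_ground_truth(rng, config)

    session = SessionData(
        force=force,
        force_lateral=_smooth_noise(rng, n, 0.2, fs) + 0.15 * np.abs(force),
        touch=touch,
        lick_times=np.asarray(sorted(lick_times)),
        emg=emg,
        frame_times=np.arange(int(round(config.duration_s * config.frame_rate)))
        / config.frame_rate,
        force_rate=fs,
        frame_rate=config.frame_rate,
        duration_s=config.duration_s,
    )
    truth = GroundTruth(ensemble_membership=membership, celltype=celltype,
                        planted_events=planted, timing_offsets=offsets,
                        emg_shared_drive=shared_drive, emg_diff_drive=diff_drive)
    return session, truth


# ---------------------------------------------------------------------------
# neural activity


#: events/s of added peak rate per z-unit of requested effect; calibrated so
#: that the trial-window evoked response of a planted neuron, in session
#: z-scored ΔF/F0, approximately equals the effect parameter under the
#: default baseline rate, transient amplitude and noise.
_RATE_PER_Z = 3.2


def _event_rate_matrix(truth, config, frame_times, rng):
    """Per-neuron event rate: heterogeneous baseline + planted tuning bumps."""
    n_neurons = config.n_neurons
    base = config.base_rate_hz * rng.uniform(0.5, 1.5, size=n_neurons)
    rate = np.tile(base[:, None], (1, frame_times.size))
    prep_amp = config.exec_effect if config.prep_effect is None else config.prep_effect
    sigma = {"exec": 0.06, "prep": 0.06}
    for ev in truth.planted_events:
        for i, role in truth.ensemble_membership.items():
            if role == "none" or not role.startswith(ev.identity):
                continue
            kind = role.split("-")[1]
            if kind == "exec":
                center, amp = ev.peak_s, config.exec_effect * _RATE_PER_Z
            else:
                center, amp = ev.cross3g_s - truth.timing_offsets[i], prep_amp * _RATE_PER_Z
            s = sigma[kind]
            lo = np.searchsorted(frame_times, center - 4 * s)
            hi = np.searchsorted(frame_times, center + 4 * s)
            tt = frame_times[lo:hi]
            rate[i, lo:hi] += amp * np.exp(-0.5 * ((tt - center) / s) ** 2)
    return rate


def _calcium_signal(counts, config):
    """Exponential-kernel convolution of discrete events (unit transient amp)."""
    a = np.exp(-1.0 / (config.frame_rate * config.calcium_decay_s))
    return sps.lfilter([1.0], [1.0, -a], counts * config.transient_amp, axis=1)


def _compose_fluorescence(signal, config, rng):
    """Scale ΔF-like signal into raw + neuropil fluorescence channels."""
    n_neurons, n_frames = signal.shape
    f0 = rng.uniform(80.0, 120.0, size=n_neurons)[:, None]
    t = np.arange(n_frames) / config.frame_rate
    phases = rng.uniform(0, 2 * np.pi, size=n_neurons)[:, None]
    neuropil = 20.0 + 3.0 * np.sin(2 * np.pi * t[None, :] / 120.0 + phases)
    neuropil = neuropil + 0.3 * rng.standard_normal((n_neurons, n_frames))
    f_corrected = f0 * (1.0 + signal)
    f_raw = (f_corrected + 0.7 * neuropil
             + config.noise_sd * f0 * rng.standard_normal((n_neurons, n_frames)))
    return f_raw, neuropil


def simulate_neural_activity(session: SessionData, truth: GroundTruth,
                             config: SimConfig, seed: int | None = None,
                             extra_signal=None):
    """Add Poisson-transient fluorescence driven by the planted events.

    Execution neurons gain a rate bump at their action's force peak,
    preparation neurons one centered their per-neuron lead before the 3 g
    cross; events convolve with an exponential calcium kernel and are scaled
    into raw fluorescence with an additive neuropil channel and noise.
    ``extra_signal`` (neurons x frames) is added to the ΔF-like signal before
    scaling — used by the stimulation path.
    """
    config.validate()
    if (config.n_push_prep or config.n_pull_prep) and config.prep_lead_s <= 0:
        raise ValueError("prep_lead_s must be positive")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 10_007)
    rate = _event_rate_matrix(truth, config, session.frame_times, rng)
    counts = rng.poisson(rate / config.frame_rate)
    signal = _calcium_signal(counts, config)
    if extra_signal is not None:
        signal = signal + extra_signal
    f_raw, neuropil = _compose_fluorescence(signal, config, rng)
    return dataclasses.replace(
        session, fluorescence_raw=f_raw, fluorescence_neuropil=neuropil,
        celltype_labels=truth.celltype,
    )


# ---------------------------------------------------------------------------
# stimulation sessions

_STIM_BLOCK = ("none", "stim", "none", "none", "stim", "none")
_NOSTIM_IDENTITIES = {0: "push", 2: "pull", 3: "pull", 5: "push"}


def schedule_stim_trials(n_blocks: int):
    """Scheduled trial order of a stimulation session.

    Each 6-trial block runs (no stim, push-triggered stim, no stim, no stim,
    pull-triggered stim, no stim); the stimulated ensemble pattern alternates
    between congruent and non-congruent across successive blocks, so any two
    consecutive blocks cover all six trigger x pattern conditions.

    Returns a list of (trigger_identity, pattern) with pattern in
    {'push', 'pull', 'none'}.
    """
    if n_blocks < 1:
        raise ValueError("need at least one block")
    schedule = []
    for b in range(n_blocks):
        congruent = b % 2 == 0
        for slot, kind in enumerate(_STIM_BLOCK):
            if kind == "none":
                schedule.append((_NOSTIM_IDENTITIES[slot], "none"))
            else:
                trigger = "push" if slot == 1 else "pull"
                if congruent:
                    pattern = trigger
                else:
                    pattern = "pull" if trigger == "push" else "push"
                schedule.append((trigger, pattern))
    return schedule


def _stim_force_effect(fs, effect_g, stim_duration_s=0.1, ramp_s=0.08,
                       hold_s=0.05, decay_s=0.15):
    """Added force: ramp to the planted amplitude, hold past the window, decay."""
    ramp = np.linspace(0.0, effect_g, int(round(ramp_s * fs)), endpoint=False)
    hold = np.full(int(round(hold_s * fs)), effect_g)
    decay = np.linspace(effect_g, 0.0, int(round(decay_s * fs)))
    return np.concatenate([ramp, hold, decay])


def simulate_stim_session(config: SimConfig, ensembles, n_blocks: int = 10,
                          seed: int | None = None):
    """Closed-loop stimulation session following the 6-trial block schedule.

    ``ensembles`` is an EnsembleSelection naming the targeted push/pull
    neurons (they are planted as the execution ensembles so the targeted
    populations genuinely encode the actions). On stimulation trials the
    targeted neurons receive an added transient of amplitude
    ``config.stim_neural_effect`` for the 100 ms window, delayed by
    ``config.stim_latency_s`` after the 3 g crossing; congruent trials
    additionally ramp ``config.stim_effect_g`` onto the force trace in the
    ongoing action's direction.
    """
    push_members = np.asarray(ensembles.push_members, dtype=int)
    pull_members = np.asarray(ensembles.pull_members, dtype=int)
    if push_members.size == 0 or pull_members.size == 0:
        raise ValueError("ensembles must be non-empty")
    if np.intersect1d(push_members, pull_members).size:
        raise ValueError("ensembles must be disjoint")
    all_members = np.concatenate([push_members, pull_members])
    if all_members.max() >= config.n_neurons or all_members.min() < 0:
        raise ValueError("ensembles reference neurons outside the session")

    schedule = schedule_stim_trials(n_blocks)
    slot_s = 3.5  # 2 s inter-trial interval + action window
    duration = len(schedule) * slot_s + 4.0
    config = dataclasses.replace(config, duration_s=duration)
    rng = np.random.default_rng((config.seed if seed is None else seed) + 77_003)
    fs = config.force_rate
    n = int(round(duration * fs))

    force = _smooth_noise(rng, n, config.force_noise_sd_g, fs)
    touch = np.zeros(n, dtype=bool)
    emg_events = []
    lo, hi = config.force_peak_range_g
    records, planted, planted_meta = [], [], []

    for i, (trigger, pattern) in enumerate(schedule):
        sign = 1.0 if trigger == "push" else -1.0
        t_onset = i * slot_s + 2.0 + rng.uniform(0.1, 0.5)
        rise = rng.uniform(*config.bump_rise_range_s)
        decay = rng.uniform(*config.bump_decay_range_s)
        bump = _raised_cosine_bump(rise, decay, rng.uniform(lo, hi), fs)
        onset_idx = int(round(t_onset * fs))
        stop = min(n, onset_idx + bump.size)
        force[onset_idx:stop] += sign * bump[: stop - onset_idx]
        t0 = max(0, onset_idx - int(round(config.touch_lead_s * fs)))
        touch[t0: min(n, stop + int(round(0.2 * fs)))] = True
        emg_events.append((onset_idx, bump, sign))
        planted_meta.append((i, trigger, pattern, onset_idx, stop, sign))

    # measure crossings, then apply stimulation force effects
    for i, trigger, pattern, onset_idx, stop, sign in planted_meta:
        measured = _measure_event(force, onset_idx, stop, sign, fs)
        if measured is None:  # cannot happen with >=6 g peaks; defensive
            continue
        cross_s, peak_s, peak_g = measured
        planted.append(PlantedEvent(trigger, onset_idx / fs, cross_s, peak_s, peak_g))
        stim_onset = cross_s + config.stim_latency_s if pattern != "none" else None
        if pattern != "none" and pattern == trigger and config.stim_effect_g:
            eff = _stim_force_effect(fs, config.stim_effect_g)
            j0 = int(round(stim_onset * fs))
            j1 = min(n, j0 + eff.size)
            force[j0:j1] += sign * eff[: j1 - j0]
        records.append(StimTrialRecord(
            trial_index=i, block=i // 6, trigger_identity=trigger, pattern=pattern,
            stim_onset_s=stim_onset, cross3g_s=cross_s,
            onset_s=onset_idx / fs, offset_s=stop / fs,
        ))

    # snippets around the crossing for inspection/serialization
    snip = int(round(0.5 * fs))
    for rec in records:
        c = int(round(rec.cross3g_s * fs))
        rec.force_snippet = force[max(0, c - snip): c + snip].copy()

    emg, _, _ = _compose_emg(rng, n, emg_events, fs, config)
    membership = {i: "none" for i in range(config.n_neurons)}
    for idx in push_members:
        membership[int(idx)] = "push-exec"
    for idx in pull_members:
        membership[int(idx)] = "pull-exec"
    celltype = np.where(rng.random(config.n_neurons) < 0.5, "D1", "D2")
    truth = GroundTruth(
        ensemble_membership=membership, celltype=celltype, planted_events=planted,
        stim_effect_g=config.stim_effect_g, stim_neural_effect=config.stim_neural_effect,
    )

    frame_times = np.arange(int(round(duration * config.frame_rate))) / config.frame_rate
    session = SessionData(
        force=force, force_lateral=_smooth_noise(rng, n, 0.2, fs) + 0.15 * np.abs(force),
        touch=touch, lick_times=np.asarray([]), emg=emg, frame_times=frame_times,
        force_rate=fs, frame_rate=config.frame_rate, duration_s=duration,
        stim_log=records,
    )

    # neural: direct stimulation transient on the targeted ensemble
    extra = np.zeros((config.n_neurons, frame_times.size))
    if config.stim_neural_effect:
        kern_frames = int(round(0.1 * config.frame_rate)) + 1
        a = np.exp(-1.0 / (config.frame_rate * config.calcium_decay_s))
        box = np.ones(kern_frames)
        resp = sps.lfilter([1.0], [1.0, -a], box)
        resp = np.concatenate([resp, resp[-1] * a ** np.arange(1, 20)])
        resp = resp / resp.max() * config.stim_neural_effect
        for rec in records:
            if rec.pattern == "none":
                continue
            members = push_members if rec.pattern == "push" else pull_members
            f0 = np.searchsorted(frame_times, rec.stim_onset_s)
            f1 = min(frame_times.size, f0 + resp.size)
            extra[members, f0:f1] += resp[: f1 - f0]
    session = simulate_neural_activity(session, truth, config, seed=seed,
                                       extra_signal=extra)
    return session, truth


# ---------------------------------------------------------------------------
# adaptive reinforcement


def adaptive_reinforcement_policy(recent_identities):
    """Reinforcement flags from the last <= 10 trial identities.

    If one action's proportion strictly exceeds 0.70 over the window, that
    action is unrewarded and the other reinforced; otherwise both are
    reinforced. An empty history reinforces both (documented default).
    """
    recent = list(recent_identities)
    if len(recent) > 10:
        raise ValueError("history must hold at most the last 10 trials")
    if not recent:
        return True, True
    if set(recent) - {"push", "pull"}:
        raise ValueError("identities must be 'push' or 'pull'")
    p_push = sum(1 for r in recent if r == "push") / len(recent)
    reinforce_push = not p_push > 0.70
    reinforce_pull = not (1.0 - p_push) > 0.70
    return reinforce_push, reinforce_pull
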