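"""End-to-end synthetic study suites.

Bundles the full pipeline — simulate a session, condition the signals,
detect events, decode, and run the geometry / perturbation / EMG analyses —
into reusable session-level and suite-level drivers. The analysis scripts,
the test suite and the acceptance script all run these same code paths.

Problem sizes are chosen so a suite of 20 sessions finishes in minutes on
one core: 480 s sessions at 5 actions/min per action (~40 trials per
action), 120 neurons with planted 8-neuron execution and preparation
ensembles. The decoder sweep configs use fewer repeated splits and a
coarser regularization grid than the DecoderConfig defaults; the protocol
(stratified 90/10 splits, inner C selection, 1/n class weights) is
unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import decoding, emg, events as ev, geometry, perturbation, signals, simulate

__all__ = [
    "SessionBundle",
    "fast_decoder_config",
    "sweep_decoder_config",
    "behavior_suite_config",
    "null_suite_config",
    "ensemble_suite_config",
    "process_session",
    "peak_trials",
    "session_decoding",
    "session_lag_geometry",
    "ensemble_recovery",
    "run_decoding_suite",
    "run_null_suite",
    "run_ensemble_suite",
    "run_stim_session",
    "run_stim_suite",
    "emg_session_analysis",
    "run_emg_suite",
]

GEOMETRY_LAGS = (-0.30, -0.22, -0.14, -0.07, 0.0)  # seconds before the 3 g cross
TIMING_DIMS = ("early_prep", "late_prep", "cross", "peak")
_TIMING_LAGS = {"early_prep": -0.14, "late_prep": -0.07, "cross": 0.0}


# ---------------------------------------------------------------------------
# configurations


def fast_decoder_config(seed=0):
    """Headline-decoder protocol at suite scale (25 splits, 4-point C grid)."""
    return decoding.DecoderConfig(n_repeats=25, n_subfolds=5,
                                  regularization_grid=(1e-2, 1e-1, 1.0, 1e1),
                                  seed=seed)


def sweep_decoder_config(seed=0):
    """Lighter protocol for per-lag decoder sweeps (10 splits, 3-point grid)."""
    return decoding.DecoderConfig(n_repeats=10, n_subfolds=5,
                                  regularization_grid=(1e-1, 1.0, 1e1),
                                  seed=seed)


def behavior_suite_config(seed=0, **overrides):
    """Study conditions of the decoding/geometry suite."""
    base = dict(duration_s=480.0, n_neurons=120, n_push_exec=8, n_pull_exec=8,
                n_push_prep=8, n_pull_prep=8, exec_effect=1.5, prep_lead_s=0.3,
                action_rate_per_min=5.0, force_peak_range_g=(6.0, 12.0), seed=seed)
    base.update(overrides)
    return simulate.SimConfig(**base)


def null_suite_config(seed=0):
    """Zero planted selectivity: chance-level decoding control."""
    return behavior_suite_config(seed, exec_effect=0.0, n_push_prep=0, n_pull_prep=0)


def ensemble_suite_config(seed=0):
    """Stimulation-session regime: small population, mostly action-modulated."""
    return behavior_suite_config(seed, duration_s=360.0, n_neurons=18,
                                 n_push_prep=0, n_pull_prep=0)


# ---------------------------------------------------------------------------
# session pipeline


@dataclass
class SessionBundle:
    config: simulate.SimConfig
    session: simulate.SessionData
    truth: simulate.GroundTruth
    fluor: signals.FluorescenceSet
    events: list  # isolation-flagged 3 g cross actions


def process_session(config, seed=None) -> SessionBundle:
    """Simulate one session and run it through conditioning and detection."""
    session, truth = simulate.simulate_behavior_session(config, seed=seed)
    session = simulate.simulate_neural_activity(session, truth, config, seed=seed)
    fluor = signals.compute_dff(session.fluorescence_raw, session.fluorescence_neuropil,
                                frame_rate=config.frame_rate)
    detected = ev.detect_3g_cross_actions(session.force, session.touch,
                                          fs_hz=config.force_rate,
                                          frame_rate_hz=config.frame_rate)
    detected = ev.flag_isolation(detected, window_s=0.5, reference="peak")
    return SessionBundle(config=config, session=session, truth=truth,
                         fluor=fluor, events=detected)


def peak_trials(bundle, lag0_rule="both"):
    selectors = {
        "both": lambda e: e.pre_isolated and e.post_isolated,
        "pre": lambda e: e.pre_isolated,
        "post": lambda e: e.post_isolated,
        "either": lambda e: e.pre_isolated or e.post_isolated,
    }
    chosen = [e for e in bundle.events if selectors[lag0_rule](e)]
    return decoding.extract_trial_vectors(bundle.fluor.dff_z,
                                          bundle.session.frame_times,
                                          chosen, lag_s=0.0, alignment="peak")


def session_decoding(bundle, config=None, with_shuffle=True):
    """Force-peak decoder (with shuffle control) for one session."""
    config = config or fast_decoder_config(bundle.config.seed)
    trials = peak_trials(bundle)
    decoder = decoding.fit_action_decoder(trials, config)
    shuffled = (decoding.fit_action_decoder(trials, config, shuffle=True)
                if with_shuffle else None)
    return {"trials": trials, "decoder": decoder, "shuffle": shuffled,
            "n_trials": trials.vectors.shape[0]}


def session_lag_geometry(bundle, peak_decoder, lags=GEOMETRY_LAGS, config=None):
    """Per-lag decoders before the 3 g cross, angles to the force-peak decoder,
    and percentile-crossing times of the four canonical dimension projections."""
    config = config or sweep_decoder_config(bundle.config.seed)
    course = decoding.decode_time_course(
        bundle.fluor.dff_z, bundle.session.frame_times, bundle.events,
        lags=lags, alignment="cross", config=config, with_shuffle=False)
    peak_dim = geometry.decoder_dimension(peak_decoder)
    angles = {}
    dims = {"peak": peak_dim}
    for lag, entry in course.items():
        if entry["decoder"] is None:
            angles[lag] = None
            continue
        dim = geometry.decoder_dimension(entry["decoder"], source_lag_s=lag,
                                         source_alignment="cross")
        angles[lag] = geometry.subspace_angle(dim, peak_dim)
        for name, want in _TIMING_LAGS.items():
            if np.isclose(lag, want):
                dims[name] = dim

    # percentile-crossing times per dimension, averaged over the two actions
    # (pull projections are negated: they deflect downward by convention)
    timings = {}
    iso = [e for e in bundle.events if e.pre_isolated]
    for name in TIMING_DIMS:
        dim = dims.get(name)
        if dim is None or not iso:
            timings[name] = None
            continue
        peths = geometry.project_population(
            bundle.fluor.dff_z, bundle.session.frame_times, dim, iso, window_s=1.2)
        crossings = []
        for ident, negate in (("push", False), ("pull", True)):
            if ident not in peths:
                continue
            t = geometry.activation_timing(peths[ident], percentile=0.99,
                                           window_s=2.0, negate=negate)
            if t is not None:
                crossings.append(t)
        timings[name] = float(np.mean(crossings)) if crossings else None
    return {"angles": angles, "timings": timings, "course": course}


def ensemble_recovery(bundle, decoder):
    """Fraction of frac=1 ensemble members that are planted execution members."""
    sel = geometry.select_ensembles(decoder, ensemble_frac=1.0)
    push_truth = set(bundle.truth.members("push-exec"))
    pull_truth = set(bundle.truth.members("pull-exec"))
    hits = (len(push_truth & set(sel.push_members.tolist()))
            + len(pull_truth & set(sel.pull_members.tolist())))
    return hits / (sel.push_members.size + sel.pull_members.size)


# ---------------------------------------------------------------------------
# suite drivers


def run_decoding_suite(base_seed=0, n_sessions=20, with_geometry=True):
    """Decoding + geometry over a suite of planted-ensemble sessions."""
    results = []
    for s in range(n_sessions):
        seed = base_seed * 1000 + s
        bundle = process_session(behavior_suite_config(seed))
        dec = session_decoding(bundle)
        row = {
            "seed": seed,
            "accuracy": dec["decoder"].accuracy_mean,
            "shuffle_accuracy": dec["shuffle"].accuracy_mean,
            "n_trials": dec["n_trials"],
            "bundle": bundle,
            "decoder": dec["decoder"],
        }
        if with_geometry:
            row["geometry"] = session_lag_geometry(bundle, dec["decoder"])
        results.append(row)
    return results


def run_null_suite(base_seed=0, n_sessions=20):
    """Chance-level control: zero planted selectivity.

    Uses 50 repeated splits per session: with no signal the split-to-split
    noise dominates a 25-repeat estimate, so the null control doubles the
    repeats to report per-session accuracy more precisely.
    """
    results = []
    for s in range(n_sessions):
        seed = base_seed * 1000 + 500 + s
        bundle = process_session(null_suite_config(seed))
        cfg = dataclasses.replace(fast_decoder_config(seed), n_repeats=50)
        dec = session_decoding(bundle, config=cfg, with_shuffle=False)
        lo, hi = decoding.binomial_band(dec["n_trials"], level=0.95)
        results.append({
            "seed": seed,
            "accuracy": dec["decoder"].accuracy_mean,
            "n_trials": dec["n_trials"],
            "in_band": lo <= dec["decoder"].accuracy_mean <= hi,
        })
    return results


def run_ensemble_suite(base_seed=0, n_sessions=20):
    """Ensemble-membership recovery at ensemble_frac = 1."""
    results = []
    for s in range(n_sessions):
        seed = base_seed * 1000 + 700 + s
        bundle = process_session(ensemble_suite_config(seed))
        dec = session_decoding(bundle, with_shuffle=False)
        results.append({
            "seed": seed,
            "recovery": ensemble_recovery(bundle, dec["decoder"]),
        })
    return results


def _stim_ensembles(n_per=6):
    weights = np.zeros(2 * n_per)
    weights[:n_per] = np.linspace(1.0, 0.5, n_per)
    weights[n_per:] = -np.linspace(1.0, 0.5, n_per)
    return geometry.EnsembleSelection(
        push_members=np.arange(n_per), pull_members=np.arange(n_per, 2 * n_per),
        k=n_per, ensemble_frac=1.0,
        member_weights={int(i): float(weights[i]) for i in range(2 * n_per)},
    )


def stim_suite_config(seed=0, stim_effect_g=1.5, stim_neural_effect=1.5):
    """Stimulation-session conditions: peaks near the trained 6 g threshold."""
    return simulate.SimConfig(
        n_neurons=40, n_push_exec=6, n_pull_exec=6, exec_effect=1.5,
        force_peak_range_g=(6.0, 7.5), bump_rise_range_s=(0.10, 0.14),
        bump_decay_range_s=(0.14, 0.18), stim_effect_g=stim_effect_g,
        stim_neural_effect=stim_neural_effect, seed=seed)


def run_stim_session(seed=0, n_blocks=16, stim_effect_g=1.5, stim_neural_effect=1.5):
    """One closed-loop session: simulate, align, quantify the perturbation."""
    config = stim_suite_config(seed, stim_effect_g, stim_neural_effect)
    ensembles = _stim_ensembles()
    session, truth = simulate.simulate_stim_session(config, ensembles,
                                                    n_blocks=n_blocks, seed=seed)
    filtered = signals.lowpass_filter_force(session.force, fs_hz=session.force_rate)
    stim = [r for r in session.stim_log if r.pattern != "none"]
    nostim = [r for r in session.stim_log if r.pattern == "none"]
    pairs = perturbation.align_nostim_trials(session, stim, nostim,
                                             filtered_force=filtered)
    null_pairs = perturbation.align_nostim_trials(session, nostim, nostim,
                                                  filtered_force=filtered,
                                                  on_missing="skip")
    results = perturbation.compute_force_perturbation(session, pairs,
                                                      filtered_force=filtered)
    results.update(perturbation.compute_force_perturbation(session, null_pairs,
                                                           filtered_force=filtered))
    return {"config": config, "session": session, "truth": truth,
            "ensembles": ensembles, "pairs": pairs, "null_pairs": null_pairs,
            "results": results, "filtered": filtered}


def run_stim_suite(base_seed=0, n_sessions=10, n_blocks=16, stim_effect_g=1.5,
                   stim_neural_effect=1.5):
    """Perturbation recovery over a suite of stimulation sessions."""
    sessions = []
    for s in range(n_sessions):
        sessions.append(run_stim_session(base_seed * 1000 + 300 + s, n_blocks,
                                         stim_effect_g, stim_neural_effect))
    summary = {}
    for cond in ("congruent", "non_congruent", "none"):
        vals = [r["results"][cond].end_of_stim_g for r in sessions
                if cond in r["results"]]
        summary[cond] = {
            "end_of_stim_g": float(np.mean(vals)),
            "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
            "n_sessions": len(vals),
        }
    return {"sessions": sessions, "summary": summary}


# ---------------------------------------------------------------------------
# EMG


def six_g_cross_time(force, event, fs_hz=1000.0, threshold=6.0):
    """First sample within the event interval where |force| reaches 6 g."""
    sign = 1.0 if event.identity == "push" else -1.0
    i0, i1 = int(round(event.onset_s * fs_hz)), int(round(event.offset_s * fs_hz))
    above = np.flatnonzero(sign * force[i0:i1] >= threshold)
    return (i0 + above[0]) / fs_hz if above.size else None


def emg_session_analysis(session, truth, window_s=5.0):
    """Trial-averaged EMG structure of one session.

    Z-scores each channel over the session, averages trials of each action
    locked to the 6 g cross, and runs the PC1 / modulation-variance /
    specificity analyses. The planted common-drive trace from GroundTruth is
    PETH-averaged the same way to give the recovery target.
    """
    fs = session.force_rate
    detected = ev.detect_3g_cross_actions(session.force, session.touch, fs_hz=fs,
                                          frame_rate_hz=session.frame_rate)
    six_g = [e for e in detected if e.is_6g]
    times = {ident: [t for t in (six_g_cross_time(session.force, e, fs) for e in six_g
                                 if e.identity == ident) if t is not None]
             for ident in ("push", "pull")}
    if min(len(v) for v in times.values()) < 4:
        raise ValueError("too few 6 g actions per identity for EMG analysis")

    z = (session.emg - session.emg.mean(axis=1, keepdims=True))
    z = z / session.emg.std(axis=1, keepdims=True)

    avg, per_trial, lags = {}, {}, None
    for ident, ts in times.items():
        chans, stacks = [], []
        for ch in range(4):
            peth = geometry.compute_peth(z[ch], fs, ts, window_s)
            chans.append(peth.mean)
            lags = peth.time_lags_s
        avg[ident] = np.asarray(chans)
        half = int(round(window_s * fs))
        rows = []
        for t in ts:
            c = int(round(t * fs))
            if c - half < 0 or c + half >= z.shape[1]:
                continue
            rows.append(z[:, c - half:c + half + 1])
        per_trial[ident] = np.asarray(rows)

    pc1 = emg.emg_pc1_projection(avg["push"], avg["pull"])
    drive_peth = {ident: geometry.compute_peth(truth.emg_shared_drive, fs,
                                               times[ident], window_s).mean
                  for ident in times}
    proj_cat = np.concatenate([pc1["push"], pc1["pull"]])
    drive_cat = np.concatenate([drive_peth["push"], drive_peth["pull"]])
    pc1_corr = float(np.corrcoef(proj_cat, drive_cat)[0, 1])

    modulation = emg.emg_modulation_metrics(avg["push"], avg["pull"], lags)
    specificity = emg.emg_action_specificity(per_trial["push"], per_trial["pull"],
                                             lags, seed=0)
    return {"average": avg, "lags": lags, "pc1": pc1, "pc1_corr": pc1_corr,
            "modulation": modulation, "specificity": specificity,
            "n_trials": {k: len(v) for k, v in times.items()}}


def run_emg_suite(base_seed=0, n_sessions=6):
    """EMG structure recovery over short behavior-only sessions."""
    rows = []
    for s in range(n_sessions):
        cfg = simulate.SimConfig(duration_s=300.0, n_neurons=2, n_push_exec=0,
                                 n_pull_exec=0, action_rate_per_min=5.0,
                                 force_peak_range_g=(6.5, 10.0),
                                 seed=base_seed * 1000 + 900 + s)
        session, truth = simulate.simulate_behavior_session(cfg)
        try:
            rows.append(emg_session_analysis(session, truth))
        except ValueError:
            continue
    return {
        "sessions": rows,
        "pc1_corr_mean": float(np.mean([r["pc1_corr"] for r in rows])),
        "var_average_mean": float(np.mean([r["modulation"]["var_average"] for r in rows])),
        "var_differential_mean": float(np.mean([r["modulation"]["var_differential"]
                                                for r in rows])),
    }


# ---------------------------------------------------------------------------
# summary statistics


def geometry_suite_stats(results):
    """Angle trend and timing-order statistics across a decoding suite."""
    angles_300, pooled_lags, pooled_angles = [], [], []
    order_ok, order_total = 0, 0
    for row in results:
        geo = row.get("geometry")
        if not geo:
            continue
        for lag, angle in geo["angles"].items():
            if angle is None:
                continue
            pooled_lags.append(lag)
            pooled_angles.append(angle)
            if np.isclose(lag, -0.30):
                angles_300.append(angle)
        t = geo["timings"]
        vals = [t[name] for name in TIMING_DIMS]
        if all(v is not None for v in vals):
            order_total += 1
            if vals[0] < vals[1] < vals[2] < vals[3]:
                order_ok += 1
    rho, pval = stats.spearmanr(pooled_lags, pooled_angles)
    return {
        "angle_minus300_mean": float(np.mean(angles_300)) if angles_300 else None,
        "spearman_rho": float(rho),
        "spearman_p": float(pval),
        "timing_order_fraction": order_ok / order_total if order_total else None,
        "n_timing_sessions": order_total,
    }
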