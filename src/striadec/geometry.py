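"""Decoder-dimension geometry: projections, angles, ensembles, PETHs, timing.

The decoder's weight vector, normalized to unit length, defines a population
dimension whose scalar projection w·x tracks action identity over time.
Comparing dimensions fit at different lags (principal angle), selecting the
most strongly weighted neurons into push/pull ensembles, and timing when
trial-averaged projections cross a percentile threshold together describe
how preparation- and execution-related population activity are organized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecoderDimension",
    "EnsembleSelection",
    "Peth",
    "decoder_dimension",
    "project_population",
    "subspace_angle",
    "select_ensembles",
    "compute_peth",
    "normalize_overlay",
    "activation_timing",
]


@dataclass(frozen=True)
class DecoderDimension:
    """Unit-norm decoder weight vector with its provenance lag/alignment."""

    unit_weights: np.ndarray
    source_lag_s: float = 0.0
    source_alignment: str = "peak"

    def __post_init__(self):
        w = np.asarray(self.unit_weights, dtype=float)
        object.__setattr__(self, "unit_weights", w)
        if not np.isclose(np.linalg.norm(w), 1.0, atol=1e-9):
            raise ValueError("unit_weights must have L2 norm 1")


@dataclass(frozen=True)
class EnsembleSelection:
    """Equal-size push/pull ensembles of extreme-weight neurons."""

    push_members: np.ndarray
    pull_members: np.ndarray
    k: int
    ensemble_frac: float
    member_weights: dict

    def __post_init__(self):
        push = np.asarray(self.push_members, dtype=int)
        pull = np.asarray(self.pull_members, dtype=int)
        object.__setattr__(self, "push_members", push)
        object.__setattr__(self, "pull_members", pull)
        if push.size != pull.size:
            raise ValueError("ensembles must have equal sizes")
        if np.intersect1d(push, pull).size:
            raise ValueError("ensembles must be disjoint")


@dataclass
class Peth:
    """Peri-event time histogram: trial mean ± s.e.m. on a lag grid."""

    time_lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    signal_name: str = ""


def decoder_dimension(weights, source_lag_s=0.0, source_alignment="peak"):
    """Normalize decoder weights to the unit population dimension w / ||w||."""
    w = np.asarray(getattr(weights, "weights", weights), dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("zero weight vector has no direction")
    return DecoderDimension(w / norm, source_lag_s, source_alignment)


def subspace_angle(dim_a: DecoderDimension, dim_b: DecoderDimension) -> float:
    """Principal angle in degrees between two decoder dimensions, in [0, 90].

    For one-dimensional subspaces this is arccos(|w_a · w_b|); 0° means the
    decoders use the same population dimension, 90° orthogonal ones.
    """
    wa, wb = dim_a.unit_weights, dim_b.unit_weights
    if wa.shape != wb.shape:
        raise ValueError("dimensions must have equal length")
    c = np.clip(abs(float(np.dot(wa, wb))), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def select_ensembles(decoder, ensemble_frac=1.0) -> EnsembleSelection:
    """Select the top k·ensemble_frac push- and pull-weighted neurons.

    k is the smaller of the positive- and negative-weight neuron counts;
    each ensemble takes m = max(1, floor(k·frac)) neurons with the most
    extreme weights of its sign, so the two ensembles have equal size and
    never intersect.
    """
    w = np.asarray(getattr(decoder, "weights", decoder), dtype=float)
    pos = np.flatnonzero(w > 0)
    neg = np.flatnonzero(w < 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both positive and negative weights to form ensembles")
    k = int(min(pos.size, neg.size))
    m = max(1, int(np.floor(k * ensemble_frac)))
    push = pos[np.argsort(-w[pos], kind="stable")][:m]
    pull = neg[np.argsort(w[neg], kind="stable")][:m]
    members = np.concatenate([push, pull])
    return EnsembleSelection(
        push_members=np.sort(push), pull_members=np.sort(pull), k=k,
        ensemble_frac=float(ensemble_frac),
        member_weights={int(i): float(w[i]) for i in members},
    )


def compute_peth(signal, fs_hz, event_times, window_s, signal_name="") -> Peth:
    """Stack a uniformly sampled signal around events; mean and s.e.m. per lag.

    ``window_s`` is the half-width: lags run from -window_s to +window_s at
    the signal's own sampling rate. Events whose window exits the trace are
    dropped; raises if none remain. The s.e.m. uses the n-1 denominator.
    """
    signal = np.asarray(signal, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    half = int(round(window_s * fs_hz))
    lags = np.arange(-half, half + 1) / fs_hz
    rows = []
    for t in event_times:
        c = int(round(t * fs_hz))
        if c - half < 0 or c + half >= signal.size:
            continue
        rows.append(signal[c - half:c + half + 1])
    if not rows:
        raise ValueError("no events with a full window inside the trace")
    stack = np.asarray(rows)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(stack.shape[1])
    return Peth(time_lags_s=lags, mean=stack.mean(axis=0), sem=sem,
                n_trials=n, signal_name=signal_name)


def project_population(dff_z, frame_times, dim: DecoderDimension, events,
                       window_s, reference="peak"):
    """PETH of the scalar projection w·x(t), split by action identity.

    Returns a dict identity -> Peth on the imaging frame grid.
    """
    dff_z = np.asarray(dff_z, dtype=float)
    if dim.unit_weights.size != dff_z.shape[0]:
        raise ValueError("dimension length must equal neuron count")
    frame_times = np.asarray(frame_times, dtype=float)
    frame_rate = 1.0 / np.median(np.diff(frame_times))
    proj = dim.unit_weights @ dff_z
    attr = "peak_s" if reference == "peak" else "cross3g_s"
    out = {}
    for ident in sorted({e.identity for e in events}):
        times = [getattr(e, attr) - frame_times[0] for e in events if e.identity == ident]
        out[ident] = compute_peth(proj, frame_rate, times, window_s,
                                  signal_name=f"svm_projection_{ident}")
    return out


def normalize_overlay(series, lags, reference_lag_s):
    """Affine-normalize a per-lag series: reference lag -> 0, window max -> 1."""
    series = np.asarray(series, dtype=float)
    lags = np.asarray(lags, dtype=float)
    idx = np.argmin(np.abs(lags - reference_lag_s))
    if not np.isclose(lags[idx], reference_lag_s):
        raise ValueError("reference lag is not on the lag grid")
    ref = series[idx]
    span = series.max() - ref
    if span == 0:
        raise ValueError("series is flat between reference and maximum; cannot normalize")
    return (series - ref) / span


def activation_timing(peth: Peth, percentile=0.99, window_s=2.0, center_s=0.0,
                      negate=False):
    """First upward crossing of a percentile threshold of the trial-mean trace.

    The threshold is the given percentile of the mean values inside a
    ``window_s``-wide window centered at ``center_s`` (the force peak).
    Pull projections are negated upstream of the threshold (they deflect
    downward by the push-positive convention). Returns the crossing lag in
    seconds, or None when the trace never crosses from below (flat series).
    """
    lags = peth.time_lags_s
    m = -peth.mean if negate else peth.mean
    sel = (lags >= center_s - window_s / 2) & (lags <= center_s + window_s / 2)
    if not sel.any():
        raise ValueError("timing window lies outside the PETH grid")
    mw = m[sel]
    lw = lags[sel]
    thr = np.quantile(mw, percentile)
    below = mw < thr
    for i in range(1, mw.size):
        if below[i - 1] and mw[i] >= thr:
            # sub-sample crossing time by linear interpolation between bins
            frac = (thr - mw[i - 1]) / (mw[i] - mw[i - 1])
            return float(lw[i - 1] + frac * (lw[i] - lw[i - 1]))
    return None
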