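"""Shared versus action-specific muscle activation from 4-channel EMG.

Both isometric actions engage overlapping flexor/extensor co-contractions,
so most EMG variance is a common drive shared across muscles and actions.
These analyses quantify that structure: the dominant principal component of
trial-averaged EMG across both actions, average vs differential modulation
(half the push-pull difference), and across-action vs within-action
(split-half) vector distances around the 6 g crossing.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "emg_pc1_projection",
    "emg_modulation_metrics",
    "emg_action_specificity",
]


def emg_pc1_projection(push_avg, pull_avg, event_index=None):
    """First principal component of trial-averaged EMG over both actions.

    ``push_avg``/``pull_avg`` are 4 x samples trial-averaged matrices on the
    same lag grid. They are concatenated along time (4 muscles x 2·samples),
    PC1 is extracted over the muscle dimension, and each action's matrix is
    projected onto it. The component is signed so the mean projection at the
    event sample (grid center by default) is non-negative.

    Returns dict with 'weights' (4,), 'push', 'pull' projections and
    'explained_variance_ratio'.
    """
    push_avg = np.atleast_2d(np.asarray(push_avg, dtype=float))
    pull_avg = np.atleast_2d(np.asarray(pull_avg, dtype=float))
    if push_avg.shape != pull_avg.shape or push_avg.shape[0] != 4:
        raise ValueError("expected matched 4 x samples matrices for both actions")
    X = np.concatenate([push_avg, pull_avg], axis=1)  # 4 x (2*samples)
    if np.allclose(X, X.mean(axis=1, keepdims=True)):
        raise ValueError("EMG matrix has no variance; PC1 undefined")
    pca = PCA(n_components=1)
    pca.fit(X.T)
    w = pca.components_[0]
    center = push_avg.shape[1] // 2 if event_index is None else event_index
    mu = X.mean(axis=1)
    if (w @ (push_avg[:, center] - mu)) + (w @ (pull_avg[:, center] - mu)) < 0:
        w = -w
    return {
        "weights": w,
        "push": w @ (push_avg - mu[:, None]),
        "pull": w @ (pull_avg - mu[:, None]),
        "explained_variance_ratio": float(pca.explained_variance_ratio_[0]),
    }


def emg_modulation_metrics(push_avg, pull_avg, lags_s, window_s=0.4):
    """Average and differential modulation traces and their variances.

    average = mean of the two actions per channel; differential = half the
    push - pull difference. Variances are computed per channel over the
    ``window_s`` window centered on the event and summarized by their mean.
    """
    push_avg = np.atleast_2d(np.asarray(push_avg, dtype=float))
    pull_avg = np.atleast_2d(np.asarray(pull_avg, dtype=float))
    lags_s = np.asarray(lags_s, dtype=float)
    if push_avg.shape != pull_avg.shape or push_avg.shape[1] != lags_s.size:
        raise ValueError("action matrices must share the lag grid")
    sel = (lags_s >= -window_s / 2) & (lags_s <= window_s / 2)
    if not sel.any():
        raise ValueError("analysis window lies outside the lag grid")
    average = 0.5 * (push_avg + pull_avg)
    differential = 0.5 * (push_avg - pull_avg)
    var_avg = average[:, sel].var(axis=1)
    var_diff = differential[:, sel].var(axis=1)
    return {
        "average": average,
        "differential": differential,
        "var_average_per_channel": var_avg,
        "var_differential_per_channel": var_diff,
        "var_average": float(var_avg.mean()),
        "var_differential": float(var_diff.mean()),
    }


def _trial_vectors(per_trial_emg, lags_s, window_s):
    sel = (lags_s >= -window_s / 2) & (lags_s <= window_s / 2)
    if not sel.any():
        raise ValueError("analysis window lies outside the lag grid")
    return per_trial_emg[:, :, sel].mean(axis=2)  # trials x 4


def emg_action_specificity(push_trials, pull_trials, lags_s, window_s=0.1,
                           n_resamples=1000, seed=0):
    """Across-action vs within-action EMG vector distances.

    Each trial is reduced to the 4-vector of mean EMG over ``window_s``
    around the 6 g cross. The across-action distance is the magnitude of the
    difference between action means; the within-action distance is the
    magnitude of the difference between the means of two random halves of one
    action's trials. Both come with resampling distributions (trials are
    re-split / resampled ``n_resamples`` times with a fixed seed).
    """
    push_trials = np.asarray(push_trials, dtype=float)
    pull_trials = np.asarray(pull_trials, dtype=float)
    lags_s = np.asarray(lags_s, dtype=float)
    if push_trials.shape[0] < 4 or pull_trials.shape[0] < 4:
        raise ValueError("need >= 4 trials per action for split halves")
    va = _trial_vectors(push_trials, lags_s, window_s)
    vb = _trial_vectors(pull_trials, lags_s, window_s)
    rng = np.random.default_rng(seed)

    def half_split_distance(v):
        idx = rng.permutation(v.shape[0])
        half = v.shape[0] // 2
        return float(np.linalg.norm(v[idx[:half]].mean(axis=0)
                                    - v[idx[half:2 * half]].mean(axis=0)))

    across = float(np.linalg.norm(va.mean(axis=0) - vb.mean(axis=0)))
    across_dist = np.empty(n_resamples)
    within_dist = np.empty(n_resamples)
    for i in range(n_resamples):
        ia = rng.integers(0, va.shape[0], va.shape[0])
        ib = rng.integers(0, vb.shape[0], vb.shape[0])
        across_dist[i] = np.linalg.norm(va[ia].mean(axis=0) - vb[ib].mean(axis=0))
        within_dist[i] = half_split_distance(va if i % 2 == 0 else vb)
    return {
        "across_action": across,
        "across_distribution": across_dist,
        "within_distribution": within_dist,
        "within_median": float(np.median(within_dist)),
    }
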