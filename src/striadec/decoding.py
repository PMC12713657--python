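"""Linear decoding of action identity from single-trial population activity.

Each trial is the per-neuron mean of z-scored ΔF/F0 over a 5-frame (~167 ms)
window centered at a configurable lag relative to an alignment event (force
peak or 3 g cross). A linear max-margin classifier (LinearSVC) predicts push
vs pull on repeated stratified 90/10 splits, with the regularization
strength selected by inner cross-validation on each training set and
classes weighted by 1/(class trial count). A shuffle control refits the
same pipeline on permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import LinearSVC

__all__ = [
    "TrialMatrix",
    "DecoderConfig",
    "Decoder",
    "extract_trial_vectors",
    "fit_action_decoder",
    "decode_time_course",
    "matched_celltype_decoding",
    "binomial_band",
]

_MAX_SEED = 2**31 - 1


@dataclass
class TrialMatrix:
    """Trials x neurons activity vectors with action labels."""

    vectors: np.ndarray
    labels: np.ndarray
    lag_s: float
    alignment: str
    neuron_ids: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.vectors.ndim != 2 or self.vectors.shape[1] < 1:
            raise ValueError("vectors must be trials x neurons with >=1 neuron")
        if self.labels.shape[0] != self.vectors.shape[0]:
            raise ValueError("labels length must equal trial count")


@dataclass(frozen=True)
class DecoderConfig:
    """Training protocol: repeated stratified splits with inner C selection."""

    n_repeats: int = 100
    test_fraction: float = 0.10
    n_subfolds: int = 10
    regularization_grid: tuple = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
    min_trials_per_class: int = 20
    min_neurons: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if not self.regularization_grid:
            raise ValueError("regularization grid must be non-empty")


@dataclass
class Decoder:
    """Fitted action-identity classifier and its cross-validated accuracies.

    ``weights`` come from a final fit on all trials at the modal selected
    regularization, oriented so positive weights favor push. Pooled accuracy
    is total correct / total held-out predictions, so the per-action
    accuracies weighted by their prediction counts reproduce it exactly.
    """

    weights: np.ndarray
    intercept: float
    chosen_regularization: float
    accuracy_mean: float
    accuracy_per_action: dict
    accuracy_sd: float
    weights_z: np.ndarray
    repeat_accuracies: np.ndarray
    test_counts_per_action: dict
    n_trials_per_action: dict
    config: DecoderConfig = field(repr=False, default=None)

    @property
    def classes(self):
        return tuple(sorted(self.n_trials_per_action))


def extract_trial_vectors(dff_z, frame_times, events, lag_s, alignment="peak",
                          window_frames=5):
    """Mean activity in a ``window_frames`` window centered at event time + lag.

    Events whose window exits the session are dropped; raises if none survive.
    """
    dff_z = np.asarray(dff_z, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if alignment not in ("peak", "cross"):
        raise ValueError("alignment must be 'peak' or 'cross'")
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be a positive odd count")
    attr = "peak_s" if alignment == "peak" else "cross3g_s"
    frame_rate = 1.0 / np.median(np.diff(frame_times))
    half = window_frames // 2
    n_frames = dff_z.shape[1]
    vectors, labels = [], []
    for e in events:
        t = getattr(e, attr) + lag_s
        idx = int(round((t - frame_times[0]) * frame_rate))
        if idx - half < 0 or idx + half >= n_frames:
            continue
        vectors.append(dff_z[:, idx - half:idx + half + 1].mean(axis=1))
        labels.append(e.identity)
    if not vectors:
        raise ValueError("no trials survive window extraction")
    return TrialMatrix(
        vectors=np.asarray(vectors), labels=np.asarray(labels),
        lag_s=lag_s, alignment=alignment, neuron_ids=np.arange(dff_z.shape[0]),
    )


def _class_weights(y):
    classes, counts = np.unique(y, return_counts=True)
    return {c: 1.0 / n for c, n in zip(classes, counts)}


def _make_svc(C, class_weight):
    # large intercept_scaling leaves the intercept effectively unpenalized,
    # keeping accuracy invariant to common affine rescaling of the features
    return LinearSVC(C=C, class_weight=class_weight, dual=False, tol=1e-4,
                     max_iter=5000, intercept_scaling=100.0)


def _select_C(X, y, grid, n_subfolds, seed):
    """Inner cross-validation over the regularization grid (ties -> smaller C)."""
    skf = StratifiedKFold(n_splits=n_subfolds, shuffle=True, random_state=seed)
    best_C, best_acc = None, -1.0
    folds = list(skf.split(X, y))
    for C in sorted(grid):
        accs = []
        for tr, va in folds:
            clf = _make_svc(C, _class_weights(y[tr]))
            clf.fit(X[tr], y[tr])
            accs.append(np.mean(clf.predict(X[va]) == y[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_C = acc, C
    return best_C


def _one_repeat(X, y, config, seed):
    """One stratified 90/10 split with inner C selection; per-class test tallies."""
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.test_fraction, stratify=y, random_state=seed)
    C = _select_C(X_tr, y_tr, config.regularization_grid, config.n_subfolds, seed)
    clf = _make_svc(C, _class_weights(y_tr))
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    correct = {c: int(np.sum((y_te == c) & (pred == c))) for c in np.unique(y)}
    total = {c: int(np.sum(y_te == c)) for c in np.unique(y)}
    return C, correct, total


def _validate_trials(trials, config):
    classes, counts = np.unique(trials.labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need two action classes to fit a decoder")
    if counts.min() < config.min_trials_per_class:
        raise ValueError(
            f"need >= {config.min_trials_per_class} trials per action "
            f"(got {dict(zip(classes, counts))})")
    if trials.vectors.shape[1] < config.min_neurons:
        raise ValueError(f"need >= {config.min_neurons} neurons")
    return classes, counts


def fit_action_decoder(trials: TrialMatrix, config: DecoderConfig = None,
                       shuffle: bool = False) -> Decoder:
    """Fit the repeated-split linear decoder; ``shuffle`` permutes labels per repeat."""
    config = config or DecoderConfig()
    classes, counts = _validate_trials(trials, config)
    X = trials.vectors
    rng = np.random.default_rng(config.seed)
    chosen, rep_acc = [], []
    correct_tot = {c: 0 for c in classes}
    count_tot = {c: 0 for c in classes}
    for r in range(config.n_repeats):
        seed_r = int((config.seed * 100003 + 7919 * r) % _MAX_SEED)
        y = rng.permutation(trials.labels) if shuffle else trials.labels
        C, correct, total = _one_repeat(X, y, config, seed_r)
        chosen.append(C)
        rep_acc.append(sum(correct.values()) / sum(total.values()))
        for c in classes:
            correct_tot[c] += correct.get(c, 0)
            count_tot[c] += total.get(c, 0)

    # modal C over repeats (ties -> smaller C) for the final all-data fit
    vals, freq = np.unique(chosen, return_counts=True)
    modal_C = float(vals[np.lexsort((vals, -freq))][0])
    y_final = rng.permutation(trials.labels) if shuffle else trials.labels
    clf = _make_svc(modal_C, _class_weights(y_final))
    clf.fit(X, y_final)
    w = clf.coef_.ravel().astype(float).copy()
    b = float(clf.intercept_[0])
    if "push" in clf.classes_ and clf.classes_[1] != "push":
        w, b = -w, -b  # orient: positive decision score predicts push
    w_sd = w.std()
    weights_z = (w - w.mean()) / w_sd if w_sd > 0 else np.zeros_like(w)

    total_preds = sum(count_tot.values())
    per_action = {c: correct_tot[c] / count_tot[c] for c in classes}
    return Decoder(
        weights=w, intercept=b, chosen_regularization=modal_C,
        accuracy_mean=sum(correct_tot.values()) / total_preds,
        accuracy_per_action=per_action,
        accuracy_sd=float(np.std(rep_acc)),
        weights_z=weights_z,
        repeat_accuracies=np.asarray(rep_acc),
        test_counts_per_action=dict(count_tot),
        n_trials_per_action={c: int(n) for c, n in zip(classes, counts)},
        config=config,
    )


def _select_events(events, lag_s, lag0_rule):
    """Trial-selection rule of the time course: isolation matched to lag sign."""
    if lag_s < 0:
        return [e for e in events if e.pre_isolated]
    if lag_s > 0:
        return [e for e in events if e.post_isolated]
    rules = {
        "pre": lambda e: e.pre_isolated,
        "post": lambda e: e.post_isolated,
        "either": lambda e: e.pre_isolated or e.post_isolated,
        "both": lambda e: e.pre_isolated and e.post_isolated,
    }
    return [e for e in events if rules[lag0_rule](e)]


def decode_time_course(dff_z, frame_times, events, lags, alignment="peak",
                       config: DecoderConfig = None, with_shuffle=True,
                       lag0_rule="both", window_frames=5):
    """Decoding accuracy as a function of time lag around the action.

    Negative lags use pre-isolated trials, positive lags post-isolated ones;
    lag 0 follows ``lag0_rule``. Lags with too few trials are reported as
    missing (None) rather than fabricated.

    Returns a dict lag -> {'accuracy', 'shuffle', 'n_trials', 'decoder'}.
    """
    config = config or DecoderConfig()
    force_events = [e for e in events if e.is_force_action]
    if any(e.pre_isolated is None for e in force_events):
        raise ValueError("events must carry isolation flags (run flag_isolation)")
    out = {}
    for lag in lags:
        selected = _select_events(force_events, lag, lag0_rule)
        entry = {"accuracy": None, "shuffle": None, "n_trials": len(selected),
                 "decoder": None}
        try:
            trials = extract_trial_vectors(dff_z, frame_times, selected, lag,
                                           alignment, window_frames)
            dec = fit_action_decoder(trials, config)
            entry.update(accuracy=dec.accuracy_mean, decoder=dec,
                         n_trials=trials.vectors.shape[0])
            if with_shuffle:
                sh = fit_action_decoder(trials, config, shuffle=True)
                entry["shuffle"] = sh.accuracy_mean
        except ValueError:
            pass  # insufficient trials at this lag: reported missing
        out[float(lag)] = entry
    return out


def matched_celltype_decoding(trials: TrialMatrix, celltype_labels,
                              config: DecoderConfig = None):
    """Decode separately per cell type with matched neuron counts.

    For the more numerous cell type an independent random neuron subset of the
    other type's size is drawn in every repeat, so both accuracies reflect the
    same population size.
    """
    config = config or DecoderConfig()
    celltype_labels = np.asarray(celltype_labels)
    types, type_counts = np.unique(celltype_labels, return_counts=True)
    if types.size != 2:
        raise ValueError("exactly two cell types are required")
    if type_counts.min() < config.min_neurons:
        raise ValueError(f"each cell type needs >= {config.min_neurons} neurons")
    _validate_trials(trials, config)
    n_match = int(type_counts.min())
    rng = np.random.default_rng(config.seed)
    results = {}
    for ct in types:
        members = np.flatnonzero(celltype_labels == ct)
        accs = []
        for r in range(config.n_repeats):
            seed_r = int((config.seed * 99991 + 6299 * r + hash(str(ct)) % 1000) % _MAX_SEED)
            subset = (rng.choice(members, n_match, replace=False)
                      if members.size > n_match else members)
            X = trials.vectors[:, subset]
            _, correct, total = _one_repeat(X, trials.labels, config, seed_r)
            accs.append(sum(correct.values()) / sum(total.values()))
        results[str(ct)] = {
            "accuracy_mean": float(np.mean(accs)),
            "repeat_accuracies": np.asarray(accs),
            "n_neurons_used": n_match,
        }
    return results


def binomial_band(n, level=0.95, p=0.5):
    """Two-sided binomial acceptance band for an accuracy at chance ``p``."""
    from scipy import stats

    lo, hi = stats.binom.interval(level, n, p)
    return lo / n, hi / n
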