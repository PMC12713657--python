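"""Greedy covariate matching of push and pull trial sets.

Before asking whether neural activity distinguishes two actions, the trial
sets are equated on behavioral covariates (average force, peak force,
two-axis force magnitude at peak, duration, licking) by iteratively
discarding trials from the larger set until every feature's mean difference
is inside its tolerance.

The removal rule: z-score features with pooled statistics, take the target
direction mean(action 1) - mean(action 2) where action 1 is the smaller set,
zero the components already within tolerance (in native units), and drop the
action-2 trial whose feature vector has the smallest dot product with the
target — the trial pulling action 2 farthest away from action 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MatchSpec", "MatchResult", "match_trials", "filter_reward_adjacent",
           "DEFAULT_TOLERANCES"]

#: native-unit tolerances used in the analyses (grams, seconds, Hz, probability)
DEFAULT_TOLERANCES = {
    "average_force_g": 0.1,
    "peak_force_g": 0.1,
    "two_axis_peak_magnitude_g": 0.2,
    "duration_s": 0.030,
    "lick_rate_hz": 0.5,
    "lick_probability": 0.1,
}


@dataclass(frozen=True)
class MatchSpec:
    """Feature names (column order) and per-feature native-unit tolerances."""

    features: tuple
    tolerances: dict

    def __post_init__(self):
        if not self.features:
            raise ValueError("feature set must be non-empty")
        missing = [f for f in self.features if f not in self.tolerances]
        if missing:
            raise ValueError(f"missing tolerances for {missing}")
        if any(self.tolerances[f] <= 0 for f in self.features):
            raise ValueError("tolerances must be positive")

    @classmethod
    def default(cls, features=None):
        feats = tuple(features) if features else tuple(DEFAULT_TOLERANCES)
        return cls(feats, dict(DEFAULT_TOLERANCES))


@dataclass
class MatchResult:
    kept_a: list
    kept_b: list
    removed_a: list = field(default_factory=list)  # in removal order
    removed_b: list = field(default_factory=list)
    final_differences: dict = field(default_factory=dict)
    n_iterations: int = 0

    @property
    def converged(self) -> bool:
        return True  # match_trials raises instead of returning a failed result


def match_trials(features_a, features_b, spec: MatchSpec) -> MatchResult:
    """Iteratively remove trials until all feature means match within tolerance.

    ``features_a``/``features_b`` are trials x features arrays in the column
    order of ``spec.features``. Raises ``ValueError`` (naming the worst
    feature) if either action would be exhausted before convergence.
    """
    fa = np.atleast_2d(np.asarray(features_a, dtype=float))
    fb = np.atleast_2d(np.asarray(features_b, dtype=float))
    if fa.shape[1] != len(spec.features) or fb.shape[1] != len(spec.features):
        raise ValueError("feature columns must match spec.features")
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least 2 trials per action")
    if not (np.isfinite(fa).all() and np.isfinite(fb).all()):
        raise ValueError("features must be finite")

    tol = np.array([spec.tolerances[f] for f in spec.features])
    pooled = np.vstack([fa, fb])
    mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # zero-variance feature: unit denominator
    za, zb = (fa - mu) / sd, (fb - mu) / sd

    kept = {"a": list(range(fa.shape[0])), "b": list(range(fb.shape[0]))}
    removed = {"a": [], "b": []}
    data = {"a": (fa, za), "b": (fb, zb)}
    max_iter = fa.shape[0] + fb.shape[0]

    for it in range(max_iter + 1):
        mean_a = fa[kept["a"]].mean(axis=0)
        mean_b = fb[kept["b"]].mean(axis=0)
        diff = mean_a - mean_b
        within = np.abs(diff) <= tol
        if within.all():
            return MatchResult(
                kept_a=kept["a"], kept_b=kept["b"],
                removed_a=removed["a"], removed_b=removed["b"],
                final_differences=dict(zip(spec.features, diff)),
                n_iterations=it,
            )
        # action 1 = fewer kept trials (ties go to a), action 2 = the other
        one, two = ("a", "b") if len(kept["a"]) <= len(kept["b"]) else ("b", "a")
        _, z1 = data[one]
        _, z2 = data[two]
        target = z1[kept[one]].mean(axis=0) - z2[kept[two]].mean(axis=0)
        target = np.where(within, 0.0, target)
        if len(kept[two]) <= 2:
            worst = spec.features[int(np.argmax(np.abs(diff) / tol))]
            raise ValueError(
                f"matching infeasible: action '{two}' exhausted before feature "
                f"'{worst}' reached tolerance"
            )
        dots = z2[kept[two]] @ target
        drop = kept[two][int(np.argmin(dots))]  # argmin takes lowest index on ties
        kept[two].remove(drop)
        removed[two].append(drop)

    raise RuntimeError("matching failed to terminate (internal error)")


def filter_reward_adjacent(cross_times, solenoid_times, min_gap_s=4.0):
    """Mask of trials whose crossing is >= ``min_gap_s`` after any solenoid opening.

    Used to exclude sucrose-consumption-contaminated trials before matching.
    """
    cross_times = np.asarray(cross_times, dtype=float)
    solenoid_times = np.asarray(solenoid_times, dtype=float)
    keep = np.ones(cross_times.size, dtype=bool)
    for i, t in enumerate(cross_times):
        prior = solenoid_times[(solenoid_times < t)]
        if prior.size and (t - prior.max()) < min_gap_s:
            keep[i] = False
    return keep
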