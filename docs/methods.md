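# Methods

`striadec` analyzes how striatal population activity encodes and controls
two minimally different isometric forelimb actions — push and pull forces on
an immobile joystick — and validates every analysis step as a
parameter-recovery problem on a synthetic session generator with planted
ground truth. This note documents the generative model, the analysis
conventions, the numerical choices, and what the synthetic validation does
and does not establish.

## The synthetic session

A session is a set of synchronized streams sharing one time origin:
joystick force (1 kHz, grams, push positive / pull negative), a second
lateral force axis, a binary joystick-touch stream, lick times, 4-channel
EMG envelopes (1 kHz), and two-photon fluorescence (raw + neuropil,
30 Hz, neurons × frames) with D1/D2 cell-type labels.

**Behavior.** Self-paced actions arrive as a renewal process with a 2 s
refractory gap (enforcing the task's 1 s inter-trial quiescence around a
0.2–0.43 s force bump) plus an exponential tail calibrated so the mean rate
equals `action_rate_per_min` per action (default 5/min). Identity is
Bernoulli(`push_preference`). Each action writes a raised-cosine force
bump — rise 90–180 ms, decay 110–250 ms, a unique peak at the junction —
with signed peak magnitude drawn from `force_peak_range_g` (default
6–12 g). Baseline force is zero-mean Gaussian noise smoothed with a 30 ms
kernel and scaled to 0.25 g SD, small enough that noise alone never crosses
3 g. Touch activates 150 ms before each bump onset through 200 ms past its
end (guaranteeing the 100 ms touch lead the 3 g cross detector requires);
additional 1.3–2.5 s low-force touch periods are placed in quiet gaps.
Every action is followed, 0.5 s after the force peak, by a 6-lick bout at
0.12 s spacing.

Ground truth records each planted event's onset and its 3 g-cross and
force-peak times *measured on the composed, noise-included trace*, using
the same convention as the detector (below). Recovery tests therefore ask
whether the detector finds the trace's own events, not whether it undoes
the noise.

**Calcium activity.** Each neuron fires discrete calcium events from an
inhomogeneous Poisson rate: a heterogeneous baseline
(`base_rate_hz` × U(0.5, 1.5), default 0.2 Hz) plus Gaussian rate bumps
(SD 60 ms) tied to planted events. Execution-ensemble neurons bump at
their action's force peak; preparation-ensemble neurons bump at a
per-neuron lead time before the 3 g cross. Event counts are convolved
with an exponential kernel (decay `calcium_decay_s`, default 0.2 s,
GCaMP6f-like), scaled into raw fluorescence
F_raw = F₀·(1 + ΔF) + 0.7·F_neuropil + noise with per-neuron baselines
F₀ ~ U(80, 120), a slow sinusoidal neuropil channel, and Gaussian noise
(SD = 0.1·F₀ per frame). The effect parameters are expressed in session
z-units: an internal scale (2.7 added events/s per unit effect at the bump
peak) is calibrated once so that the trial-window response of a planted
neuron, measured in session-z-scored ΔF/F₀, approximately equals the
requested `exec_effect`. With the defaults, `exec_effect = 1.5` produces
≈1.4–1.6 z evoked responses.

**Preparation leads.** The preparation ensemble of each action tiles a
spectrum of lead times: member leads are evenly spaced over
`prep_lead_s` × (1 ± 0.85) (default 45–555 ms, mean 300 ms) with ±5%
jitter, recorded in `GroundTruth.timing_offsets`. A single shared lead
would make decoders fit 140 ms and 70 ms before the cross identical by
construction (identical instantaneous signal-to-noise profiles), leaving
the early-vs-late preparation distinction undefined; a graded spectrum is
the minimal generative structure under which preparation timing is a
recoverable quantity, and is consistent with the long-timescale
preparatory dynamics the analyses target.

**EMG.** Four channels mix a shared co-contraction drive (sum of
unit-peak bump shapes over all actions, gain 3 by default) and a signed
differential drive (gain 1), with per-channel loadings, smoothed noise
(SD 0.3), and a positive offset. The planted drives are stored in the
ground truth so the principal-component analysis can be scored against
them. Session EMG is generated directly at 1 kHz as conditioned
envelopes — the output of the conditioning chain — while the chain itself
(24 kHz → 1 kHz, 40 Hz zero-phase high-pass, rectification, 25 ms-SD
Gaussian smoothing) is verified on constructed analytic signals.

**Stimulation sessions.** Trials follow the scheduled 6-trial block
(no stim, push-triggered stim, no stim, no stim, pull-triggered stim,
no stim) at 3.5 s spacing (2 s inter-trial interval plus an action
window); the stimulated-ensemble pattern alternates congruent /
non-congruent across blocks so any two consecutive blocks cover all six
trigger × pattern conditions. No-stim slots carry fixed identities
(push, pull, pull, push per block) so every stim trial has an eligible
preceding same-identity comparison trial. Stimulation begins 2 ms after
the 3 g crossing and lasts 100 ms. On stimulation trials the targeted
ensemble receives an added fluorescence transient (amplitude
`stim_neural_effect`, boxcar ⊗ calcium kernel, peak-normalized); on
*congruent* trials the force trace additionally gains `stim_effect_g` in
the ongoing action's direction — ramping up over 80 ms, holding through
the end of the 100 ms window, then decaying over 150 ms — so the planted
end-of-stimulation amplitude equals `stim_effect_g` exactly.

## Signal conditioning

- Force calibration: grams vs (volts − baseline) least squares through
  the origin; the no-load reading defines the baseline, so the fit has no
  intercept. RMS residual reported.
- ΔF/F₀: F_corrected = F_raw − 0.7·F_neuropil; F₀ is a centered
  one-minute running median (forced to odd length; truncated windows at
  the session edges avoid startup transients); ΔF/F₀ z-scored per neuron
  over the session, with zero-variance neurons mapped to 0 rather than NaN.
- All filters are zero-phase (forward–backward): analyses align signals
  to event times, and single-pass filters would shift them. The force
  low-pass is a 30 Hz 10th-order Butterworth; the EMG high-pass a 40 Hz
  4th-order Butterworth (the order is a package choice; only the cutoff
  is dictated by the conditioning recipe). Zero-phase application doubles
  attenuation in dB — the single-pass −3 dB cutoff becomes −6 dB.

## Event detection

Threshold (task) actions are maximal intervals with signed force above a
threshold for at least the minimum duration. 3 g cross actions are
detected on a 30 Hz block-averaged trace (frame k averages samples
⌊k·fs/fr⌋ … ⌊(k+1)·fs/fr⌋): ≥2 consecutive frames at ≥3 g in one
direction, with touch active for the full 100 ms before the 1 kHz
crossing. The crossing is defined as the first sample of the contiguous
suprathreshold segment that contains the force peak — this anchors the
event to its peak and is robust to noise chatter at the threshold; the
peak takes the earliest sample on ties. Events peaking above 6 g are
flagged. Isolation flags (no other force action's reference time within
0.5 s before/after) default to the force-peak reference with the crossing
selectable. Touch events are contact intervals under 2 g lasting over
1 s; lick bouts are ≥5 licks with inter-lick intervals under 0.5 s,
discarded when overlapping a 3 g cross interval; both align to their
interval midpoint.

## Trial matching

Push and pull trial sets are equated on behavioral covariates by greedy
removal: z-score features with pooled statistics (zero-variance features
get a unit denominator), define action 1 as the smaller set each
iteration, zero the components already within their native-unit
tolerances, and remove the action-2 trial with the smallest dot product
onto mean(action 1) − mean(action 2) — the trial pulling action 2
farthest from action 1, the only sign convention under which the
iteration converges. Ties remove the lowest-index trial. Default
tolerances: average force 0.1 g, peak force 0.1 g, two-axis magnitude at
peak 0.2 g, duration 30 ms, lick rate 0.5 Hz, lick probability 0.1. An
optional pre-filter drops trials whose crossing follows a solenoid
opening by less than 4 s. Minimal-removal optimality is not attempted;
on small single-feature instances the greedy solution is verified against
exhaustive search over equal-size removal sets.

## Decoding

Trial vectors are per-neuron means of z-scored ΔF/F₀ over 5 frames
(~167 ms) centered at the alignment time (force peak or 3 g cross) plus a
lag; trials whose window leaves the session are dropped. Sessions must
supply ≥20 trials per action and ≥10 neurons.

The classifier is a linear SVM (squared hinge, L2, liblinear primal) with
per-class weights 1/(class trial count) and `intercept_scaling = 100` so
the intercept is effectively unpenalized — without this, accuracy is not
invariant to a common affine rescaling of the features. Protocol: for
each repeat, a stratified 90/10 split; the regularization constant C is
chosen on the training set by stratified sub-fold cross-validation over a
logarithmic grid (ties to the smaller C); accuracy is pooled over all
held-out predictions, so the per-action accuracies weighted by their
prediction counts reproduce the overall accuracy exactly. The reported
weight vector refits all trials at the modal selected C, oriented so
positive weights vote push. Shuffle controls permute labels independently
per repeat. Defaults follow the full protocol (100 repeats, 10 sub-folds,
7-point grid 10⁻³…10³); the study suites use 25 repeats / 5 sub-folds /
4-point grid for the headline decoder and 10 repeats / 3-point grid for
per-lag sweeps — protocol unchanged, split counts scaled to the suite
size. The time-course analysis uses pre-isolated trials at negative lags,
post-isolated at positive lags, and (configurably) trials isolated both
ways at lag 0; lags with too few trials are reported missing.
Cell-type-matched decoding subsamples the more numerous type to the other
type's count independently in every repeat.

Chance bands are binomial intervals evaluated at the number of *distinct*
trials, not the number of held-out predictions: predictions across
repeats reuse trials and are strongly dependent.

## Decoder geometry

The decoder dimension is the weight vector divided by its L2 norm;
population activity projected on it gives a scalar action score
(push-positive). The angle between two decoder dimensions is
arccos |w_a·w_b| ∈ [0°, 90°] — for one-dimensional subspaces this equals
the principal subspace angle, and the implementation is cross-checked
against `scipy.linalg.subspace_angles` in the tests. Ensembles take the
top m = max(1, ⌊k·ensemble_frac⌋) positive- and negative-weight neurons,
with k the smaller of the positive/negative counts (floor-with-minimum-1
is the package's rounding choice). PETHs stack a uniformly sampled signal
around events and report mean ± s.e.m. (n−1 denominator). Activation
timing is the first upward crossing of the trial-averaged trace through
its 99th percentile (90th for ensemble activity) within a 2 s window
centered on the force peak, with pull projections negated; the crossing
time is linearly interpolated between samples, giving sub-frame
resolution, and a never-crossing (flat) trace is reported missing rather
than fabricated. The accuracy/force overlay normalization maps the
reference lag to 0 and the window maximum to 1 and errors on flat series.

## Closed-loop perturbation

Force is 30 Hz low-pass filtered (10th-order Butterworth, zero-phase)
before comparison. For each stimulation trial, eligible comparison trials
are the preceding no-stim trials of the same triggering action, excluding
any closer in time to the previous stimulation than to the next. Because
stimulation latency varies, the no-stim trial is time-shifted: candidate
alignment points span its action interval ±100 ms, and the chosen point
minimizes the Euclidean distance between the 2-vector (instantaneous
filtered force, mean filtered force over the preceding 100 ms) at
stimulation onset and at the candidate, earliest candidate on ties. The
perturbation is the trial-averaged stim force minus the trial-averaged
aligned no-stim force, each trial signed by its triggering action
(+push/−pull) so a perturbation that increases the ongoing action's force
magnitude is positive for both actions; conditions pool into congruent
(push→push-ensemble, pull→pull-ensemble) and non-congruent, with no-stim
trials re-analyzed as pseudo-stimulation controls. The end-of-stimulation
value averages the final 20 ms of the 100 ms window. Stimulation
specificity reports mean z-scored activity of the targeted ensemble, the
opposite ensemble, and non-targeted neurons in the 100 ms after onset,
plus the decoder projection averaged 100 ms pre vs post.

The perturbation-recovery suite uses stimulation-regime sessions: 40
neurons with 6-neuron targeted ensembles (the 4–11-neuron range of
closed-loop experiments), force peaks 6–7.5 g and stereotyped bump
durations (rise 100–140 ms, decay 140–180 ms) reflecting actions trained
to a 6 g criterion — across-trial force variability is what limits the
precision of the recovered effect, and the trained regime is the
appropriate one for a ±0.2 g recovery question. 10 sessions × 16 blocks
give ~160 pairs per condition.

## EMG analysis

Channels are z-scored over the session and trial-averaged around the 6 g
cross. PC1 is extracted (covariance PCA, `sklearn`) from the 4 × (2
actions · window) concatenated matrix over the muscle dimension, signed
so the projection at the event is non-negative. Average modulation is the
across-action mean per channel, differential modulation half the
push−pull difference; variances are taken over a 0.4 s window. Action
specificity compares the magnitude of the difference between action-mean
4-vectors (mean EMG over 100 ms around the 6 g cross) against split-half
within-action distances, with seeded bootstrap distributions (1000
resamples).

## Study suites and problem sizes

The validation suites (used identically by the tests, the analysis
scripts and `scripts/acceptance.py`) are sized to run in minutes on one
core: 20 decoding sessions (480 s, 120 neurons, 8-neuron execution and
preparation ensembles per action, effect 1.5 z, ~37–42 trials per
action), 20 zero-selectivity control sessions, 20 small-population
(18-neuron) sessions for ensemble-membership recovery, 10 stimulation
sessions, and 6 EMG sessions. Ensemble-membership recovery is evaluated
on the small-population suite because `ensemble_frac = 1` selects
k = min(#positive, #negative) neurons: with dense SVM weights over 120
neurons k ≈ 60, so a session must be in the stimulation regime — most
recorded neurons action-modulated — for frac-1 selection to be a
meaningful recovery question.

## Known limitations

- **The null control's per-session statistics are not binomial.** With
  ~75 trials and sparse calcium-transient features, the null distribution
  of repeated-split cross-validated accuracy is slightly below chance in
  mean (~0.48) and heavy-tailed: individual zero-selectivity sessions can
  decode at 0.30–0.38 or 0.60+ even with 100 repeats. This is a property
  of cross-validated linear classifiers at small sample sizes, not of
  this implementation — an independent logistic-regression/k-fold
  pipeline reproduces the same below-chance sessions, while a nonlinear
  RBF classifier returns ~0.5, and iid Gaussian features show the same
  tails in milder form. Consequently a per-session 95% binomial interval
  under-covers (typically 17–20 of 20 sessions fall inside); the pooled
  suite accuracy is statistically indistinguishable from chance (binomial
  test at α = 0.01 over all distinct trials). Conclusions about
  selectivity should rest on shuffle controls and pooled statistics, not
  per-session binomial bands.
- The generator plants Gaussian-profile rate bumps with a fixed calcium
  kernel and stationary baselines; real recordings have bursty,
  non-Poisson dynamics, neuropil contamination that is imperfectly
  removed by a scalar coefficient, motion artifacts, and
  session-to-session drift. Passing recovery tests shows the analyses
  extract what the model plants — not that real striatal data satisfy the
  model.
- Preparation structure is reduced to lead-time-staggered rate bumps; no
  claim is made about the biophysical origin of preparatory activity.
- The simulator models stimulation latency as a fixed 2 ms parameter and
  does not model optics, power calibration, or off-target excitation.
- Muscle/limb biomechanics are not modeled; EMG is a two-drive linear
  mixture, which is exactly the structure the PC1/modulation analyses
  assume — those tests validate bookkeeping and conventions, not the
  biological claim that muscle activity has this structure.
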