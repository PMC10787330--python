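# Methods

## Problem and model

`workmode` estimates, minute by minute, the probability that a smartphone
user is in *work mode* from two passively logged streams: screen events
(notification timestamps, screen on/off, active-app labels, 1-s
resolution) and GPS fixes at a nominal 600-s cadence. GPS supplies the
training labels: a dwell rule marks the user on-working whenever the
device has been within 1 km of a registered workplace (up to 5 per user)
for a continuous 1800-s period, and off-working after a continuous 1800-s
period without such a detection. The estimator is a two-stage supervised
model, trained separately for every participant:

1. **Stage 1 — gradient boosted trees.** Screen events inside each 1800-s
   window are summarized as 5 features per app — usage duration,
   notifications inside usage episodes, notifications outside episodes,
   reaction time (notification → start of the triggered episode) and
   reaction intensity (duration of the triggered episode) — giving a
   feature vector of length 5 × |app vocabulary|. An XGBoost binary
   classifier maps each window to a provisional work probability.
2. **Stage 2 — 1-D convolutional smoother.** The provisional
   probabilities of the preceding `lookback` minutes are fed to a small
   1-D CNN (3 convolution layers and 2 fully connected layers; max
   pooling after the first two convolutions, global average pooling after
   the third; ReLU activations inside, sigmoid output) that emits the
   next-minute probability. Because behavioral state is strongly
   autocorrelated at the hour scale, the smoother removes window-level
   noise and recovers label context that single windows cannot see.

Each minute of the evaluated span (05:45–24:00 local) is then interpreted
by crossing the final probability p with the GPS indicator:
office (p > 0.5, at worksite), break (p ≤ 0.5, at worksite),
remote work (p > 0.5, off site), off (p ≤ 0.5, off site). A probability
of exactly 0.5 falls on the non-working side.

## Wall-clock rules and exclusions

* Days run midnight-to-midnight in the participant's local zone (default
  UTC+8); all rules below are wall-clock rules.
* Data between 00:00 and 05:45 are excluded everywhere: the span is
  dominated by sleep, and nocturnal non-use is easily mistaken for
  non-use at work.
* Only *typical workdays* train the models: off-working at both ends of
  the evaluated span, first work interval starting before noon, total
  work duration above 4 h (sum of intervals). At least 5 such days are
  required per participant. Days with no worksite fix at all are
  *holidays* (zero work hours); everything else is *other*.
* Training windows are non-overlapping 1800-s windows aligned to
  midnight. Windows containing both on- and off-working minutes are
  dropped (the label would be ambiguous), as are days without screen
  events.
* Evaluation (accuracy, ROC) excludes the *transition area*: ±15 min
  around every GPS on/off switch, where the dwell rule makes the labels
  unreliable.

## Geofence boundary convention

The 1800-s confirmation is treated as pure detection latency: an interval
*starts* at the first fix of the qualifying in-range run and *ends* at
the last in-range fix before the qualifying out-of-range run. Without
backdating every episode would lose ~30 min at each end. A gap in the
track longer than 1800 s counts as absence of detection. Runs are
evaluated per calendar day; intervals crossing midnight are split there.
At exact boundaries, an in-range run qualifies when it has spanned
≥ 1800 s, and recording ends only when strictly more than 1800 s pass
without a detection — so a 20-min out-of-range excursion sampled at the
600-s cadence does not split an interval.

## Stimulus–response pairing

A usage episode is attributed to the most recent notification of the same
app that arrived at or before the episode start and after the previous
episode of that app. One episode therefore reacts to at most one
notification (the nearest stimulus, as in mental chronometry), and a
notification already answered by an earlier episode is not reused.
Reaction time and intensity within a window are arithmetic means over the
notification-triggered episodes *starting* in that window; both are
missing (and later imputed) when no such episode exists. Reaction
intensity uses the full episode duration, unclipped by the window edge.

## Minute-resolution bridging

Stage 1 is trained on aligned non-overlapping windows but must produce a
per-minute sequence for stage 2. The bridging convention: the provisional
probability at minute t comes from the 1800-s window *ending* at t, slid
at a 60-s stride. These trailing windows are minute-aligned, so they are
computed exactly with per-minute bins and rolling sums (the rolling path
and the direct window path are verified equal in the tests).

## Leakage control

* Cross-validation folds are blocked by day: all windows of one day share
  a fold. Adjacent windows of one day are strongly dependent, so
  row-level folds would overstate stage-1 performance.
* Stage-2 training inputs are *out-of-fold* provisional series: each
  training day is scored by the fold model that never saw it. At
  inference the refit all-data stage-1 model is used.
* The early-stopping validation split of the CNN is also blocked by day:
  neighboring sequence windows share L−1 of their L minutes, and a random
  minute-level split lets the network memorize its way past early
  stopping (observed as saturated outputs and degraded held-out ranking).
* The missing-value sampler is fitted on training folds only.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| geofence radius | 1.0 km | worksite detection range |
| confirmation period | 1800 s | dwell time to start/stop work recording |
| GPS cadence | 600 s | fix interval |
| feature window | 1800 s | stage-1 window length |
| probability threshold | 0.5 | on-working cutoff |
| transition exclusion | 15 min | mask around GPS switches |
| AUC floor | 0.7 | low-discrimination boundary |
| greedy ΔAUC | 0.01 | stop rule for minimal-feature search |
| min typical days | 5 | training-data requirement |
| CNN lookback L | 30 min | provisional history per prediction |
| CNN filters/kernels | 32/64/64, 5/5/3 | convolution stack |
| CNN training | Adam 1e-3, ≤60 epochs, patience 5 | early stopping on day-blocked validation loss |
| XGBoost | depth 4, lr 0.1, ≤400 rounds, early stopping 30 | per-fold early stopping on the validation fold |

The lookback of 30 min (one feature-window length) balances noise
suppression against responsiveness at the scale of break/remote episodes
(tens of minutes); longer lookbacks smooth breaks away almost entirely.
The CNN budget (≤60 epochs, patience 5, min-delta 1e-4) reflects that the
probability-only input converges within a few epochs. Boosting
hyperparameters are conventional defaults for a few hundred training rows;
none of these values is dictated by the method itself, and all live in
config objects. The feature-importance metric for the greedy search is
total gain.

## Synthetic data generator

The generator emulates what the logging app measures, with known ground
truth per minute (office / break at work / off / remote):

* **Notifications** are per-app Poisson processes whose rates switch
  between a work regime (minutes office-working or remote-working) and an
  off regime (breaks and genuine off time). No events are generated
  before 06:00 (sleep).
* **Responses**: each notification is answered with a regime-dependent
  probability after a log-normal reaction time; the triggered episode has
  a log-normal duration. Self-initiated episodes arrive as separate
  Poisson processes. Overlapping candidate episodes are resolved to a
  single-screen stream (earliest wins).
* **Schedule**: work start ~ N(08:30, 40 min) truncated before noon,
  duration ~ N(10.2 h, 1.2 h), one lunch break (~40 min) plus Poisson(1)
  coffee breaks (~15 min), Poisson(1.5) evening remote episodes
  (~75 min), holidays with probability 2/7. These magnitudes reproduce
  the observed cohort-level aggregates for hospital staff (about 10.2 h
  of GPS work, ~55 min of breaks and ~110 min of remote work per day).
* **GPS**: fixes every 600 s; commute is a 30-min linear interpolation
  between home and workplace; location noise is isotropic Gaussian
  (0.05 km SD).
* **Contrast**: a single knob in [0, 1] shrinks each app's off-regime
  parameters toward its work-regime parameters (geometric interpolation
  for rates and medians, linear for probabilities). 1 — the default — is
  full separation; 0 makes regimes indistinguishable.
* **Reproducibility**: each participant draws from an RNG stream keyed by
  (seed, participant id), so cohorts are reproducible participant by
  participant.

The per-app parameter table (six apps: Phone, Email, Slack, YouTube,
Instagram, Messenger) is a free design choice — no public distributional
statistics of real screen events exist — and encodes the intended
mechanism: work-oriented apps are answered fast and briefly at work,
leisure apps fast and at length off work.

**What the simulator does not model**: phones switched off for hours,
multiple devices, OS-specific logging quirks, non-commute travel,
location-dependent notification muting, or any coupling between apps.
Passing tests on this generator show the pipeline recovers the states it
encodes under realistic noise; they do not certify performance on real
cohorts, where the regime separation may be far weaker.

## Numerical and degenerate-input choices

* Ties at the 0.5 threshold go to the non-working side everywhere.
* The first L minutes of each day pass the provisional value through
  unchanged (no full lookback exists; sequences never cross midnight).
* AUC is rank-based with ties credited 0.5; one-class inputs yield an
  explicit "no AUC" result (holidays alone have no positives).
* The paired t statistic errors on zero-variance nonzero differences and
  returns (0, 1) for identical samples.
* Stage-1 refit after cross-validation uses the mean early-stopped round
  count of the folds.
* The stability-vs-training-days analysis retrains stage 1 only; the
  boosted classifier is the data-hungry component, and the fixed held-out
  set keeps the curve comparable across counts.

## Known limitations

* **Causal detection lag.** Both stages look backwards (trailing feature
  window, causal smoother), so any regime switch is detected with a lag
  of roughly 20–30 min. Breaks and remote episodes shorter than that lag
  are invisible in the final probability, and recovered episodes are
  time-shifted; at paper-scale break durations (~40 min) minute-level
  overlap with the true episodes is poor even when classification AUC is
  high. The segmentation mechanism test therefore uses longer scheduled
  episodes (90–120 min).
* Daily aggregates are computed over 05:45–24:00, not 24 h.
* The per-participant model cannot start before ~5 typical workdays of
  data exist, and apps unseen during training are ignored at inference.
* Problem sizes in the shipped experiments (20 participants × 30 days;
  100-track and 1000-window oracle sweeps) were chosen as the smallest
  cohorts at which the cohort-level statistics stabilize.
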