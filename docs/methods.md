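# Methods

This note documents the models, algorithms, parameters and design
choices behind `gaitbarrier`, in the order data flows through the
package.

## Problem setting

A pedestrian walks a surveyed urban route carrying a smartphone that
logs a 6-axis IMU (3-axis accelerometer in m/s², 3-axis gyroscope in
rad/s) at 100 Hz and position (here 1-D arclength along the route) at
1 Hz. Built-environment hazards — uneven sidewalk, curb drops, narrow
alleys, driveway crossings — perturb gait transiently. The task has two
stages: (1) classify each 2-s gait window as normal vs abnormal, and
(2) aggregate window outputs into a per-5-m-segment environmental-
barrier (EB) score that localises hazards along the route.

## Synthetic cohort simulator (`synth`)

No public dataset of barrier-annotated older-adult walks exists, so the
simulator is a first-class, tested component. It emulates:

- **Clean gait**: each channel is a sum of K = 3 sinusoidal harmonics of
  a per-subject step frequency f₀ with per-axis amplitudes and phases,
  plus white Gaussian sensor noise. The vertical accelerometer axis
  carries a constant +9.81 m/s² gravity offset, so the acceleration
  magnitude baseline is ≈ g, as in real waist-worn recordings. Gravity
  is not rotated (no orientation simulation — a stated non-goal).
- **Subject variability**: profiles are drawn uniformly per subject:
  f₀ ∈ [1.0, 2.0] Hz, walking speed ∈ [1.0, 1.2] m/s (hard bounds
  [0.8, 1.4]), fundamental amplitudes 0.8–1.6 m/s² (acc) and
  0.3–0.7 rad/s (gyro) with a 0.5 decay per harmonic order and ±30%
  per-harmonic jitter, noise SD 0.05–0.15 m/s² / 0.02–0.08 rad/s, and a
  caution factor ∈ [0, 1] that halves, at most, the perturbation
  response (cautious walkers negotiate hazards more smoothly).
- **Barrier response**: inside each barrier's negotiation zone the
  signal receives (i) amplitude scaling 1 + 0.8·s·m (s = severity,
  m = 1 − caution/2), (ii) a 0.35-s half-sine jerk transient at the
  extent entry (3 m/s² on acc, 1.2 rad/s on gyro at s·m = 1), (iii) a
  phase advance of 0.8·s rad on every harmonic, and (iv) a gait-band
  (1–4.5 Hz) noise burst scaled to 1.2·s·m times the channel's
  fundamental amplitude (the "irregular oscillation" signature). Walking
  speed dips by 15%·s inside the extent.
- **Negotiation envelope**: the response intensity is trapezoidal —
  a linear ramp over a 1 m anticipation zone before the barrier, full
  intensity across the extent (floored at 1.0 s of traversal), and a
  linear ramp over a 1 m recovery zone. Gait adjustment begins when the
  walker sees the hazard and persists briefly after clearing it; the
  1 m distances deliberately match the ±1 m labeling radius, so every
  window labeled abnormal overlaps some perturbed samples. Without the
  envelope roughly a quarter of abnormal-labeled windows would contain
  purely clean signal, which both misrepresents real negotiation
  behaviour and makes the labels partly arbitrary.

The gain constants above are calibration knobs of the simulator, chosen
once for phenomenological plausibility (in-event variance visibly
exceeds clean-gait variance; GASF images show localized distortions);
no field data constrains their exact values.

Determinism: the cohort is a pure function of (config, master seed).
Per-trial generators derive from `SeedSequence((master, subject,
trial))` and the subject profile from `(master, subject)`, so any trial
is reproducible in isolation. Events log both the extent-traversal span
and the full perturbed sample span; samples outside the latter are
bit-identical to clean gait.

## Preprocessing (`preprocess`)

- **Filter**: 4th-order Butterworth low-pass, 5 Hz cutoff, applied to
  all six raw channels. Single-pass causal filtering by default (the
  stated order describes a single-pass response); a `zero_phase` switch
  enables forward–backward filtering, which squares the magnitude
  response. Initial filter state is set to the steady state of the
  first sample, so a constant input passes through unchanged.
- **Magnitudes**: `svm_mag(x, y, z) = √(x² + y² + z²)` per sample for
  the accelerometer and gyroscope triads (channels `SVM_Acc`,
  `SVM_Gyro`), giving orientation-invariant intensity. (The gait
  literature overloads "SVM"; in this package `svm_mag` is always the
  signal vector magnitude and `svc` always the support-vector
  classifier.)
- **Windows**: fixed 2.0 s sliding windows with 50% overlap;
  L = round(window_s·fs) samples, step = round(L·(1 − overlap)) (ties
  round half up); trailing partial windows are discarded. Window counts
  follow floor((N − L)/step) + 1.
- **Labels**: a window's spatial span (entry/exit arclength, linearly
  interpolated from the 1 Hz trace) is intersected with each barrier
  extent inflated by ±1 m; any intersection ⇒ abnormal. Span
  intersection (not centroid distance) is used so a window that touches
  the negotiation zone at either end is treated as containing part of
  the encounter.
- **Exclusions**: annotated borderline windows stay stored but are
  omitted from training and evaluation. An optional balanced subsampler
  keeps all abnormal windows and an equal-count random subset of normal
  windows; it is off by default and used by the scaled benchmark.

## GASF encoding (`gaf`)

Each window channel is min–max normalised to [−1, 1] (a constant window
maps to all zeros and is flagged degenerate), mapped to polar
coordinates θ_t = arccos(x_t), r_t = t/L (t = 1…L), and encoded as the
Gramian angular summation field G_ij = cos(θ_i + θ_j), evaluated in the
equivalent algebraic form x_i x_j − √(1−x_i²)√(1−x_j²). G is symmetric,
bounded in [−1, 1], with diagonal 2x_i² − 1. Only the summation field is
implemented (the difference field is a non-goal). At the native
100 Hz × 2.0 s window the matrix is exactly 200×200; other sizes are
reached by linear resampling of the series before encoding. Min–max
normalisation absorbs channel gain and offset, so the encoder is
invariant to affine rescaling of the raw signal; it also discards the
window's absolute amplitude — the classifier sees waveform shape only,
which is why the simulator's irregular-oscillation and phase signatures
matter more than raw spike height. 8-bit PNG export
(round-half-up intensity mapping) is provided for inspection only; the
classifier consumes float matrices.

## Classifier (`classifier`, `nn`)

Architecture (2-D, default single `SVM_Acc` channel): conv 16@5×5 →
ReLU → maxpool 2×2 → conv 32@3×3 → ReLU → maxpool 2×2 → conv 32@3×3 →
ReLU → flatten → dense 64 → ReLU → dense 2 → softmax, same padding,
stride 1, dropout 0.25 after conv blocks and 0.50 after the dense
layer. An alternative `head="gap"` variant replaces flatten with global
average pooling (≈16 k parameters vs ≈5.1 M at 200×200); the flatten
head is the default. An 8-channel stacked input mode is available via
the `channels` setting.

Training: Adam (lr 1e-3), batch 32, two-class cross-entropy with label
smoothing 0.05, L2 weight decay 1e-4, up to 50 epochs with early
stopping after 5 stagnant validation epochs (best-validation weights
restored), He-normal init, seed 42 by default. Augmentation (training
only): rotation uniform ±5°, integer translation ±3 px, bilinear
resampling, edge replication; no flips or shears. The inner validation
split is subject-stratified — whole subjects are moved to validation
until it holds ≈20% of training windows — so early stopping never sees
the training subjects' windows. When balanced subsampling is enabled it
is applied to the inner-train and validation portions alike, so the
early-stopping loss tracks the same balanced objective the network is
trained on.

The raw 1-D ablation shares depth (three conv blocks, 16/32/32),
pooling policy, dense width, optimizer, batch size, and early-stopping
policy, but convolves directly over the 200-sample `SVM_Acc` sequence,
standardised with training-fold mean/SD (raw magnitudes sit at ≈9.81
m/s², which would otherwise saturate ReLU dynamics).

The network engine is a compact numpy implementation (im2col
convolutions backed by BLAS matmul, float32 throughout); its gradients
are verified against central finite differences in the test suite.
Max-pool gradients route to the first maximal element of each window
(deterministic tie-break); the first conv layer skips the unused input
gradient. With fixed seeds and single-threaded BLAS, training is
bit-reproducible; floating-point nondeterminism from threaded BLAS
reductions is the only documented exception.

Evaluation is leave-one-subject-out: one fold per subject, trained on
the rest; the partition property (each window predicted exactly once,
by the fold holding out its subject) is asserted at run time.
Probabilities are raw softmax outputs — no post-hoc temperature
scaling — so the calibration metrics describe the model as trained. A
grid-search tuner was considered and omitted: the shipped defaults are
a single selected configuration, and every knob is exposed in
`ModelConfig` for manual sweeps.

## Baselines (`baselines`)

- **Peak-feature SVC**: RBF support-vector classifier (C = 10,
  γ = 0.01) on the window's peak `SVM_Acc` (optional extended set adds
  mean, SD). Features are standardised with statistics fitted on the
  training fold only. Same LOSO folds as the CNN.
- **Rosenstein MaxLE**: delay-embed (m = 6, τ = 5 samples), pair each
  state with its nearest neighbour outside a Theiler window, average
  the natural-log separation over time offsets, fit the slope of the
  initial region, convert to s⁻¹ via fs. Defaults: Theiler window = one
  mean period (dominant periodogram peak), fit window = half a mean
  period; for 2-s windows both shrink to fit the embedding. Periodic
  signals sit in a |λ| ≤ 0.05 s⁻¹ zero band; white noise diverges
  immediately; on the Lorenz x-series the estimate agrees with an
  independent Benettin two-trajectory oracle within 20% when the fit
  window spans the initial linear scaling region (~1.5 Lyapunov times).
  Short-window estimates are noisy — which is precisely the weakness
  this baseline is meant to exhibit; a per-trial mode is available.
  Window labels come from a Youden-J-optimal threshold learned on the
  training fold: candidate thresholds are midpoints of adjacent sorted
  unique scores, J = sensitivity + specificity − 1, ties broken toward
  the smallest threshold.
- **Multi-user entropy**: per participant, the filtered acceleration
  magnitude is min–max normalised to [0, 1] (pooled over that
  participant's trials, removing inter-subject gain), samples are
  pooled across participants into 5-m segments, and each segment's
  40-bin histogram yields Shannon entropy H_s (bits) with ε = 1e-6
  additive smoothing; H is then min–max normalised across segments into
  an EB score. The per-participant normalisation scope is this
  package's choice — the aggregation is inherently multi-user, so
  removing subject gain before pooling is the consistent reading. This
  method produces no window labels; it enters only the segment-level
  comparison.

## Spatial mapping and metrics (`spatial`, `evaluation`)

The route is tiled into half-open [start, start+5 m) segments (the last
may be shorter). A window belongs to the segment containing its *start*
arclength; windows starting at or past the route end are dropped with a
warning. The EB score of a segment is the mean abnormality indicator of
its windows — p_w for the CNN, the 0/1 predicted label for SVC/MaxLE:

    EBscore(s) = (1/N_s) Σ_{w∈s} [abnormal(w)]

Segments with N_s = 0 are flagged missing and excluded from ranking
metrics (the mean is undefined there, and scoring them 0 would
conflate "no data" with "no hazard").

Segment metrics: AUC-ROC (Mann–Whitney statistic, ties ½) and AUC-PR
(precision–recall step integral) via scikit-learn, cross-checked in the
tests against exhaustive pair counting; Precision@k / Recall@k with
ties at rank k broken by segment index; and run-based detection
metrics: scores are binarised (threshold 0.5 for probability scores;
Youden-J over segment rates for the binary-label baselines, whose
rates have no natural 0.5 calibration), truth and detections are
grouped into maximal contiguous runs, each truth run's IoU is taken
against the union of overlapping detection runs (0 if none), mIoU is
the mean over truth runs, and FP/km counts detected segments in runs
overlapping no truth run per kilometre. mIoU has no single canonical
definition; this run-based per-truth-event form is isolated in one
function, and a global set-level IoU is reported alongside.

Window metrics: accuracy, F1 (abnormal positive; 0 with a warning when
undefined), sensitivity, specificity at threshold 0.5; ROC/PR curves
with AUCs from the same rank-statistic code as the segment metrics;
Brier score; and ECE over 10 equal-width probability bins (bin count
configurable; 10 is the common reporting convention) defined as the
count-weighted mean absolute gap between mean predicted probability and
observed abnormal fraction. The reliability table recomposes exactly to
the ECE value (asserted in tests). LOSO metrics are micro-averaged by
pooling all held-out predictions; per-fold accuracy mean ± SD is
reported alongside.

## Scaled benchmark (`benchmark`)

The package's standard end-to-end study simulates 10 subjects × 2
trials on a 600 m route with 6 barriers of severity 0.8–1.0
(≈11,000 windows, ≈7% abnormal), encodes 32×32 GASF images, and runs
LOSO with at most 10 epochs and balanced subsampling of normal training
windows. These sizes keep a full multi-method run in the minutes range
on one CPU core. Expectations at this size: GAF-CNN pooled window
AUC-ROC ≥ 0.85 and at least matching the peak-feature SVC; the top
B + 2 segments by CNN EB score (B = number of true barrier segments)
cover every injected barrier zone.

What passing on synthetic data does and does not show: it validates
the pipeline's correctness (windowing, encoding, leakage-free LOSO,
aggregation, metric algebra) and that the CNN can exploit GASF texture
under realistic subject variability. It does not validate performance
on real gait: the simulator has no orientation drift, no turning or
stopping behaviour, no terrain texture between barriers, stationary
per-subject dynamics, and barrier responses drawn from one parametric
template. Real-data claims require real recordings.

## Numerical choices and degenerate inputs

- Constant window channels normalise to all zeros (GASF = −1
  everywhere) and are flagged `degenerate` rather than erroring.
- `to_polar` clips |x| ≤ 1 with tolerance 1e-12 and rejects anything
  beyond; non-finite input is rejected everywhere at the boundary.
- Rounding: window length/step and the PNG intensity map round half
  up; segment intervals are half-open with 0-based indices.
- Zero nearest-neighbour distances in the Lyapunov estimator are
  floored at 1e-12 inside the log (exactly periodic signals).
- All randomness flows through `numpy.random.Generator` objects seeded
  from explicit `SeedSequence` tuples; no global seeding.

## Known limitations

- The CNN engine is single-threaded numpy; at the native 200×200 image
  size, LOSO training of the ≈5.1 M-parameter flatten-head model is
  slow on one core — the 32×32 benchmark size or the `gap` head are
  the practical configurations there.
- The entropy baseline needs ≥2 distinct segment entropies for its
  min–max normalisation to spread scores; short routes with uniform
  signal yield flat profiles.
- MaxLE on 2-s windows (200 samples, m = 6, τ = 5 → 175 embedded
  states) is at the low end of what the estimator needs; its window
  scores are noisy by construction.
- Segment truth marks any segment intersecting a barrier extent; a
  barrier straddling a boundary marks two segments, which the top-k
  and mIoU metrics treat as two targets of one zone (the zone-coverage
  check groups them back into runs).
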