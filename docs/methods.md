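# Methods

`gaitscore` implements an automated UPDRS-III gait-subscore estimator for
Parkinson's disease from two shank-mounted IMUs (100 Hz) and four surface-EMG
channels (tibialis anterior and gastrocnemius, left and right; 1 kHz), for
subjects walking a straight 10 m path with ≥ 5 s of quiet standing before and
after.  This note records the model, its assumptions, and the design choices
made where the problem was genuinely open.

## Coordinate convention and calibration

The shank anatomical frame is x = vertical (gravity-aligned), y = anterior,
z = mediolateral; a correctly mounted, stationary accelerometer reads
`[g, 0, 0]`.  Mounting misalignment is modelled as a fixed rotation between
the sensor and anatomical frames and estimated in two stages:

* **Static** — the mean accelerometer vector over the pooled pre- and
  post-trial standing windows gives the pitch (about y) and yaw (about z)
  errors: `e_pitch = atan(-ā_z / √(ā_x² + ā_y²))`, `e_yaw = atan(ā_y / ā_x)`.
  The two windows have equal length, so concatenating them weights their
  means equally.
* **Dynamic** — rotation about the shank's long axis (roll) leaves gravity
  unchanged but leaks forward displacement into the mediolateral axis.  For
  straight-line walking the ideal per-cycle displacement is purely anterior,
  so `e_roll = atan(xz_cycle / xy_cycle)` per gait cycle.  The roll estimate
  is the **median over all valid cycles**, which is robust to the
  acceleration/deceleration cycles at the ends of the walk.

Correction applies `Rx(-e_roll)·Ry(-e_pitch)·Rz(-e_yaw)` to every
accelerometer *and* gyroscope sample.  This elementary-rotation order is the
unique one under which the static formulas exactly zero the y and z
components of the static mean; both sensor modalities are rotated so the
whole trial lives in one frame.

Displacement integration uses trapezoidal quadrature with zero-velocity
updates (ZUPT): velocity is anchored to zero at both cycle-bounding heel
strikes and the residual linear velocity drift over the cycle is removed
before the second integration.  Cycles shorter than 0.4 s or longer than
2.5 s are rejected as implausible.

## Gait events

No event-detection algorithm is dictated by the scoring model, so the
package uses the standard shank-gyroscope morphology: one dominant positive
sagittal peak at mid-swing per cycle, flanked by negative troughs near
toe-off (before) and heel strike (after).  Mid-swing candidates are strictly
positive peaks with prominence ≥ 0.4 × the 90th-percentile amplitude and
≥ 0.5 s separation; troughs are located in 0.35 s windows on either side.
The positivity requirement matters: between the two deep troughs the stance
"plateau" can be locally prominent, but it is always negative under the
correct sign convention.  The sagittal sign is auto-detected from the sign
of the signal's skewness (the swing peak dominates).  All thresholds are
config-exposed.  The heel strike that opens the very first cycle has no
preceding mid-swing peak, so the first cycle of a walk is not detectable by
construction; trials are generated/recorded with enough cycles that this
does not matter.

## Kinematic features

Six per-cycle parameters: stride length SL (net anterior displacement), gait
cycle duration GC, swing-phase ratio SPR = (hs_end − toe_off)/(hs_end −
hs_start) using the ipsilateral toe-off, mean gait speed MGS ≡ SL/GC (the
deterministic ratio, not the mean instantaneous speed), maximum foot
clearance MFC (peak vertical displacement above the cycle-start position of
the ankle-mounted sensor), and shank range of motion SR (max − min of the
drift-corrected integral of the sagittal angular velocity).  SL and MFC are
normalized by subject height before any cross-subject use.

The balance head consumes a fixed 4×6 summary (MF) of the pooled per-cycle
vectors from both legs: k-means with k = 4 (10 restarts, fixed seed) on
per-feature z-scored vectors; the de-standardized centroids are sorted
ascending by SL/H so the matrix is invariant to cycle ordering and centroid
permutation.  Whether the four rows should instead encode side × statistic
combinations is not decidable from the scoring model alone; centroids are
the minimal reading of "a clustering algorithm summarizing the gait
pattern", and the choice is isolated behind `summarize_mf`.

## EMG features

Each channel is band-passed 20–450 Hz (4th-order Butterworth, zero-phase
forward–backward) and normalized by the 99th percentile of its absolute
value over the trial (robust to isolated spikes; plain max normalization is
the obvious alternative and differs negligibly on clean data).  The linear
envelope is `√(ε² + H(ε)²)` (Hilbert magnitude) smoothed by a zero-phase
10 Hz low-pass — a typical linear-envelope cutoff.  Per gait cycle, traces
are linearly resampled onto 97 points of the normalized cycle; left-side
channels follow left-leg cycles and right-side channels right-leg cycles,
with cycle boundaries mapped between the IMU and EMG streams through their
shared wall clock.

* **FTF** (4×97): cycle-averaged envelopes, per-channel max-normalized to
  [0, 1].
* **ETFF** (100×97×4): magnitudes of a complex-Morlet (`cmor1.5-1.0`)
  continuous wavelet transform, 100 scales log-spaced so center frequencies
  span 10–500 Hz (bracketing the 20–450 Hz passband and the ≈100 Hz energy
  peak of gait EMG), time-warped per cycle and averaged across cycles.
  Averaging (rather than concatenation) is what keeps the tensor a fixed
  size regardless of cycle count.

The 97-point and 100-scale sizes are fixed constants of the feature
contract.  `stance_energy_spread` summarizes temporal dispersion as the
circular standard deviation of column energy, restricted to scale rows
carrying ≥ half the peak row energy so broadband background does not dilute
burst timing.

## Scoring heads

Three small networks (all < 10⁵ parameters, trained with Adam +
cross-entropy, early stopping on a 20% validation split, deterministic given
a seed) are implemented in an in-repo NumPy reverse-mode autodiff module
(`gaitscore.nn`); every op's gradient is verified against finite differences
in the test suite.

* **Diagnosis** (PD vs HC) from FTF: two conv–batchnorm–ReLU blocks
  (kernel 5, 16→32 channels) with max-pooling and dropout p = 0.3, an LSTM
  (hidden 32) over the pooled 24-step sequence, 2-class softmax.
* **Evaluation** (level 0/1/2) from ETFF: the volume is average-pooled
  (5×6×1) at the input — scalogram energy varies smoothly over scale and
  cycle time, so this retains the discriminative structure at a fraction of
  the cost — then two 3-D conv blocks (kernel 3×3×2, 8→16 channels) with
  pooling, global average pooling and a 3-class softmax.  A classification
  output (not scalar regression) is required because the fusion rules
  threshold per-level probabilities.
* **Balance** (severe impairment = level 2, vs not) from MF: the six
  kinematic features are embedded as tokens (dim 8), combined by
  scaled-dot-product self-attention (attention map exposed via
  `feature_attention`), flattened and classified.  The balance label
  (level == 2) follows from gait kinematics separating level-2 subjects far
  more strongly than level 0 vs 1.

Early stopping only arms after a 15-epoch burn-in: with batch normalization
on small datasets the validation loss shows a transient hump while running
statistics converge, and stopping inside it freezes an untrained model.
Per-trial probabilities are averaged into one subject-level prediction.
All layer sizes are configuration, not architecture constants.

## Fusion rules

All decision thresholds start at 0.5; verdicts use strict inequalities.
Rule 1 (diagnosis says healthy): forbid level 2, raise the level-1 threshold
to 0.7.  Rule 2 (diagnosis positive): raise the level-0 threshold to 0.7.
Rule 3 (no severe balance impairment): raise the level-2 threshold to 0.7.
Rule 4 (severe impairment): forbid level 0, raise the level-1 threshold to
0.7.  Rules 1/2 fire on complementary verdicts, as do 3/4 (asserted).  The
final level is the argmax of `p_level[k] − threshold[k]` over non-forbidden
levels, ties toward the lower level — the rules themselves do not define
what happens when zero or several levels clear their thresholds, and the
margin rule degrades gracefully to plain argmax when all rules are off while
always producing exactly one level.  An independently coded brute-force
transcription of the rules is kept in the tests and checked for exact
agreement over a dense probability grid × all 16 rule on/off configurations.

## Evaluation protocol and statistics

Subject-wise cross-validation on a 10 HC / 5 PD-1 / 6 PD-2 cohort: each of
21 folds holds out 2 HC + 1 PD-1 + 1 PD-2 (resampled until every subject is
held out ≥ 2 times), pooling 84 subject-level predictions.  The baseline is
the evaluation head alone (all rules off, argmax); the fused model enables
all four rules.  Comparisons: paired t-test on the 21 fold accuracies
(df = 20, 95% CI) and a McNemar test on the pooled predictions with Edwards
continuity correction, `χ² = (|a−b|−1)²/(a+b)` — the correction is what
reproduces the worked example (a = 1, b = 24 → 19.360) exactly.  Cohen's d
uses the pooled-SD denominator (n_a + n_b − 2); post-hoc power is two-sided
two-sample t power from the noncentral-t distribution with noncentrality
`d·√(n_a·n_b/(n_a+n_b))`.  A published power table of this kind cannot be
reproduced row-for-row by any single standard formula (e.g., a |d| = 0.23
comparison listed with power 0.966), so power is validated against an
independent implementation (pingouin) rather than against printed values.
The 16-configuration rule ablation re-fuses the pooled predictions for every
rule subset, laid out rows = (rule1, rule2) ∈ {00,01,10,11}, columns =
(rule3, rule4).  Occlusion sensitivity zeroes one FTF channel at test time
and reports the per-fold mean ± SD accuracy drop of the diagnosis head.

## Synthetic cohort generator

Real recordings of this protocol are not redistributable, so the package
ships a generator that emulates the study conditions with exact ground
truth; it is first-class, tested code.  Per leg and cycle (phase u ∈ [0,1),
heel strike at 0, toe-off at 1 − swing_ratio):

* forward position `y = SL·(u − sin 2πu / 2π)` — one stride length per
  cycle with zero velocity at heel strikes (matching the integrator's ZUPT
  assumption);
* vertical position `x = MFC·sin⁴(πv)` during swing (v = normalized swing
  phase) — continuous acceleration at toe-off and heel strike, which keeps
  trapezoidal double-integration accurate at 100 Hz;
* sagittal angular velocity: raised-cosine bumps (positive mid-swing peak,
  troughs at toe-off and heel strike), mean-removed per cycle and scaled so
  the angular excursion equals `shank_rom_rad`;
* accelerometer output = trajectory second derivative + gravity, rotated
  into the sensor frame by the per-IMU misalignment truth (`Rz·Ry·Rx`, the
  inverse of the calibration correction); gyroscopes are rotated by the
  same matrix;
* EMG: Gaussian carriers band-passed to 60–160 Hz (energy near 100 Hz),
  amplitude-modulated by cycle-locked raised-cosine bursts — TA around heel
  strike, GA at push-off — over a 5% baseline floor.

Severity moves the defaults in the clinically reported directions: SL
1.30/1.12/0.88 m, GC 1.02/1.08/1.18 s, SPR 0.40/0.38/0.33, MFC
0.130/0.115/0.095 m, SR 1.10/0.92/0.70 rad for levels 0/1/2; EMG burst
dispersion 1.0/1.4/1.9, right-to-left amplitude ratio 1.0/0.85/0.70 with a
0/3/7% timing delay on the right side.  Between-subject variability is
lognormal with CV 8% (HC) / 12% (PD); sensor noise defaults to white
σ_a = 0.05 m/s², σ_g = 0.01 rad/s and an EMG noise floor of 2%, all
switchable off for oracle tests.  Mounting misalignment is drawn uniformly
within ±10° per axis by default.  Trials contain max(8, ⌈10 m / SL⌉) cycles
per leg (the right leg offset by half a cycle) between two 5 s static
windows; cycle durations jitter with a per-level CV.

What the generator does **not** emulate: freezing-of-gait or tremor
episodes, turning, double-support decomposition, motor-unit structure in
the EMG, soft-tissue artifact, or sensor drift.  Group separations in the
synthetic cohort are cleaner than in real patients — the default cohort is
nearly linearly separable, so absolute accuracies here (baseline ≈ 0.95–1.0)
sit well above what heterogeneous clinical data yields, and passing tests
demonstrate correctness of the machinery and the *direction* of effects
(fusion ≥ baseline; all-rules-on ≥ all-rules-off; HC-vs-PD effect signs),
not clinical performance.

## Numerical choices and degenerate inputs

Problem sizes used by the shipped experiments: 21 subjects × 3 trials,
21 CV folds, head training ≤ 45/40/150 epochs (diagnosis/evaluation/balance)
with early stopping — chosen so a full cohort run completes in minutes on
one CPU core.  Static windows must have ‖mean‖ within [0.8 g, 1.2 g]
(otherwise not-static) and positive x (otherwise upside-down).  Roll needs
> 0.1 m forward displacement per cycle.  Zero-amplitude EMG passes through
normalization unchanged (divide-by-zero guard).  0/0 precision or recall is
reported as 0.  k-means ties and permutations are resolved by sorted rows
and a fixed seed; `fuse` ties break toward the lower (less severe) level.
All file indices are 0-based with half-open `[start, end)` ranges.

## Known limitations

Only UPDRS gait levels 0–2 are modelled.  MFC is sensor clearance at the
ankle, not true foot clearance.  The EMG sampling rate is configurable
(default 1 kHz; anything > 900 Hz works with the 450 Hz band edge) and the
two modalities are assumed to share a wall clock — there is no
cross-modality synchronization estimation.  Head hyperparameters are
defaults tuned for the synthetic cohort scale, not a search result.
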