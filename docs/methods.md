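# Methods

`synspace` implements synergy-space decoding of forearm motion: elbow
flexion–extension (FA_y) and forearm pronation–supination (FA_x) are
predicted from residual shoulder kinematics (SH_x internal–external
rotation, SH_y flexion–extension, SH_z abduction–adduction) by routing
a recurrent regressor through a low-dimensional spatial-synergy space.
This note documents the model, the numerical choices, and what the
synthetic test bed does and does not establish.

## Spatial synergy model

Joint-angle trajectories during planar reaching are modeled as

    x(t) = W · c(t) + residual,

where the columns of `W` (5 × N) are time-invariant spatial synergies
and `c(t)` are their activation signals.  `W` and `C` are obtained by
PCA of the source matrix `X` (5 channels × concatenated averaged
movements): the thin SVD of the row-centered matrix gives the channel
covariance eigenvectors, and for every rank N the truncated
factorization minimizes the Frobenius reconstruction error ‖X − WC‖_F
(Eckart–Young).  Row means are removed before decomposition and
restored at reconstruction; the data reaching PCA are already min-max
normalized to [−1, 1], so no further scaling is applied.

The number of retained components is the smallest N whose cumulative
explained-variance fraction strictly exceeds 0.85.  The decoding
methodologies are fixed-width regardless: the two-synergy route always
uses the first two components of the five-channel decomposition, the
one-synergy route uses the first component of a decomposition of the
two forearm channels alone, and direct estimation bypasses synergies
entirely.

**Sign convention.**  Each component is flipped so that the sum of its
loadings is positive (fallback: largest-magnitude entry positive when
the sum is numerically zero).  A sum is a smooth functional of the
loadings, so the convention is stable across runs, libraries, and —
critically — across subjects whose synergies differ slightly.  An
anchor based on the single largest entry is not stable here: min-max
normalization tends to equalize the loading magnitudes of the dominant
component across channels, so the argmax wanders between channels of
opposite sign and can flip the whole component.  Cross-subject
transfer, which substitutes one subject's `W` under another subject's
decoder, depends on this consistency.

## Preprocessing

Processing order for the source matrix: segment → time-normalize →
average over the 15 repetitions per target → zero-phase 6th-order
Butterworth low-pass at 10 Hz → normalize to [−1, 1].  Decoder training
sequences take the same segmented trials individually: filter →
normalize, with activation targets obtained by projecting each trial
through the stored decomposition.

* **Segmentation.**  The aggregate angular speed (Euclidean norm of the
  finite-difference velocities of the 2 Hz zero-phase-smoothed angles)
  is thresholded at 5% of the way from the rest floor (10th percentile
  of the trace) to the session peak.  Onset requires the threshold to
  be exceeded for 100 ms; the return to rest must hold for 150 ms
  (an out-and-back reach pauses at its reversal point, so the close
  condition must outlast that dip but stay shorter than an inter-trial
  rest); candidate movements shorter than 300 ms are discarded.  The
  floor-relative threshold makes detection robust to sensor noise at
  rest and reduces to a plain fraction-of-peak rule on clean data.
  Smoothing is applied to the angles *before* differencing: for a
  zero-phase filter the two orders are equivalent in the interior, but
  differencing raw noise first produces large edge transients.
* **Alignment for averaging.**  Trials are linearly resampled on the
  normalized time axis to the global median training-trial length, so
  all per-target averages share one `tmax` and concatenate into a valid
  source matrix.
* **Filtering.**  Zero-phase (forward–backward) application doubles the
  effective order and cancels phase lag; chosen because the analysis is
  offline and estimates are compared sample-by-sample to ground truth.
* **Normalization.**  One per-channel min/max record is fitted on the
  union of the filtered individual training trials and the filtered
  per-target averages, and used everywhere an angle is normalized or
  denormalized for that subject; covering both sets guarantees the
  source-matrix entries stay in [−1, 1] even when filter edge
  transients on an averaged trial poke marginally outside the
  individual-trial range.  Shoulder angular velocities — central differences of the
  filtered angles, one-sided at the ends — get their own record.
  Records are role-tagged ("angles" / "velocities") and validation or
  cross-subject data are always mapped with the *training* records of
  the subject being evaluated; out-of-range values are not clipped.

## Decoder

A stacked LSTM (1–3 recurrent layers, 64 hidden units by default, 10%
inverted dropout between layers, linear output head) maps windows of
the 10 previous time steps of the selected input channels to the
target at the window's final step.  Windows never cross movement
boundaries; the first 9 samples of each movement therefore yield no
prediction and evaluation drops them from the reference signal.  The
four input combinations are (SH_y, SH_z), (SH_x, SH_y, SH_z),
(SH_y, SH_z, dSH_y, dSH_z) and all six angle + velocity channels;
crossed with the three methodologies and three depths they form the
36-scenario grid.

Training minimizes MSE with Adam (learning rate 0.005 by default,
batch 32, up to 100 epochs with early stopping on a seeded 10% window
split, patience 10).  The LSTM, backpropagation through time, and Adam
are implemented directly in NumPy; single-threaded execution is exactly
deterministic given the scenario seed, which is what makes the
pipeline-reproducibility guarantees exact rather than
tolerance-based.  Training uses all individual trials (an
`averaged_only` flag restores training on the eight averaged
movements).  Forearm estimates in degrees come from
`means + W[:, :2] · Cp` (two-synergy), the forearm-only analogue
(one-synergy), or direct denormalization of the network outputs.

Hyperparameters without an external specification (hidden units,
batch size, epochs, learning rate, early-stopping patience) are package
defaults chosen for reliable convergence of the overfit-regime sanity
checks; they are ordinary `ScenarioSpec` fields.

## Evaluation and statistics

RMSE is computed on denormalized angles in degrees, pooled over outputs
as the square root of the grand mean of squared errors.  Pearson
correlations are reported per output with the conventional qualitative
bands (boundaries assigned to the band of larger |r|; the published
band edges overlap).

One-way ANOVA is computed directly from group summaries
(count/mean/sample-variance): between-group SS from size-weighted mean
deviations, within-group SS from pooled variances — identical to the
raw-data ANOVA when the summaries are exact, which lets the published
descriptive-statistics tables be fed in verbatim.  Tukey HSD uses the
studentized-range distribution (`scipy.stats.studentized_range`) at
equal group sizes; the unequal-n Tukey–Kramer extension is deliberately
out of scope.  p-values and critical values use α = 0.05.

Cross-subject transfer scores every (target, source) pair including
self-pairs (matching the published n² group counts; a flag excludes the
diagonal): target subject's validation inputs, normalized with the
target's records, are fed through the source subject's network, and for
synergy methodologies the target's own `W`, channel means and records
are used at reconstruction.

## Synthetic cohort design

The generator emulates the study design: per subject, 8 reaching
targets × 15 repetitions (training) plus 35 uniformly drawn validation
movements, 5 channels at 120 Hz, 1.5 s movements separated by 0.5 s
rests, with i.i.d. Gaussian angle noise (default SD 0.5°, the order of
IMU-skeletal-model angle noise) and per-trial duration jitter uniform
in [0.9, 1.1].

Each movement is driven by two latent activations through a
subject-specific orthonormal basis.  Design choices that matter:

* **Activation profiles.**  Channel n is the raised-cosine pulse
  s = sin²(πu) sharpened by ((0.7 + 0.6s)/1.3)ⁿ: exact-zero endpoints,
  unit peak at mid-movement, quadratic onset/offset tails (what the
  speed-threshold segmenter expects), and linearly independent time
  courses so a single trial genuinely spans both latent dimensions.
* **Target amplitudes.**  a₁ = A(1 + 0.4·cos θ_k),
  a₂ = A(0.35·sin θ_k + 0.03) for the k-th of 8 grid directions, with
  A = 40°.  The first synergy is strongly engaged for every target (no
  reach is near zero-effort, keeping all movements detectable) while
  the second modulates with about a quarter of the spread, producing
  the dominant-first variance spectrum characteristic of planar
  reaching (first component typically 0.75–0.9 of the variance, first
  two ≈ 1).
* **Reference basis.**  The first synergy loads appreciably on every
  channel and dominates elbow flexion; the second is led by
  pronation–supination, loads on the shoulder, and has zero
  elbow-flexion weight (one shoulder entry is solved for so the raw
  columns are exactly orthogonal).  Subject bases are this reference
  plus entry-wise Gaussian perturbations (default scale 0.08),
  re-orthonormalized; zero perturbation yields statistically
  exchangeable subjects, which is the null case for transfer tests.
* **Baselines** are per-subject draws in anatomically plausible ranges
  (shoulder ±40°, pronation ±30°, elbow 40–110°); target amplitudes are
  shared across subjects (one physical target grid).

What the generator does **not** emulate: IMU sensor physics and
orientation-filter drift, postural drift during rests, trial-to-trial
variability in movement shape beyond duration jitter and additive
noise, anatomical joint limits on the summed excursions, and any
nonlinearity between synergy activations and joint angles.  Passing
recovery and transfer tests therefore shows the pipeline is correct and
well-conditioned under its own model assumptions — not that the
decoding accuracies would transfer to human data.

## Problem sizes used in tests and the acceptance script

The test suite and acceptance script run scaled-down studies chosen to
exercise every code path at interactive runtimes: cohorts of 1–5
subjects, 3–5 repetitions per target, 1.0–1.2 s movements with 0.7 s
rests (shorter movements need the longer rest so the smoothed-speed
close condition has clearance), networks of 12–24 hidden units trained
for 3–40 epochs.  Statistical worked examples run at full published
scale, since their inputs are the printed group summaries.

## Known limitations

* The segmenter assumes rest–move–rest structure with near-constant
  rests; it has no gap-filling and rejects sessions whose detected and
  labeled movement counts disagree rather than attempting repair.
* Min-max normalization is sensitive to outliers in the training range;
  records deliberately refuse constant channels.
* With two latent factors of similar variance the per-subject PCA frame
  is ill-determined and cross-subject substitution of `W` degrades;
  this is a property of the method, reproduced (not fixed) here.
* The studentized-range p-values are exact only for the balanced
  design; unequal group sizes raise an error instead of silently
  approximating.
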