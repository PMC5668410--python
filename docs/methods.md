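# Methods

`frameindex` estimates the *coordinate frame* of a neural region's
directional code: when the forearm rotates between a pronated (Pro) and a
midway (Mid) posture, does the region's representation of an aiming
direction stay fixed in the world (extrinsic frame, rotation index 0°),
rotate with the joint (joint-like frame, 90°), or rotate partially
(muscle-like frame, intermediate angles)?  The package implements three
complementary analyses over trial-by-feature response matrices, plus a
synthetic population-code generator and a block-design preprocessing
chain that make every stage testable without access to recordings.

## The rotation-model common decoder

The core computation treats the aiming direction as a unit vector
v = (cos θ, sin θ) in the task frame and asks a single linear map
**w** (2 × N, N features) to decode it from both postures at once, with
the Mid-posture readout rotated by a candidate angle Δθ:

    v = w r_Pro = R(Δθ) w r_Mid ,   R(Δθ) = [[cos Δθ, −sin Δθ], [sin Δθ, cos Δθ]]

Rearranged for fitting, Pro samples are paired with target v and Mid
samples with R(−Δθ) v, and **w** is a penalized linear regression on the
stacked design.  Each candidate Δθ on a grid (default −45°…315° in 5°
steps, both bounds configurable) is scored by the cross-validated mean
squared error between the unit target vector and the predicted 2-vector
(Mid predictions rotated by R(Δθ) back into the task frame; the
prediction's norm is reported but never constrained).  The minimizer of
this error curve is the coordinate index Δθ̂.

*Cross-validation structure.* The outer loop holds out one run of each
posture (the i-th Pro run together with the i-th Mid run); the inner
loop is leave-one-run-out over the remaining runs and selects the
regularization strength per grid point.  Δθ̂ is by default the argmin of
the outer-fold test error over the full grid; a fully nested variant
(`select_on="inner"`, Δθ chosen on inner folds only, outer folds used
purely for error reporting) is available for selection-bias checks.
Both modes are labeled in the results object.

*Estimator family.* The penalty is a configuration switch.  The default
is an L2 (ridge) penalty: because the stacked targets depend on Δθ only
through a right-multiplication by R(Δθ), the ridge solution decomposes
exactly as W(Δθ, α) = W_a(α) + W_b(α) R(Δθ), so a single
eigendecomposition per fold serves every (α, Δθ) pair and each fold's
error curve is exactly c0 + c1 cos Δθ + c2 sin Δθ.  This makes the
nested grid search exact and fast, and the estimator family (penalized
linear map), not the specific prior, is what drives Δθ̂.  A
sparsity-promoting L1 (lasso) penalty is available (`estimator="lasso"`,
via scikit-learn) and is cross-checked against the ridge path in the
test suite at matched small scale; it refits per grid point and is
correspondingly slower.

*Numerical choices.* An explicit 2-vector intercept is fitted
(toggleable); features are centered within each training fold, targets
are not otherwise centered.  Default regularization path:
α ∈ 10^{−2} … 10^{4} (7 log-spaced values).  Ties at the curve minimum
resolve to the angle of smallest wrapped magnitude (closest to the
extrinsic frame), positive preferred at equal magnitude.  A curve that
is flat within 1e−12 (relative) is flagged "uninformative" and Δθ̂ is
reported as NaN rather than an arbitrary grid point.  Evaluating Δθ and
Δθ + 360° yields identical fits.

*Group level.* Per-participant Δθ̂ values are summarized by a circular
mean with a 95% CI and tested against reference frames (0° extrinsic,
90° joint, optionally an empirical muscle angle) with the circular
one-sample test described below.

## Label decoding and the asymmetry index

An 8-way linear SVM (one-vs-rest, squared hinge, C = 1 fixed across all
analyses; ties resolve deterministically to the lowest direction label)
classifies the aiming direction from the patterns.  Predictions are
summarized as a generalization profile: the fraction of predictions per
signed offset (predicted − true, wrapped to (−180°, 180]) from the
tested direction.  Within-posture profiles use leave-one-run-out
cross-validation; across-posture profiles train on all runs of one
posture and test on all runs of the other.

The two across-posture transfers estimate the same Pro→Mid frame
rotation with opposite raw signs (a +Δθ rotation puts the Mid→Pro mode
at +Δθ and the Pro→Mid mode at −Δθ).  The canonical across-posture
profile therefore aligns both transfers on the coordinate-index axis
(Pro→Mid offsets are negated) before pooling with equal weight, so a
frame rotation of +Δθ appears as a mode at +Δθ regardless of transfer
direction.  This alignment was a genuinely open design point; it was
fixed so that the profile axis, the asymmetry index and the coordinate
index Δθ̂ all share one sign convention.

The asymmetry index of a profile is the mean fraction over offsets
{+45°, +90°, +135°} minus the mean over {−45°, −90°, −135°}; the 0° bin
(the peak, not an error) and the 180° bin (sign-ambiguous) are excluded.
The within/across contrast is a paired t-test over participants on
(across − within), Bonferroni-corrected by a configurable family size
(default 9, mirroring a multi-region analysis family).  Zero-variance
pairings are reported with a degeneracy flag (p = 1 for no effect,
p → 0 otherwise) instead of a NaN t-statistic.

## Cosine tuning and circular statistics

Directional tuning of a scalar channel (a muscle's trial-mean
activation) is modelled as f(θ) = k·cos(θ − µ) + b and fitted in closed
form through the linear reparameterization f = A cos θ + B sin θ + b
with k = √(A² + B²), µ = atan2(B, A); no iterative optimizer.  Negative
amplitudes are impossible by construction (the sign is absorbed into µ);
fits with k below 1e−9 of the response scale are flagged untuned and
their µ is undefined.  The Pro→Mid preferred-direction shift is the
signed circular difference µ_Pro − µ_Mid on (−180°, 180°],
clockwise-positive — the convention in which empirical muscle rotations
are quoted.

Circular summaries use the mean resultant vector: mean direction is its
argument; the 95% CI halfwidth is Fisher's dispersion-based large-sample
formula arcsin(z·√(δ̂/n)), falling back to a seeded bootstrap percentile
interval when the dispersion is too large for the closed form (the
method actually used is recorded in the output).  The one-sample test of
a hypothesized mean direction is a bootstrap test (default 10,000
seeded resamples) on the absolute circular deviation of the mean
direction, chosen over parametric alternatives because it needs no
von Mises assumption; p = (1 + #{dev_boot ≥ dev_obs}) / (B + 1).

## Preprocessing chain

Raw per-run series (volumes × voxels, TR = 2 s) pass through a fixed
order: hemodynamic shift → baseline normalization → linear detrend →
trial-pattern extraction → z-scoring.

- **Shift**: signals are attributed to events 4 s earlier (a whole
  number of TRs enforced) by dropping the leading volumes.
- **Baseline normalization**: each voxel is divided by its mean over the
  initial 20 s rest period; a rest mean below 1e−12 of the run scale is
  a hard error naming the voxel.
- **Detrend**: a per-voxel linear trend is removed with the run mean
  preserved.  The slope is estimated from the task-free volumes (initial
  rest plus terminal rest) rather than from all volumes: block-related
  signal cannot then leak into the trend estimate, which keeps the
  noiseless round trip (generator → preprocessing → patterns) exact to
  machine precision instead of ~1e−4.  The operation is idempotent.
- **Extraction**: each 6 s block contributes its 3 pattern-carrying
  volumes as samples ("volume" mode, the default) or their average
  ("trial" mode).
- **Z-scoring**: each sample's feature vector is standardized on its own
  (mean 0, sd 1 across features, population sd), equalizing activation
  magnitude between postures.  "Per volume across voxels" was chosen
  over "per voxel across volumes" because the sample vector is the unit
  the classifiers consume.  Zero-variance samples are zeroed and
  reported as warnings rather than dropped, keeping feature indices
  stable across runs.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not the physiology of any particular region:

- Each voxel pools a private subpopulation of `n_neurons_per_voxel`
  cosine-tuned units (uniform preferred directions; amplitudes and
  baselines uniform in configurable ranges) through nonnegative
  row-normalized mixing weights.  Cosine tuning is closed under such
  mixing, so each voxel is itself a weak cosine channel with a random
  phase; with 20 units per voxel the expected tuned amplitude is ≈ 0.25
  response units against a unit-mean tuning amplitude.
- From Pro to Mid every unit's preferred direction moves by
  `delta_theta_true` plus a private Gaussian jitter (default sd 10°,
  mirroring the ~18° between-muscle spread reported for empirical wrist
  rotations), so the ground-truth coordinate index is known exactly.
  `delta_theta_true` is measured along the direction-label axis: a Mid
  trial at label θ equals a Pro trial at label θ − Δθ (exactly so when
  Δθ is on the 45° lattice and jitter and noise are zero).
- Trials carry i.i.d. Gaussian noise (`noise_sd`, default 0.2 response
  units ≈ the per-voxel tuned amplitude), organized into 8 runs per
  posture × 32 trials (8 directions × 4 repetitions, randomized order
  per run).  The default noise level places the simulated region in the
  operating regime the analysis assumes — within-posture classifier
  accuracy comfortably above 0.5 — while keeping single-voxel tuning
  weak.
- The EMG generator renders per-trial mean activations of cosine-tuned
  muscles (default 10 trials per direction and posture); its `pd_shift`
  is quoted clockwise-positive (µ_Mid = µ_Pro − shift), matching how
  empirical muscle rotations are reported.  Note the voxel generator's
  `delta_theta_true` and the EMG `pd_shift` are therefore quoted in
  opposite rotational senses; each matches the convention of its
  downstream analysis, and each round-trips through its own estimator
  to +its own value.
- The time-series renderer is the exact inverse of the preprocessing
  chain: 20 s rest, 6 s blocks with patterns delayed 4 s, 6 s terminal
  rest (109 volumes for a 32-trial run), a configurable baseline level
  and linear drift.

What the generator deliberately does **not** model: hemodynamic
convolution beyond the fixed 4 s delay, physiological (temporally or
spatially correlated) noise, head motion, voxel-size or ROI-geometry
effects, and behavioral errors in the produced force direction.  Passing
tests therefore demonstrate that the estimators recover the structure
they target when their assumptions hold at realistic SNR — not that any
particular empirical dataset would yield the same indices.

## Problem sizes used in the checks

The simulated study conditions are 12 participants, 200 voxels,
20 units/voxel, 8 runs per posture of 32 trials, noise sd 0.2, jitter
sd 10°.  The parameter-recovery check runs 20 replicate studies per
condition at Δθ_true ∈ {0°, 30°, 58.8°, 90°}; profile and asymmetry
checks use single studies of 4–12 participants; algebraic and oracle
checks run at reduced sizes (≤ 4 features) where exact comparisons are
meaningful.

## Known limitations

- The ridge fast path assumes the squared-error loss of the rotation
  model; other losses would lose the sinusoidal decomposition.
- The bootstrap circular test is approximate for very small n (< 5) and
  its minimum attainable p is 1/(B+1).
- With strong per-unit jitter the "true" index of a simulated region is
  itself only defined up to the population average of the jittered
  rotations.
- The 5° grid quantizes Δθ̂; group means inherit that quantization at
  very low noise.
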