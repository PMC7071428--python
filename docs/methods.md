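# Methods

This note records the models, conventions and numerical choices behind
`playmotion`, in the order the pipeline applies them.

## Sensor model and containers

A recording is a sequence of paired 640×480 uint16 frames at a nominal
30 Hz: an infrared image and a depth image whose pixels are
sensor-to-object distances in millimeters (0 = no reading). Timestamps are
stored per frame (milliseconds on the acquisition clock) rather than
assumed equidistant; every downstream Δt is computed from data. The
`.k3dv` container is a plain little-endian dump (magic `K3DV`, version,
width/height/count, then per-frame timestamp + both payloads); a directory
of `ir_%06d` / `depth_%06d` 16-bit TIFF/PNG images with a `timestamps.csv`
is read interchangeably.

## Metric calibration

Imaging an object of known height (1.75 m) at several distances yields
per-sighting scaling values `true_height / pixel_height` (m/pixel); an
ordinary least-squares line of scaling on depth gives

    m/pixel = slope · depth_mm + intercept,

with the study's fitted line (`1.5e-06`, `6.4e-04`) shipped as
`DEFAULT_CALIBRATION`. The fit requires at least two distinct depths and is
exact through two exact points. The line is specific to the room it was
calibrated in; other spaces need refitting.

## Segmentation chain

Foreground is defined by frame differencing on signed integers,
`|f_i − f_j| > pixel_threshold` (default 1400), with the *count* threshold
T = 14,000 separately marking whole frames unevaluable. The cleanup chain
is fixed in order: Sobel edge enhancement (binarized gradient magnitude),
3×3 majority fill (neighborhood sum > 5, zero-padded), closing with a
radius-9 disk, morphological reconstruction by dilation with the closed
image as marker — constrained to the difference mask, since reconstruction
requires marker ≤ mask — a 25×25-square dilation that merges an object's
difference fragments (a moving body yields separate leading/trailing
silhouette fragments) into one component, 8-connected hole filling, and
one thinning iteration. Thinning is deliberately *not* run to idempotence:
its purpose is shaving residual noise, and full skeletonization would push
every object below the 375 px component floor. Components are kept iff
their pixel count is ≥ 375.

All structuring elements fit inside a 40 px margin, so the chain is
evaluated on the foreground bounding box plus that margin; this is
bit-identical to whole-frame evaluation with zero padding and is purely a
speed optimization.

## Tracking

Association is greedy nearest-predicted-centroid with a 50 px/frame gate
and a 15-frame timeout, both chosen from the maximum plausible subject
speed at working depths and exposed in config. Each track runs a
constant-velocity Kalman filter (state: position + velocity in x, y;
process variance 1 px², measurement variance 4 px², initial covariance
100·I) — mild smoothing that converges below 1 px error on noiseless
constant-velocity paths within ~15 frames. Depth per entry comes from the
rounded smoothed centroid, expanding 3×3 → 21×21 windows until a nonzero
reading is found (nearest by Euclidean distance, raster-order
tie-break); an entry with no reading contributes nothing to the z plane.
Child identity is a manual-review artifact: a whitelist of track ids is
merged into one time-ordered stream per child.

## Fourier velocity estimation

For each plane and each 1-s window of K = 30 frames, the object's
intensity value (infrared intensity for x/y; the depth reading itself for
z) is placed at its coordinate in a zero 1-D projection array, the array is
multiplied elementwise by `exp(i·2π·a1·q·Δt)` (q = array index) and summed
— algebraically the single nonzero element survives, so the per-frame
scalar is computed directly. The scaling constant is `a1 = K / v_max` with
expected maxima of 4 m/s (x, z) and 2.8 m/s (y); a1 is kept real-valued
(7.5 and ≈10.714) because rounding it would change the velocity scale, with
integer rounding available via `integer_a1`.

For uniform motion of u px/frame the K-point FFT of the scalars peaks at
bin `k = a1·u`, so pixels of motion per window equal `k/(a1·Δt)`
(`= K·k/a1` at Δt = 1/K s). Because the encoding is a complex exponential,
the spectrum is one-sided: a peak in the upper half of the FFT is a
negative-frequency peak and flips the sign of the velocity. Peak search
takes the dominant non-DC bin in each half; a stationary object holds all
its energy in DC, and a non-DC peak that cannot rival half the DC magnitude
is treated as rounding jitter rather than motion (true motion of at least
one bin completes whole phase cycles and cancels DC). Windows with more
than half their frames unevaluable yield a missing velocity sample.

Two structural properties matter for interpretation:

* **Resolution.** Velocity is quantized to the bin spacing `K/a1` px/s
  (4 px/s in x/z, 2.8 px/s in y). Validation fixtures place scripted pixel
  speeds on bin centers; off-bin speeds incur up to half a bin of
  quantization.
* **Measurement band.** The peak is unambiguous only below the Nyquist bin,
  i.e. |u| < v_max/2 px/frame. Converting pixels to m/s multiplies by the
  depth-dependent scaling, so a given metric speed is measurable only when
  the subject is far enough that its pixel-domain speed stays inside the
  band. The synthetic constant-velocity fixtures therefore script large
  depths (≈7–58 m under the default calibration) for high metric speeds;
  these exceed a real structured-light sensor's range but are exactly
  representable in the container, and they are the conditions under which
  the estimator's frequency–velocity relation can be exercised across the
  0.3–3.5 m/s range.

Pixel velocities convert to m/s by the calibration scaling at the window's
mean depth, clipped at ±v_max with a logged warning. The z plane mirrors
the x/y construction with depth (mm) as the projection axis, so its
"pixel" velocity is a depth-bin rate and the same scaling applies; the
synthetic ground truth adopts the identical convention, which is why its
scripted depth rates are chosen as `v / scaling(depth)` mm/s.

## Accelerations and epochs

Velocity series are differenced at 1 Hz and divided by standard gravity
(9.80665 m/s²) to give acceleration in g; the first sample is 0 and missing
velocities propagate. Per second, `VM = √(ax²+ay²+az²)·1000`; 5 s epochs
take the mean of available seconds by default (`sum` available in config —
the mean is robust to missing seconds) and are missing when more than two
seconds are missing.

## Observation layer

Epoch reintegration multiplies each code by its within-epoch frequency and
normalizes — algebraically the arithmetic mean of the scored codes.
Not-in-frame seconds (code 5) shrink the denominator; only an all-code-5
epoch is missing. Cut points: SED < 2, LPA 2–2.99, MVPA ≥ 3, with the
boundary score 3.0 classified MVPA. Rater reliability uses ICC(2,1)
(two-way random effects, absolute agreement, single measure) — the
stricter conventional choice for coder reliability; ICC(3,1) is available
for comparison. Both are computed via pingouin and cross-checked in the
tests against a from-scratch ANOVA variance-components oracle.

## Classifiers and evaluation

Gini CARTs on the single VM feature: three one-vs-all trees (SED, LPA,
MVPA against the rest) and one multiclass tree. Hyperparameters (min leaf
20 epochs, max depth 8, no pruning) are fixed and config-exposed;
determinism comes from the fixed seed. The default evaluation protocol is
resubstitution — matching how the original study's metrics appear to have
been computed — with AUC taken on leaf-posterior scores (rank statistic,
tied scores half-credited), percentile-bootstrap 95% CIs over epoch
resampling, and sensitivity/specificity at the hard labels. A permutation
control is meaningful only out-of-sample: a depth-8 tree memorizes noise at
resubstitution, so the chance-level check trains on one half of shuffled
data and scores the other.

## Equivalence testing

Per-child %time differences (estimated − observed; negative =
underestimate) are tested for equivalence with two one-sided Wilcoxon
signed-rank tests of the differences shifted by ∓Δ (Δ = 10% and 20%),
reporting the larger one-sided p and declaring equivalence at α = 0.05;
a sign-test variant is available. The median difference carries a seeded
2,000-resample percentile-bootstrap 90% CI. When all shifted differences
are exactly zero the one-sided p is 0.5 (no evidence either way) rather
than an error.

## Synthetic study conditions

The frame generator renders rectangles/ellipses on a uniform mid-gray
infrared background (value 8000) with optional clipped Gaussian noise, a
constant 4000 mm depth far-plane, integral rasterization (sensor output is
integral), and scripted depth dropouts (depth = 0 inside the object) that
reproduce the flush-against-the-wall failure of structured-light sensing.
Ground-truth observation codes derive from scripted speed
(< 0.05 / < 0.5 / < 1.5 m/s → codes 1/2/3, else 4) unless supplied
explicitly. The generator does not model photorealism, occlusion physics or
the sensor's structured-light noise pattern — so passing tests demonstrate
the correctness of the measurement chain under clean conditions, not
robustness to real-world imaging artifacts.

The epoch-level study simulator draws, per child, intensity shares from a
Dirichlet centered on the play-session pattern (LPA most common, then
MVPA, then SED; concentration 30) and VM values from class-conditional
lognormals with medians 5 / 30 / 150 (×1000 g) and σ_log = 0.5 — ordered,
moderately overlapping classes whose Bayes confusion stays well under 15%.
Default size: 10 children × 60 epochs (5 min at 5 s epochs), matching the
original study's analyzed volume.

Validation problem sizes: the velocity-recovery suite uses 12 fixtures
(4 velocities × 3 planes) of 10 s each in the acceptance script and a
3 × 3 grid of 8 s fixtures in the test suite; segmentation checks use 2–3 s
scenes. These sizes give every per-second statistic dozens to hundreds of
observations while keeping a full validation run to a few minutes.

## Known limitations

* The velocity estimator's band/resolution trade-off is fixed by a1; real
  nearby subjects moving fast alias, exactly as in the original design.
* Depth-plane velocity is a calibrated bin rate, not a direct mm/s
  measurement; its metric meaning follows the same scaling convention as
  x/y rather than true anteroposterior kinematics.
* The VM trace follows the whole-body centroid, so motionless-but-upright
  behaviors (quiet standing) are indistinguishable from sitting, and
  load-carrying walks read as light activity — both known failure modes of
  centroid/waist-style measurement.
* One child per whitelist: no appearance-based re-identification, no
  occlusion reasoning, no multi-camera fusion.
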