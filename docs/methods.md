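# Methods

## Problem and overall design

`oculoscreen` implements a screening computation for intermittent
strabismus from wearable, per-eye infrared eye tracking. Because
intermittent deviation appears only episodically, a single static
photograph is a poor screen; the method instead records both eyes while
the subject pursues a moving target, summarizes each recording as a
16-component oculomotor descriptor, and classifies subjects with
leave-one-out cross-validation (LOOCV). The package contains the full
chain — image-level pupil and canthus extraction, the projection
statistic E, featurization, classification, attribution — plus a
ground-truthed synthetic data generator, so every stage is testable
without access to clinical recordings.

## Pupil extraction with boundary-point constraints

Per frame: Gaussian denoising (window 5, sigma by the usual
`0.3·((k−1)/2−1)+0.8` rule), binarization by Otsu's threshold computed on
the darkest-quartile pixels only (robust to illumination gradients),
largest dark connected component, Moore-neighbor contour tracing
(8-connected, closed chain), and a direct algebraic least-squares ellipse
fit (via scikit-image's conic estimator) giving the *coarse* ellipse with
center O, semi-axes a ≥ b.

Corneal glints that straddle the pupil boundary carve concave dents into
the traced chain; eyelashes and eyelid edges add spikes and straight
segments. Each chain point C with neighbors P and N (taken at stride k
along the chain) is screened by three constraints before a refit:

1. *Tangent direction*: |cos∠(OC, PN)| < 0.3. Both vectors are unit
   normalized; the printed form of this screen uses a raw pixel dot
   product against 0.3, which is not scale-invariant, so normalization is
   applied to make the threshold resolution-independent.
2. *Convexity*: the discrete second difference (CN − PC) must make an
   obtuse angle with OC. A zero second difference (locally straight
   chain) is treated as undefined and rejected.
3. *Radial extent*: b − δ_lo < |OC| < a + δ_hi, with δ_hi = 3 px and
   δ_lo = 1.5 px. The upper slack prevents over-deletion near the major
   axis; the lower slack admits true minor-axis points that a hard bound
   at b would reject (for a circular pupil, *every* boundary point sits at
   |OC| = b up to discretization).

Survivors are refit; if fewer than 5 points or less than 10% of the chain
survive, the coarse fit is returned flagged `refinement-degraded` (the
fallback policy is this package's choice). One screen-and-refit pass is
the default; iteration to convergence is available but off.

**Neighbor stride.** On pixel-quantized chains, stride-1 tangent chords
are quantized to 8 directions and straight runs have a zero second
difference, so the screens reject most of a perfectly clean boundary.
The default stride is 4, which makes the tangent estimate fine enough
that clean analytic boundaries pass essentially everywhere while glint
dents are still rejected; the stride is configurable.

Measured on 100 rendered frames with one glint occluding 10–20% of the
boundary arc (the acceptance suite recomputes this): the refined fit's
median center error is ≈ 0.2 px versus ≈ 3.5–4 px for the coarse fit.

## Canthus extraction

Per frame: Gaussian blur; the palpebral-fissure band is the row range of
pixels brighter than the sclera threshold (midway between the image
median, i.e. skin, and the 99.5th percentile); coarse corner candidates
are the lateral extremes of that bright eye region, optionally snapped to
the nearest Harris corner peak within 5 px (the Harris response also
provides the confidence percentile); each candidate's 31×31 ROI is
histogram-equalized and binarized, and the apex is the extremal-x pixel
of the wedge component in the corner's direction. The local binarization
is intersected with the frame-level sclera threshold so an illumination
gradient cannot pull bright skin into the wedge.

Sequence tracking adds a 15-frame temporal median filter (the device is
head-mounted, so canthi are near-static) and fills failed frames from the
running median. Side convention: the nasal (inner) canthus of the left
eye is on the image-right side, and vice versa for the right eye.

## The projection statistic E and the 16 features

With pupil center P and canthi CI (inner) and CO (outer),

    E = (CIP · CICO) / |CICO|²

is the dimensionless fraction of the inner→outer canthus baseline at
which the pupil center projects (0 at CI, 1 at CO). It normalizes away
head position, pupil size and facial geometry. Per subject the recording
yields per-frame series for each eye (Eml, Emr, N = 540 frames) and
their mean Ema; frames lost to blinks or occlusion are linearly
interpolated when the gap is ≤ 10 frames, and a subject is flagged if
more than 20% of frames are missing.

The descriptor (k is the subject index):

| feature | definition |
|---|---|
| F1–F4 | mean, population sd (1/N), max, min of Ema |
| F5, F6 | mean and sd (both 1/(N−1)) of the absolute first difference of Ema |
| F7, F8 | cross-eye inner- and outer-canthus distances (pixels, per-frame median) |
| F9, F10 | per-eye mode of E over the first 70 frames (central fixation) |
| F11, F12 | mean (1/N) of the absolute deviation from the normal standard curve, per eye |
| F13, F14 | mean (1/(N−1)) of the absolute first difference of that deviation |
| F15, F16 | sd (1/(N−1)) of that absolute first difference about F13/F14 |

The mixed variance denominators (1/N for F2, F11, F12; 1/(N−1) for the
first-difference statistics) follow the method's printed definitions and
are kept as-is. The mode of a continuous E requires quantization: bins
of width 0.01, ties broken toward the bin nearest the window median.
First differences in F13–F16 are taken in absolute value, mirroring the
explicitly absolute F5/F6.

**Standard curve.** The normal binocular reference trajectory is not
specified numerically anywhere, so the default is the per-frame median
across the *normal subjects of the training fold only*, recomputed inside
every LOOCV fold — this is the leakage-critical choice. A fallback
analytic mode rescales the ideal target template to the training
subjects' fixation modes when fewer than 3 normals are available.

**F7/F8 calibration.** The two eye cameras have separate image frames;
cross-eye distances require a rigid inter-camera offset supplied as
configuration (the simulator emits it as ground truth). Real-device
calibration is out of scope and documented as required metadata.

## Synthetic data generator

The generator defines the study conditions; it is not a tuning dial.

*Image layer.* 320×240 8-bit frames: skin (gray 120) around an
almond-shaped fissure (parabolic lid curves through the two canthi;
opening height 1.4·b + 8 px), sclera 190, iris disc (radius 2.1·a) 90,
pupil ellipse 30, eyelashes as ~2 px strokes at gray 45, Purkinje-style
glints as discs at 250, plus a linear illumination gradient and Gaussian
sensor noise. Rendering is bit-deterministic given (scene, seed). For a
glint centered on a circular pupil boundary, the occluded arc fraction f
fixes the glint radius via g = 2r·sin(πf/2); the stress sampler draws
f ∈ [0.10, 0.20].

*Series layer.* The pursuit protocol: 70-frame central fixation, then a
piecewise-linear sweep through five screen positions visited in the order
1-2-3-4-5-2 over the remaining 470 of 540 frames. The layout (1 upper
left, 2 center, 3 upper right, 4 lower right, 5 lower left) is a design
choice — only the visiting order and duration are specified by the
protocol — and its horizontal coordinate maps linearly to E ∈
[0.25, 0.75], i.e. the pupil sits mid-way between the canthi at primary
gaze. This yields three peak/valley alternations, matching the described
normal binocular curves.

Per-subject recordings add: per-eye kappa-angle baseline offsets
(N(0, 0.02)); E-measurement noise (sd 0.02); blink artifacts (3–8 frame
dips of both eyes toward the inner canthus, ~2 per recording); and, for
patients, intermittent deviation episodes — Poisson(3) count clipped to
a minimum of 2, 60 frames each, amplitude 0.15 E-units, one eye per
episode (probability ½ each side, sign random), starting only after the
fixation window (deviation is induced by the pursuit task). E is clamped
to [−0.2, 1.2] and clamp events are counted. The default cohort is 35
normal + 35 patient subjects.

*Dynamics-only cohort.* For attribution experiments a variant cohort
confines the class signal to F13–F16: patient episodes are zero-mean
anti-phase binocular oscillation (the eyes alternate in opposite
directions each frame, leaving Ema untouched), while normal subjects
receive matched anti-symmetric constant-offset vergence-wander windows of
the same amplitude, rate and duration. Instantaneous |D| statistics are
thereby matched between classes and only the first-difference features
carry signal.

*What the generator does not emulate:* photorealistic texture, vertical
gaze, saccadic main-sequence dynamics, pupillometric size changes,
head-slip of the device, or inter-subject variation in episode dynamics
beyond amplitude/rate/duration. Passing tests therefore demonstrate the
computational chain is correct and self-consistent under these
idealizations, not clinical performance on real recordings.

## Classification, attribution, ablation

Eight families with fixed defaults (no tuning): random forest (100
trees, balanced class weights), logistic regression, decision tree, RBF
SVM, kNN (k = 5), Gaussian naive Bayes, gradient-boosted trees, AdaBoost.
Scale-sensitive families (LR, SVM, kNN) are standardized inside an
sklearn pipeline, so standardization is fold-wise. `patient` is the
positive class; predicted probability ≥ 0.5 calls patient (the tie favors
screening sensitivity). The forest's balanced class weights remove the
majority-class drift that the 34-vs-35 leave-one-out training folds
would otherwise induce — without them a no-signal forest scores
systematically below chance under label permutation, because the
held-out subject's label is anti-correlated with the training majority.

Attribution is a seeded Monte-Carlo estimate of Shapley values of the
patient probability: for each subject and each of 64 sampled feature
permutations, features switch one at a time from a cohort-drawn
background row to the subject's values, and successive probability
increments are averaged. Weights are normalized mean absolute values
(sum 1). This estimator is model-agnostic and is used for all families.
Ablation drops listed feature columns and reruns the full LOOCV.

## Numerical choices and degenerate inputs

- Ellipse axes are normalized to a ≥ b with tilt folded into [0, π);
  fits with < 5 points, collinear points, or non-finite parameters raise.
- Constraint screens are pure predicates; undefined cases (zero-length
  vectors, zero second difference) reject the point.
- `compute_E` raises on coincident canthi; `extract_pupil` never raises
  on a bad frame but returns a flagged missing result, so sequences
  survive blinks and full occlusion.
- Binarization requires a dark component of ≥ 100 px; a frame whose mask
  area falls below 30% of the running median area is flagged
  blink-suspect.
- All randomness flows through `numpy.random.default_rng` seeds; renders,
  series, cohorts, LOOCV and attribution are reproducible bit-for-bit.

## Problem sizes used in the test and acceptance runs

Rendered-frame experiments use 100 frames (pupil) and 25 frames
(canthus) at 320×240; classification experiments use 70-subject cohorts
of 540-frame series, 20 label permutations for the null, 10 cohorts for
attribution ranking, and a 4-point amplitude sweep. These sizes give
stable medians and binomial bands while keeping a full run in minutes on
one CPU.

## Known limitations

- The canthus pipeline is validated on the renderer's lid geometry;
  real-world lid texture, makeup, or epicanthal folds are untested.
- The analytic standard-curve mode assumes the protocol timing is exact;
  cohort-median mode is preferred whenever ≥ 3 normal training subjects
  exist.
- The Shapley estimator has Monte-Carlo error ~1/√64 per value; rankings
  of near-tied weights can fluctuate between seeds.
- LOOCV pooled metrics have no variance estimate; treat single-cohort
  accuracies as point estimates.
- Pooled leave-one-out accuracy is *pessimistically* biased when the
  classes carry no signal: holding out a subject leaves its own group
  under-represented in training, so a memorizing classifier is
  anti-correlated with the held-out label. Balanced class weights remove
  the global 34-vs-35 drift, but a residual below-chance null (observed
  roughly 0.36–0.49 across seeds, strongest for fully exchangeable
  classes) is inherent to the evaluation design. It makes the screen
  conservative, not leaky: information leakage would push the permuted
  null *above* chance.
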