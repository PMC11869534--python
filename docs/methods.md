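# Methods

## Problem setting

A markerless pose-estimation model tracks 13 named facial key points
(four per eye, the nose tip, and four mouth points) on video frames of
cotton-top tamarins at a working resolution of 960 × 540 px, emitting
per-frame `(x, y, likelihood)` triples in the three-header-row CSV
dialect of the tracking tool. The package converts these tracks into
facial-gesture features and evaluates how well the face alone predicts
vocal activity (2 classes) and behavioral context (8 classes: vo, fe,
lo, rs, sc, sa, oa, yw), alongside landmark-validation metrics.

## Geometric preprocessing

**Cutoff.** A frame enters the analysis only if *all* landmarks have
likelihood strictly greater than 0.6 ("fully crossed"). The comparison
is strict; a likelihood of exactly 0.6 does not count as detected.
Filtering acts on raw predictions before any geometry, and missing
points are carried as NaN coordinates with likelihood 0 by the readers,
so inclusion decisions live in exactly one place.

**Alignment.** In-plane head roll is removed by rotating each frame by
φ = π − atan2(Δy, Δx), Δ = LeftEye_Inner − RightEye_Inner, wrapped to
(−π, π], which sends the inner-eye vector to the 180° direction
(negative x) of the y-down image frame. The rotation center is the
inner-eye midpoint; the choice of center is observationally irrelevant
downstream (distances are translation-invariant) but fixes coordinate
exports. Alignment is an isometry, so it provably cannot change any
distance feature; the test suite asserts this null effect rather than
assuming it.

**Distances and normalization.** All 78 pairwise Euclidean distances
are computed in condensed (lexicographic-by-index) order and divided by
the inner-eye distance, whose entry is then exactly 1 and is dropped,
leaving 77 features invariant under any similarity transform of the
input (verified to 1e-9 over random transforms). Division by a zero
inner-eye distance and coincident inner-eye points raise
degenerate-geometry errors.

## Feature pruning

The correlation structure of facial distances is strong (neighboring
pairs move together), so features are reduced before classification:
compute the absolute Pearson correlation matrix, then repeatedly locate
the most-correlated remaining pair above the 0.75 threshold and drop
the member with the larger mean absolute correlation to all other
remaining features (ties drop the later column in canonical order).
This findCorrelation-style greedy reduction is deterministic, keeps one
representative per correlated group, and guarantees the retained set's
maximum |r| ≤ 0.75 — a post-condition asserted on every output. |r| is
thresholded (not signed r): a strongly anti-correlated pair is just as
redundant. The retained set is data-dependent; on the synthetic
8-class data it is typically ~20–30 of 77 columns.

## Classification harness

Each run draws a fresh class-balanced subsample without replacement
(3000 per class for voicing, 200 per class for contexts — the size of
the rarest category, yawning), splits it 70/30 *stratified by class*
(the plain split would only approximately preserve balance), and fits
three families on byte-identical folds:

- **MLP** — one hidden layer of 5 units (the size the cited
  implementation defaults to; unstated in the source design), SGD with
  learning rate 0.1, at most 100 epochs.
- **SVM** — degree-2 polynomial kernel, tuned by grid search over
  gamma ∈ {0.005, …, 0.050}, cost ∈ {1e-8, …, 1e0} (decades), coef0 ∈
  {0.1, 1, 10}. Tuning is nested 3-fold cross-validation inside the
  training fold only, so no test information leaks into model choice.
- **RFC** — 500 trees, 3 candidate variables per split.

Features are standardized (fit on the training fold) for the
scale-sensitive MLP and SVM and left raw for the forest. Metrics are
accuracy/CCR, precision, recall, and F1 — binary with the voiced class
positive for the 2-class task, macro-averaged for the 8-class task
(the averaging convention is a package choice). Aggregation reports
mean ± SD over runs and a row-normalized mean confusion matrix whose
rows sum to 100. Because every family sees identical folds within a
run, per-run CCRs are paired; algorithm comparison applies Shapiro–Wilk
to the paired differences and a paired t-test with df = runs − 1,
unadjusted for multiplicity. Zero-variance differences are flagged as
degenerate rather than reported as a number.

All randomness descends from one master seed through named
`numpy.random.SeedSequence` substreams (per-run subsample, split,
learner initialization), so any single run is independently
reproducible and every reported number is a function of (seed, config,
table). Frames are subsampled irrespective of clip membership, so
frames of one clip can straddle train and test; a clip-grouped split is
available behind `HarnessConfig.group_by_clip` but off by default to
mirror the frame-level design.

## Landmark validation

**MEAD** — per landmark, the mean ± SD (sample SD, n−1) of Euclidean
error between manual and predicted positions over frames where the
prediction passes the cutoff *and* the manual point exists; detection
counts are reported per landmark, and landmarks with zero detections
are reported absent rather than zero. **RMSE** — root mean squared
Euclidean error, per landmark and pooled, for comparing candidate
models' exported predictions. Both metrics are rigid-invariant and
scale-equivariant when the transform is applied to both sets.

**ICC** — inter-rater agreement uses ICC(2,1): two-way random effects,
absolute agreement, single rater, computed from the two-way ANOVA mean
squares with the Shrout–Fleiss F-based 95% interval, on x and y
coordinates pooled as separate subjects (per-axis estimates are also
reported so either convention can be inspected). Absolute agreement is
the right variant for annotator placement: a systematic offset between
raters must count against agreement. The implementation is validated
against an independent library computation and against the
variance-component closed form σ²_b / (σ²_b + σ²_rater) in simulation.
pingouin's ICC rounds its confidence bounds to two decimals, too coarse
for agreement values near 1, which is why the interval is computed here
exactly.

## Synthetic data generator

The generator stands in for the study's videos. A canonical face
template (unit inner-eye distance, y-down, roll-free) is deformed per
class — `mouth_open` drops the lower lip (corners follow halfway),
`mouth_width_delta` widens the corners, `eye_aperture` collapses the
eyelids toward the eye midline — plus per-frame Gaussian shape jitter
`sigma_shape`. The deformed shape passes through a per-frame similarity
transform (roll ±25°, inner-eye scale 40–90 px, translation inside the
960 × 540 frame), then additive observation noise (σ = 2 px by
default, matching a few-pixel tracking error at this resolution).
Likelihoods are drawn per landmark from a two-component mixture —
cutoff-passing U(0.75, 1) or cutoff-failing U(0, 0.55) — with failure
rates 0.05 (eyes/nose), 0.08 (mouth top/bottom), and 0.20 (mouth
sides), reproducing the mouth-side detection deficit of real tracking
and making the fully-crossed rate (~34%) available in closed form.

Scenario presets: the 8-class scenario gives yawning an extreme opening
with near-closed eyes, vocalization a large opening (hence confusable
with yawning), feeding a moderate opening with extra mouth-side
dropout, resting closed eyes, social activity widened corners, and
near-neutral scanning/locomotion/other-activity differing mainly in
jitter — a qualitative, not quantitative, emulation of the confusion
structure seen in real data. The 2-class scenario separates mean mouth
opening (0.5 vs 0.1 inner-eye units) under deliberately large shape
jitter (0.12), because many calls are produced with a closed or
semi-open mouth; the classes therefore overlap and desk-scale CCRs land
in the 85–90% range rather than at ceiling. Deformations act in the
template frame *before* the similarity transform, so class signal
survives inner-eye normalization exactly as real gestures would.

What the generator does not model: individual identity, temporal
autocorrelation within clips, non-rigid perspective distortion,
lighting/blur-driven correlated errors, and likelihoods correlated with
coordinate error. Passing tests therefore certify the pipeline's
statistical machinery and invariances, not field performance on real
video.

## Problem sizes in tests and the acceptance script

Chance calibration runs the full study sampling design (200/class ×8 or
3000/class ×2, 70/30, 500-tree forest) at 25 repetitions, a size at
which the Monte-Carlo standard error of the mean CCR is well below one
percentage point; effect recovery uses 20 runs per amplitude at 200 per
class. These sizes are the package's chosen desk-scale defaults;
`HarnessConfig(n_runs=100)` reproduces the full design.

## Known limitations

- The pruning outcome (which columns survive) depends on the data; only
  the contract (max retained |r| ≤ threshold, determinism) is
  guaranteed.
- The SVM tuning folds (3) and the MLP architecture are package
  choices where the source design is silent; both are configurable.
- The chance-calibration check uses between-run standard error, which
  conditions on the generated table; the table itself contributes
  O(1/√N) wobble around the nominal chance level.
- ICC confidence intervals assume the two-way normal ANOVA model;
  landmark coordinates on transformed faces are only approximately so.
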