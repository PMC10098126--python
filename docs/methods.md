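# Methods

This note documents the models, parameters, and design choices behind
ddhkit: what each stage computes, which constants matter and why they
have the defaults they do, what the synthetic phantoms do and do not
emulate, and the known limitations.

## Landmark rectification

A user click that misses the bony rim is pulled onto it within a square
analysis window (side `window_size`, default 30 px, clipped at image
borders; the half-width is `window_size // 2`). Processing inside the
window is:

1. **Gaussian prefilter** — kernel 5 px, σ = 1.0 px (`gaussian_kernel`,
   `gaussian_sigma`). Conventional light smoothing: enough to keep
   single-pixel noise from fragmenting the threshold mask without
   displacing a bone/soft-tissue step (a symmetric kernel keeps the 50%
   crossing on the step).
2. **Adaptive threshold** — foreground is every pixel brighter than its
   local block mean (block 11 px, `adaptive_block`) minus
   `adaptive_offset` (2 intensity units). Bone is radiodense, hence
   bright; the offset biases the mask slightly into the dark side so the
   rim is not eroded.
3. **Edge detection** — the candidate rim is the morphological boundary
   of the foreground (foreground pixels 4-adjacent to background), kept
   only where the smoothed gradient magnitude exceeds
   `edge_min_gradient` (2 intensity units/px). The gradient gate is what
   makes step 3 a real edge detector: a local-mean threshold classifies
   *both* flat regions around a step as foreground and therefore yields a
   spurious boundary band on the dark side of every edge, plus speckle
   boundaries in flat noisy regions. Both artifacts sit on near-zero
   gradient and are rejected; the true rim, a genuine intensity step,
   survives. Setting `edge_min_gradient = 0` restores the raw mask
   boundary.

All filtering context is taken from the image, not the window placement:
the window is extended by the filters' support before processing and
cropped back afterwards. This makes the detected rim a function of image
position alone, which in turn makes snapping idempotent (a snapped point
is on the rim of its own window) — the property the test suite checks.

The click then moves to the rim pixel minimizing the Euclidean distance,
with ties broken by smallest row then smallest column (a documented,
deterministic rule that makes the argmin unique). Snaps farther than
`max_snap_distance` (15 px, half the window) are refused so a click in a
structureless area is not captured by a distant edge. All eight landmarks
are eligible by default; `enabled_labels` opts labels out per study.
Snapping is integer-pixel; no sub-pixel refinement is attempted.

## Reference geometry and angles

All constructions treat coordinates as continuous. The H-line joins the
two triradiate tops; the per-side frame has **u** along the H-line
pointing laterally (away from the midline, defined as the midpoint of the
triradiate tops — a side-symmetric rule needing no display-orientation
convention) and **v** perpendicular to it pointing superiorly. "Superior"
is anchored anatomically: v points into the half-plane of the H-line
containing that side's lateral acetabular edge (the iliac side), with
negative image-y as the fallback when the edge lies exactly on the
H-line. With this anchoring, AI, LCEA, and the IHDI grade are invariant
under arbitrary rigid motion and uniform scaling of the film, not merely
under small tilts.

* **AI** = atan2(d·v, d·u) for d = edge − triradiate top: positive when
  the edge is superior to the H-line. An edge medial to the triradiate
  top is anatomically implausible but legitimate in severe dislocation,
  so it returns a value plus a warning flag rather than an error.
* **LCEA** = atan2(e·u, e·v) for e = edge − head center: positive when
  the edge is lateral to the "vertical" (the frame's v axis, i.e.
  perpendicular to the H-line — the same convention that defines Perkin's
  line, keeping the angle tilt-invariant). The annotation scheme has no
  head-center click because the femoral head is often unossified in the
  target age range (0.4–8 y); an explicit center may be supplied, else
  the H-point stands proxy and the output carries a
  `head_center_source = h_point_proxy` flag.
* **IHDI grade** of the H-point offset (p_u, p_v) from the
  Perkin–Hilgenreiner junction: grade 4 if superior to the H-line
  (p_v > 0); else grade 1 if at or medial to Perkin's line (p_u ≤ 0);
  else grade 2 if at or medial to the 45° inferolateral diagonal
  (p_u ≤ −p_v); else grade 3. Every "at or …" tie resolves to the lower
  grade, exactly as the grading scheme's wording states.

## Decision rule

A hip is dysplastic when AI **strictly exceeds** the stratum's
x̄ + 2s threshold; boundary equality is normal (literal reading of
"exceeded"), and any hip within 0.5° of its threshold is flagged
borderline, since such hips are the recognized failure mode of
radiographic DDH reading. Non-dysplastic hips are *other dislocation*
when the H-point has left Perkin's line (IHDI grade ≥ 2, configurable via
`dislocation_min_grade`), else *normal*; grade 1 is defined by a located
H-point, so a grade-1 hip can only be abnormal through its AI. Only a
high AI is abnormal — the x̄ + 2s criterion is one-sided. LCEA is
measured and reported but does not enter the rule; the rule is stated on
AI alone, and `diagnose_hip` is the single place a future LCEA criterion
would plug into.

Criteria lookup matches nationality, sex, side (a side-specific entry
beats an `either` entry) and a half-open age bracket [min, max); gaps
raise a lookup error naming the stratum, and overlapping brackets are
rejected at load time with line numbers. The shipped
`data/criteria_synthetic.tsv` is a synthetic placeholder with the correct
schema (thresholds near 31°); the genuine normative values must be
transcribed from published growth references by the user.

## Phantom generator

The generator renders stylized hemipelves, not anatomy: per side, an
ilium polygon whose inferior edge is the acetabular roof drawn at exactly
the requested AI against the (optionally tilted) H-line, and a metaphysis
quadrilateral whose superior edge is centred on the requested H-point
offset, plus an optional femoral-head disk. Landmarks are polygon
corners, so every annotated point lies on a sharp, snappable
bone/background edge. Defaults, chosen once as study-like conditions: a
640×480 8-bit image, triradiate tops ±90 px from the midline, roof length
120 px, metaphysis width 36 px, bone 200 / background 40 intensity, and
additive Gaussian noise σ = 3 (mild radiograph-like noise, clipped to
[0, 255]); all randomness flows from the spec seed. Ground truth is the
*exact* pre-noise landmark coordinates, so forward–inverse recovery of AI
and grade is exact up to float error; pixel quantization enters only when
clicks are simulated (`jitter_annotations`, round-to-integer Gaussian
displacements) or re-snapped from the rendered image.

Batches sample one severity class per study (both hips share the class;
parameters are drawn independently per hip) with AI uniform in per-class
ranges and the H-point offset uniform inside the class's IHDI region at a
≥ 4 px margin from every region boundary (twice the 2 px documented
margin, to survive rounding anywhere downstream); AI ranges keep ≥ 1.5°
clear of the diagnostic threshold. Truth labels are therefore
unambiguous, which is what makes the 100%-agreement acceptance check
meaningful.

What the phantoms do **not** emulate: projection physics, scatter or
Poisson noise, soft-tissue shading, pelvic rotation/tilt artifacts,
overlapping bony structures, and the real variability of pediatric
anatomy. Passing tests demonstrate the geometry, the decision logic, and
the rectifier's behavior on clean edges under Gaussian noise — not
clinical-grade landmark detection on real films.

## Evaluation statistics

* Rates are plain confusion-count ratios ×100. The AUC of a
  single-threshold binary rater is the two-point ROC trapezoid,
  (sensitivity + specificity)/2 on the proportion scale — the documented
  assumption under which the published rater AUCs are reproduced from
  their printed counts.
* DeLong's paired test uses the placement-value covariance estimator with
  a two-sided normal p; identical scores (zero variance, zero difference)
  degenerate to z = 0, p = 1. This is the one statistic implemented from
  scratch (no pre-installed library provides it); a case-bootstrap oracle
  cross-checks it in the tests.
* Bland–Altman: bias ± 1.96·SD of the paired differences, sample SD
  (n−1 denominator, used throughout); the bias test is a one-sample t of
  the differences against zero — for paired measurements this, rather
  than a two-sample test, is the statistically coherent reading.
* ICC is ICC(2,1) — two-way random effects, absolute agreement, single
  measurement, the standard test–retest form (computed via pingouin;
  the ANOVA mean-square formula serves as the test oracle). Zero
  between-subject variance is an error, not a number.
* Weighted kappa uses linear weights |i−j|/(k−1) (via scikit-learn, with
  the direct O/E formula as test oracle); a rater who used a single
  category makes kappa undefined and raises.

## Problem sizes and numerical notes

The acceptance script and test suite run the clean-batch check at 60
studies (120 hips), the IHDI oracle at 10,000 points, refinement-vs-jitter
at 8 phantoms × 8 landmarks, and the null-limit checks at n = 2,000
(kappa) and n = 500 (ICC) — sizes at which every stochastic check is
stable across seeds while the whole pipeline remains quick to re-run.
Geometric comparisons use 1e-6° tolerances (float error only); phantom AI
recovery is asserted at 0.5°, the quantization budget once integer clicks
are involved. Degenerate inputs fail loudly: coincident triradiate tops,
points off-image, empty criteria strata, and undefined statistics all
raise typed errors rather than returning numbers.

## Known limitations

Semi-automatic by design: landmarks must be clicked; no learned detector
is included. The construction depends on an open triradiate cartilage and
is not applicable after its closure or after hip surgery. Film quality
screening (rotation/tilt checks) is out of scope, as are additional
indices (Tönnis grade, Reimers migration index, neck-shaft angle) and any
treatment recommendation. The LCEA from an H-point proxy is a flagged
approximation, not Wiberg's angle from an ossific-nucleus center.
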