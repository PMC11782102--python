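# Methods

This note records the measurement model, the choices that were
genuinely open when the package was designed, and what the synthetic
phantoms do and do not establish.

## The measured quantity

For a pancreas mask P and a main-pancreatic-duct mask D (binary voxel
volumes sharing one geometry), the package measures, at each point of a
tail-to-head centerline through P, the cross-sectional area ratio

    DP(s) = A_duct(s) / A_parenchyma(s),

on the plane perpendicular to the centerline at arc length s, and
summarizes a case by the 90th percentile of DP over all valid sections.
Duct dilation raises the numerator; focal parenchymal atrophy lowers
the denominator; both push the upper tail of the DP distribution
upward, which is why one percentile serves as a detector for two
findings.  A high percentile (rather than the maximum) is used so that
a handful of corrupted sections — a locally missing segmentation, a
briefly distorted centerline — cannot dominate the score.

**Denominator convention.** The duct is segmented inside the pancreas,
so "parenchyma" is taken as pancreas minus duct; `DP = r²/(R²−r²)` on
circular sections.  A `whole_pancreas` option (`DP = r²/R²`) is
provided; the two are monotonically related, so threshold-based
detection is unaffected by the choice.

**Sections with no detected duct score 0.** They are real measurements
(the duct may genuinely be invisible there) and biasing the score
downward under duct under-segmentation is the transparent failure mode.
Sections whose retained parenchyma is empty are *invalid* and excluded
from the percentile instead of contributing an infinite or undefined
ratio.

## Centerline estimation

The centerline is a minimum-cost route on the 26-connected foreground
voxel graph.  The step from voxel u to v costs

    |u − v|_mm / (1 + D(v))^p,        p = 2 by default,

where D is the spacing-aware Euclidean distance transform (mm to the
nearest background voxel).  Deep voxels are cheap, so the optimal route
runs along the medial ridge of the organ.  The exponent and the
connectivity are exposed in `RunConfig`; p = 2 makes the medial
attraction strong enough that the path stays within about one voxel of
the true axis of a straight tube (verified in the tests).

**Endpoints** are found by the two-pass geodesic farthest-point
heuristic (from an arbitrary foreground voxel, take the geodesically
farthest voxel A; from A the farthest voxel B).  Each endpoint is then
**snapped onto the medial ridge**: it moves to the voxel with the
strictly largest interior distance within one organ half-thickness (the
global distance-transform maximum) of it.  Without this step the
endpoints sit on the organ surface (the tip of a rounded end, the rim
of an end face) and the route acquires a spurious surface-to-axis
excursion at each end, inflating the measured organ length by up to one
organ thickness.  If no strictly deeper voxel exists nearby (thin
structures), the endpoint is kept, so degenerate masks such as
one-voxel-wide paths keep their exact termini.

**Orientation.** The pancreatic tail lies toward the patient's left, so
the endpoint with the larger patient-left world coordinate is the tail
and the polyline is returned tail→head.  To make "patient left"
deterministic, every mask is reoriented on load into a fixed LAS world
frame (+x patient-left, +y anterior, +z superior); NIfTI (RAS) and
MetaImage (LPS) headers are converted accordingly.

**Determinism.** Foreground voxels are enumerated in lexicographic
order, so node ids, Dijkstra's tie handling, and therefore the whole
centerline are reproducible bit-for-bit; masks with several foreground
components use the largest and log a warning.

## Centerline processing and frames

The raw voxel path zig-zags at the voxel scale (its polyline length
overshoots a smooth curve's by ~5%).  It is processed in three steps,
each with a parameter in `RunConfig`:

- **Smoothing**: moving average over the point itself and up to two
  points on each side (window shrinks *symmetrically* near the ends, so
  endpoints are fixed and collinear equally-spaced input is unchanged).
- **Resampling**: linear interpolation to equidistant points at 0.5 mm
  arc steps — the scale of CT pixel spacing, fine enough to see
  shape changes at the pixel level.  The head endpoint is kept even
  when the length is not a multiple of the step, so the full organ is
  profiled; only the last gap may be short.
- **Tangents**: the chord to the point 10 mm ahead.  Chords to the
  immediate neighbor would inherit the residual voxel-scale vibration
  and tilt the section planes erratically, producing outlier ratios;
  10 mm is long enough to quench that and short enough to follow the
  organ's curvature.  Points whose lookahead overruns the head use the
  chord to the final point (graceful degradation instead of a 10 mm
  dead zone); the final point copies its predecessor's tangent.

Normal and binormal vectors only need to span the plane orthogonal to
the tangent.  They are propagated by the double-reflection
rotation-minimizing-frame scheme, which avoids arbitrary flips between
consecutive sections.  Cross-sectional *areas* are invariant to the
in-plane orientation of the frame, so this choice cannot change the
score: exactly so for 90° (lattice-preserving) rotations, and up to
nearest-neighbor boundary discretization (about h/r relative, ~1% at
0.5 mm pixels on a 10 mm organ, up to ~8% for a 2 mm duct at 1 mm
voxels) for arbitrary angles.

## Cross-sections and component filtering

Each section is a square nearest-neighbor resampling of the mask on the
frame's plane: ±40 mm at 0.5 mm pixels by default (a pancreas
cross-section fits comfortably; samples outside the volume are
background).  A plane through one part of a curved organ can also slice
a distant part of it, and segmentation outputs can contain stray
islands; both would inflate the areas.  In-plane 8-connected pancreas
components that contain no *piercing pixel* — a centerline sample lying
within half an along-axis step (0.25 mm) of the plane, projected into
grid coordinates — are therefore removed.  If no component contains a
piercing pixel, the nearest component within 2 mm is accepted
(discretization tolerance); otherwise the section is invalid.  Duct
components are kept only where their one-pixel dilation touches the
retained pancreas — the dilation matters when duct and parenchyma are
stored as disjoint labels, which leaves a one-pixel seam between them.

## Statistics

Group comparison uses Welch's unequal-variance t-test
(Welch–Satterthwaite degrees of freedom, two-sided p; two zero-variance
groups with equal means compare as p = 1).  ROC curves sweep all
distinct score thresholds with *score ≥ threshold* called positive
(inclusive, so a threshold equal to a case's score calls it positive);
AUROC equals pairwise concordance with half-credit ties, which the
tests verify exactly against an O(n²) oracle.  Operating points are
reported at sensitivity ≥ 90% maximizing specificity and vice versa;
among ties the larger (more conservative) threshold wins, and an
unattainable floor returns the best attainable point flagged.  The
three-group comparison (both findings / dilation only / neither) uses
three pairwise Welch tests at the Bonferroni level α/3 ≈ 0.0167.

## Synthetic phantoms

A phantom is a curved tube: a generating curve (straight, planar arc,
or planar sinusoid; laid out with s = 0 at the patient-left end), a
parenchyma radius profile R(s), a duct radius profile r(s), and an
optional in-plane duct offset.  Voxelization marks a voxel foreground
when its center is within the radius (boundary-inclusive: `dist ≤ R`) of
the nearest curve point; the inclusive rule keeps the voxel-counted
area of small ducts within a few percent of πr², where a strict
inequality under-counts by ~10% at r = 2 mm and 0.5 mm voxels.  The
grid origin carries a fixed sub-voxel dither (0.277, 0.331, 0.413 of a
voxel) so the tube axis is never exactly lattice-aligned — a voxel-
centered circle is the worst case for boundary quantization and no real
acquisition is aligned that way.

Circular sections give the exact profile `DP(s) = r(s)²/(R(s)²−r(s)²)`
and its percentile, which is the oracle for the end-to-end tests: at
0.5 mm voxels the full pipeline reproduces the closed-form score of the
concentric tube within ~3% and of a ramped duct within ~1%.

Optional noise emulates two segmentation failure modes: smooth surface
jitter (a Gaussian-filtered random field added to the radius threshold)
and speckle — spherical islands placed at least 5 mm clear of the tube
so ground truth for the component filter is unambiguous.  Per-case RNG
streams derive from (cohort seed, case index), making cohorts
reproducible and order-independent.

**Cohort generator defaults** (chosen once as realistic desk-scale
conditions): straight base tube 80 mm long, R = 10 mm, r = 2 mm, 1 mm
isotropic voxels; dilation positives scale r by 3 and atrophy positives
scale R by 0.6 over a random contiguous span of 25–50% of the arc
length (spans shorter than ~10% would escape a 90th percentile by
construction; a clamp keeps a dilated duct inside an atrophied wall
when both lesions share a span).  Problem sizes in the tests and the
acceptance script (60–120 mm tubes at 0.5–1.5 mm voxels, cohorts of
8–20 cases) were chosen so the whole validation runs in minutes on one
CPU while keeping ≥ 190 interior sections on the fine phantoms.

**What the phantoms do not show.** They have circular sections, smooth
curvature, and no contact with neighboring organs; real pancreata are
lobulated, the duct is not a perfect tube, and CNN masks err in
structured ways (under-segmented duct tails, leakage into the duodenum)
that jitter and speckle only caricature.  Passing the phantom suite
demonstrates that the *measurement* chain is correct and robust to the
modeled defect classes — not that the score attains any particular
clinical sensitivity or specificity, which depends on the upstream
segmentation quality.

## Numerical conventions and degenerate inputs

- Voxel indices are 0-based; world coordinates are voxel-center based;
  geometry round-trips are exact to < 1e-6.
- Percentiles use closest-ranks linear interpolation
  (`numpy.percentile` default).
- Dijkstra ties are resolved by lexicographic voxel order; the
  whole pipeline is deterministic given the masks.
- Empty masks, disconnected termini, single-class label vectors,
  too-small statistical groups and zero-parenchyma sections raise
  informative errors rather than returning sentinel values; per-case
  failures inside a cohort run are logged and excluded with a count.

## Known limitations

- A single non-branching centerline is assumed (adequate for the
  pancreas; not for branching vasculature).
- Nearest-neighbor section sampling quantizes areas at the pixel scale;
  ratios for ducts a few voxels wide carry ~5–10% discretization noise
  at 1 mm voxels.
- The tail/head rule relies on the anatomical convention that the tail
  is the patient-left end; masks of other organs would need a different
  orientation rule.
- DICOM series ingestion, image resampling/registration and any
  segmentation are out of scope: the package consumes binary masks.
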