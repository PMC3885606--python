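# Methods

This note documents the models and procedures behind each engine, the
parameters that matter, what the synthetic benchmarks do and do not
emulate, and the numerical choices made where the design was open.

## Imaging model and calibration

All engines assume 8-bit grayscale plate images with dark objects
(worms, eggs, debris) on a bright agar background; a configuration
flag inverts the polarity. The spatial calibration `scale` (µm per
pixel) converts pixel measurements to micrometers. Two calibrations
appear throughout: ~20 µm/px for whole-well scans (lifespan,
locomotion, eggs in a multi-well rig) and ~6.25 µm/px for body-size
scans, which tile a well far more densely; at 20 µm/px an adult worm
is only ~3 px wide, too coarse for 1%-level length measurement.

**Adaptive thresholding.** A pixel is foreground iff its intensity is
below `local_mean × (1 − offset_fraction)`, with the local mean over a
square window (border-clamped, computed by a uniform filter — the
separable equivalent of the integral-image formulation). Defaults:
window = min image dimension / 8 rounded up to odd, offset 0.15. The
rule is scale-free in intensity, so smooth illumination gradients and
plate shadows do not produce spurious foreground (a 60→220 ramp yields
< 1% foreground at these defaults). Raising the offset can only
remove foreground pixels, never add them.

## Lifespan: two-scan moving-worm counting

Living worms reveal themselves by changed pixels between two scans of
a well taken `interval` apart (default 120 s). The count proceeds:

1. binarize |scan₁ − scan₂|. Difference images are bright-on-black, so
   the rule is a changed pixel iff diff > max(noise floor, 2 × local
   mean diff); the absolute floor (default 30, ≈3.5 σ of the
   difference of two σ≈6 sensor-noise fields) suppresses speckle and a
   3×3 opening removes what remains. Absolute difference makes the
   result independent of scan order.
2. candidate worms = regions of the binarized second scan with area in
   [`min_worm_area`, `max_worm_area`] (default 40–2000 px, bracketing
   L4–adult at 20 µm/px);
3. a candidate moves iff the changed pixels inside it reach
   `min_changed_fraction` of its area (default 25%; a fraction scales
   across worm sizes, and an absolute `min_changed_pixels` override
   exists);
4. worms pressed against large dark objects never appear as
   candidates (the merged region fails the size filter), so worm-sized
   difference components disjoint from every candidate are added as
   extra movers. A well-displaced mover leaves two disjoint
   difference components — its vacated site and its occupied site —
   and only components substantially dark in the *second* scan count,
   so each hidden mover is tallied exactly once and visible movers are
   never double-counted.

**Survival post-processing.** Daily counts can increase spuriously
(detection is imperfect), which is impossible under a fixed, FUdR-
arrested population; the step-wise decrease filter replaces each count
with the maximum of all counts from that day onward (right-to-left
running maximum — idempotent, non-increasing by construction). Deaths
on day *t* are count(*t*−1) − count(*t*): a worm is scored dead on the
first day its movement is no longer seen, with day 0 the first day of
adulthood. Mean lifespan is the death-weighted mean death day; a
series with no observed deaths is flagged censored rather than given a
mean. Because the method is movement-based it measures *healthy*
lifespan: paralyzed-but-living worms, and worms that wander into the
dark well rim, are scored dead.

## Locomotion: tracking and velocity

Each frame is thresholded and labeled; regions are kept by area and by
an eccentricity floor (default 0.7) that rejects round debris.
Association is greedy nearest-centroid with ties broken by smaller
area difference, gated by `max_step` (default 10 px/frame) and by
relative area change (gate 1.6× the track's running median area). A
track ends with reason `collision` when two tracks claim one region or
when an oversized (merged) region appears within `max_step` of the
track's last position — the merged blob's centroid can jump half a
body length, so proximity is tested against its bounding box;
`boundary` when its region touches the frame edge; `lost` when no
region matches; `video_end` otherwise. Identity is never re-linked
through a collision. Tracks shorter than `min_track_frames` (default
14 frames = 2 s at 7 fps) are discarded.

**Smoothing.** Video flicker adds positional noise to centroids
(~0.25–0.3 px sd on clean synthetic frames). Trails are smoothed by
piecewise cubic least-squares fits over sliding windows of 7 samples
overlapping by 3, averaging overlapped evaluations — a cubic Bezier
segment under uniform parameterization *is* a cubic polynomial curve,
so these are least-squares Bezier fits. Collinear input is reproduced
exactly and smoothing cannot lengthen a straight-truth trail.

**Velocity.** Mean velocity = smoothed path length × scale / elapsed
time. The path length is integrated with a 14-frame resampling stride
(2 s at 7 fps): summing sub-pixel per-frame steps of a jittered path
inflates length by ≈ σ²/(2d) per step, a ~4% bias for a 0.25 px/frame
worm, while a 2-s stride renders the bias negligible without
truncating plate-scale paths. The stride slightly shortens strongly
curved paths; for crawling worms over 2 s the effect is well below the
other error terms. Trails whose whole bounding box is smaller than
`stationary_box` (default 5 px) are non-moving objects (dead worms,
debris) and are excluded from population statistics but reported.
Histogram and cumulative-distribution tables are emitted as TSV.

## Length: skeleton-based morphometry

Candidates are regions passing area and bounding-box filters; interior
holes are filled (a worm silhouette is solid) and the region is
thinned to its medial skeleton. Only a branch-free skeleton with two
endpoints is a valid worm — an egg or debris particle touching the
body induces a branch, and such objects are rejected with reason
`branched` rather than mismeasured. Degenerate skeletons (< 8 px) are
compact blobs, rejected `too_fat`.

Two length estimators are provided. `chain_code` is the classical
trace: 1 per horizontal/vertical step, √2 per diagonal (closed forms:
a 101-px horizontal run is 100.0, a perfect diagonal 100√2). Its
orientation-dependent quantization bias — up to +8% for staircase
paths near 22.5° — is fine against a manual polyline oracle that
shares the bias, but not against analytic truth, so the default
`spline` estimator fits a smoothing parametric spline through the
ordered skeleton pixels and integrates its arc length. Thinning also
erodes the tips by roughly half the body width per end; the tip
correction extends each end along the terminal tangent until the ray
exits the silhouette and adds that distance minus the local half-width
(from the distance transform), which is exact for a round-capped band.
Without it lengths bias low by ~one body width. Finally, fatness =
area / skeleton length (the mean width, px) must lie in
`fatness_range` (default 2–8 px): disks are maximally fat, fragments
too thin. All candidates are returned with their rejection reason so
manual inspection can audit every decision.

## Eggs: multi-threshold counting

Eggs vary in darkness, sit on scarred agar, and touch one another; no
single threshold segments them all. The five-step pipeline:

1. **Singles.** Canny edges (thresholds in intensity units, σ = 1.5) →
   gap bridging + hole filling (dilate by ⌈gap/2⌉, flood-fill, erode;
   plain closing cannot bridge a gap in a one-pixel curve) → keep
   blobs in a broad area band with elliptical eccentricity and high
   solidity. A plate with compact dark blobs but no valid single egg
   aborts with an explicit priors-unavailable error; a plate with no
   dark blobs at all (or only thin track marks) counts zero.
2. **Priors.** Reference area = median single area minus half its
   perimeter (the filled edge contour includes the smeared boundary
   ring); reference gray = median over the eroded cores; bands derive
   from these (area 0.5–1.5×, eccentricity from the observed singles
   padded by −0.15/+0.10).
3. **Multi-thresholding.** Binarize at every level (default 30…230
   step 10 → 21 binary images; at least 10 required), open 3×3,
   label. Obscured eggs separate from their background in whichever
   subset of levels brackets their gray value.
4. **Morphology filtering.** Per level, keep blobs whose mean gray is
   within ±45 of the reference and whose shape fits: single-band blobs
   count once (a 1.2–1.5× blob that is unusually elongated or waisted
   is split as a pair — two small touching eggs masquerade at that
   size); aggregates up to 5× the reference area are split into
   k = round(area/ref + 0.08) sub-detections via deterministic k-means
   on the blob pixels (the small bias compensates the contact-waist
   area lost where eggs touch). Solidity gates are permissive (0.70
   single, 0.60 clump) because genuinely touching eggs have waists;
   debris is excluded by gray level and eccentricity instead.
5. **Clustering.** Detections within `merge_radius` (default 0.55× the
   reference equivalent diameter — above replicate scatter, below the
   center spacing of touching eggs) of a cluster's running-mean
   centroid merge, with the constraint that a cluster holds at most
   one detection per level: two detections in one binary image are by
   construction distinct objects, which prevents adjacent eggs'
   replicates from chaining into one cluster. Clusters seen at fewer
   than `min_occurrences` (default 3) distinct levels are dropped.
   The surviving clusters are the egg count.

## The simulator

Virtual worms are sine curves (default body 40 px, amplitude 5 px,
thickness 3 px, wavelength = body length) whose phase advances each
frame (default 0.45 rad/frame ≈ 0.5 Hz at 7 fps) while the body
translates along its heading at constant speed. Positions stay in
floating point and are rounded only at rasterization, so a
0.25 px/frame worm accumulates true sub-pixel displacement. The body
polyline is re-centered on its arc-length-weighted centroid every
frame, making the configured trajectory exactly the centroid
trajectory the tracker estimates. Validation videos are rendered
black-and-white (the style of a pure simulation video); a noisy
grayscale mode (background 220, worm 30, Gaussian σ 6) exists for the
still-plate generators. Auto-placement rejects configurations where
two worms would come within a body length of each other *at the same
instant* (paths may cross at different times), keeping per-worm ground
truth unambiguous; forced collisions for tracker tests are constructed
by specifying worms directly.

Length plates sweep a disk along smooth random arcs cut (by dense
cumulative chord length, < 10⁻⁴ relative error) to an exactly known
arc length, 600–1500 µm at 6.25 µm/px. Egg plates draw ellipses with
~2:1.3 axis ratio (semi-axes ≈ 5 × 3.2 px at 5 µm/px), per-egg gray in
70–140, a configurable fraction placed in touching contact (center
distance = sum of directional ellipse radii), plus irregular dark
blobs and thin curvilinear track marks as debris. Time-lapse pairs
displace movers 60 px between scans (1.2 mm over the 2-minute
interval, i.e. 10 µm/s — a conservative lower bound for a living
worm) and change their body phase; still worms differ only by sensor
noise. Identical seed and configuration reproduce every asset
bit-for-bit.

**What the benchmarks do not emulate.** Real plates add an OP50 lawn
edge, vignetting and condensation, worm postures beyond sinusoids
(omega turns, reversals, coiling), overlapping worms, eggs at varying
focus, and out-of-frame exits during scans. Passing the synthetic
envelopes therefore demonstrates the algorithms' correctness under the
stated image model, not field performance on every real plate; the
manual-inspection pathway (overlays + editable corrections files)
exists for the residual errors real data will produce. Debris in the
egg benchmark can overdraw an egg entirely; such eggs are unrecoverable
by any image method and are the dominant remaining error there.

## Numerical and degenerate-input choices

Coordinates are (row, col), 0-based; bounding boxes half-open.
Labeling connectivity defaults to 8. Empty masks label to an empty
list; empty skeletons and branched skeletons raise. The stepwise
filter of an empty series is empty. A survival series that never
reaches zero yields a censored mean-from-observed-deaths. Velocity of
a zero-duration track raises. Egg clustering with a non-positive merge
radius raises. Batch processing never aborts on one bad file: failures
are logged, reported, and reflected in a nonzero exit status.
Reports are UTF-8 TSV with a config-hash comment header; re-running on
identical inputs, configuration, and seed reproduces files byte-for-
byte. Manual corrections are applied atomically — one unknown record
id rejects the whole corrections file.

## Benchmark problem sizes

The validation suite uses 11 videos of 10 worms (210 frames, 640×480)
for velocity, one 20-worm two-cohort video for track recovery, 46
worms across four plates for length, 42 plates (10–80 eggs, 5–15
debris) for egg counting, and 26 wells spanning 0–100 movers for
moving-worm counting — matching the sample sizes of the original
validations these envelopes come from.
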