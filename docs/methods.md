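# Methods

`octoplume` reconstructs, as a tested pipeline, the video analysis used to
demonstrate chemosensory plume tracking in a benthic octopus: per-frame
kinematics from eye-coordinate pose tracks, image-based arm-direction
detection, region-crossing geometry against a plume polygon, segmentation of
fast arm-aligned motions (FAAM), and hypothesis tests against
perimeter-density null models. A synthetic-data generator reproduces the
statistical structure of the original recordings so every stage can be
validated against known ground truth.

## Coordinate conventions

Arena coordinates are centimeters in a 185 x 116 cm flume with the origin at
the downstream corner: x increases upstream, y across-stream, and the mean
flow direction is (-1, 0) — "against flow" motion has positive x-velocity.
Angles are degrees, counter-clockwise positive. Signed angle differences are
reported in (-180, 180]. Rendered images are indexed `[row, col]` with
`col = x * px_per_cm`, `row = y * px_per_cm`; the default render is 960 px
across the flume length (half the 1920 x 1200 camera), i.e. ~5.19 px/cm.

## Kinematics

The raw input is a markerless pose track: pixel coordinates of the left eye,
right eye, and mantle tip with a confidence per frame, sampled at 10 Hz.
Processing:

1. **Outlier rejection.** A coordinate is dropped when both the displacement
   into and out of its frame exceed `median + mad_k * MAD` of that body
   part's frame-to-frame displacements (default `mad_k = 5`). Requiring both
   sides isolates tracker "teleports" — a single spike is removed without
   flagging the two legitimate frames around it. The displacement-MAD rule
   was chosen for being robust and parameter-light; the exact statistic used
   originally is not fixed by the study description, so only this default is
   guaranteed here.
2. **Interpolation.** Interior gaps are filled linearly per coordinate; no
   extrapolation — leading/trailing incomplete frames are trimmed and
   counted in the cleaning report.
3. **Smoothing.** A 5th-order Savitzky-Golay filter with a 29-frame window
   is applied to the eye and mantle coordinates (not to derived angles). The
   filter reproduces polynomials up to degree 5 exactly, so smooth motion
   passes through unchanged while frame-rate jitter is attenuated.
4. **Derived quantities.** Body center = eye midpoint. Body axis = unit
   normal of the inter-eye line, signed to face away from the mantle tip
   (`axis . (center - mantle) > 0`); undefined when the eyes coincide.
   Heading at frame *t* = direction of the center displacement from *t-1*
   to *t*; undefined below 0.05 px/frame so that pauses do not produce
   noise-dominated directions. Heading offset = signed angle from body axis
   to heading (0 = moving face-first, negative = heading clockwise of
   facing). Speed converts px/frame to cm/s.
5. **Speed z-score.** Animals of different sizes have different speed
   scales, so speeds are standardized per individual (population SD) over
   the individual's full recording. Whether the original analysis
   standardized per night or per week is not stated; full-recording was
   chosen for stability.

### Kinematics table columns

`frame`, `time_s`, `center_x_px`, `center_y_px`, `center_x_cm`,
`center_y_cm`, `body_axis_deg`, `heading_deg`, `heading_offset_deg`,
`speed_cm_s`, plus `speed_z` and (after arm detection) `n_arms`,
`nearest_arm_offset_deg`. Undefined values are NaN.

## Arm detection

Arm tips are too small and fast for markerless pose models to track
reliably, so arm directions are recovered geometrically from the images:

1. **Dynamic background.** Each frame's background is the mean of the ten
   temporally nearest frames in which the animal is more than 600 px away
   (at full camera resolution; scale the threshold with the render).
   Subtraction is clamped at zero. This tracks slow background change
   (sediment deposition) without averaging the animal into its own
   background.
2. **Standardization.** Each frame is cropped to a 600 x 600 px window
   centered on the body center and rotated (bilinear) so the body axis
   points straight down the image.
3. **Average body image.** The pixel-wise mean of all standardized frames,
   scaled to unit maximum. Because arms move from frame to frame they smear
   out in the average; the body does not.
4. **Bounding geometry.** The average image is masked by Otsu's threshold
   (the original threshold method is unstated) and a rectangle symmetric
   about the vertical body axis is grown greedily — expanding whichever
   free extent captures the most masked intensity per pixel — until it
   encloses 95% of the total. The bounding circle is centered on the body
   center with radius equal to the distance to the most distant rectangle
   vertices: large enough to clear the mantle in every direction, small
   enough that the arms cross it.
5. **Ring profile.** Five concentric one-pixel circles at radii r, r-1, ...,
   r-4 (inward, so the ring never leaves the crop; the original does not
   state the side) are sampled bilinearly, unwrapped, binned into 100
   angular bins of 3.6 degrees, and averaged bin-wise. Bin 0 starts at the
   body-axis direction; bin centers sit at 1.8 + 3.6k degrees.
6. **Circular peak detection.** `scipy.signal.find_peaks` with prominence
   0.1 x (max - min) and minimum separation 2 bins, run on the original
   profile and on a copy rolled by 5 bins (18 degrees — wider than an arm at
   the ring radius), unioning the results and de-duplicating within one
   bin. The second pass rescues peaks split across the circular array
   boundary. The prominence and separation values are not fixed by the
   original description; both are exposed as parameters.
7. **Heading-arm offsets.** Each detected arm's signed offset from the
   heading; the nearest arm minimizes |offset|, exact ties broken toward
   the positive (counter-clockwise) side.

## Regions and crossings

The plume polygon comes either from a manual vertex file (authoritative, as
in the original analysis) or automatically from a plume-visualization video:
per-pixel temporal variance, percentile threshold (default 99), convex hull
of the largest connected component. The target circle has radius 14 cm (the
animal's reach) around the station. The three-station apparatus is a
rectangle of three equal squares laid across the stream; its external
perimeter is partitioned into labeled segments, a segment owning its
counter-clockwise corner so partition corners classify unambiguously.

First-crossing events interpolate the boundary crossing point on the
straddling track segment (exactly for the circle). One event is recorded
per approach; a new approach requires the track to stay outside the region
for 30 s (configurable — the original criterion separating approaches is
unstated). Under the perimeter-density null, expected label ratios are
geometric length fractions: 3/8 for a long edge of the 3x1 rectangle, 1/3
for the baited square conditional on that edge, and the inside-plume arc
fraction of the target circle for single-station approaches.

## Conditions and FAAM

Plume visits are labeled *chemosensory tracking* (bait present, visit ends
in feeding), *food not eaten* (bait present, never eaten during that
placement), or *no food* (no bait in the flume). A visit during a placement
whose bait was eventually eaten on a later approach is excluded — it is
neither a completed track nor evidence of refusal.

FAAM bouts are maximal contiguous runs of frames satisfying
`1.5 <= speed_z <= 4.0`, `|nearest_arm_offset| <= 5 deg`, lasting at least
0.5 s (5 frames at 10 Hz). There is no gap tolerance: one disqualifying
frame splits a bout, matching the filtering semantics of the criteria.
Frames with undefined heading or no detected arm never qualify. The 4.0
upper bound is enforced exactly as specified. Per-condition statistics are
event counts, percent time (FAAM frames / condition frames x 100), and the
normalized mean of per-frame unit heading vectors per event.

One-second windows of (speed_z, nearest_arm_offset) are z-normalized
feature-wise across all windows and embedded to 2-D with UMAP
(`random_state` fixed; `n_neighbors = 15`, `min_dist = 0.1`). The embedding
is a visualization aid: the package guarantees determinism under a fixed
seed and coarse separation of kinematic regimes, never exact coordinates.

## Statistics

`binomial_one_sided` computes the exact binomial tail by logsumexp over
log-pmf terms (gammaln binomials), preserving relative precision in tails
of order 1e-16; the printed headline comparison (31 of 41 approaches from
inside the plume against a geometric ratio of 0.17) gives 2.59e-16.
Sidedness is one-sided "greater", which reproduces that printed value.
`chisq_uniform` is the Pearson statistic on counts vs length-share expected
counts with `df = segments - 1`. No multiple-testing correction is applied
(none was applied originally). Star labels follow the cut-offs
`. < 0.1, * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001`, else `n.s.`.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study stand-in; its defaults are the study
conditions wherever those are stated (10 Hz, 185 x 116 cm, flow 2 cm/s
toward -x, 14 cm target circle), and realistic choices where they are not:

* **Rendering.** The animal is a flat near-saturated disc (logistic edge at
  ~4.2 cm radius) with two sharp eye maxima 3 cm apart and eight tapering
  arm strokes from 4 to 18 cm, on a textured background with sensor noise.
  This reproduces the features the arm detector relies on — a compact
  bright body the bounding ring must clear, and thin arms crossing the
  ring — not octopus appearance. Deformable arms, suckers, and partial
  occlusion are not modeled, so arm-recovery results bound performance on
  clean silhouettes only.
* **Pose error.** Isotropic Gaussian jitter (default 1 px at half
  resolution) plus Bernoulli "teleport" outliers with depressed confidence,
  mimicking identity-swap failures. Real pose error is neither isotropic
  nor white; no noise spectrum was reported, so these defaults are chosen,
  not fitted.
* **Motion models.** `stationary`; `random_walk` (OU velocity, wall
  reflection); `surge_cast` (upstream surges alternating cross-stream
  casts — odor-gated rheotaxis); `faam_lunge` (slow meander with ballistic
  lunges: speed 12 cm/s for 1 s, one arm held within +/-1.5 deg of the
  velocity direction, lunge direction chosen at launch so the path clears
  the walls). Lunges occupy ~10% of frames: for a two-level speed process
  the lunge z-score is sqrt((1-f)/f), so the lunge fraction f must lie in
  (0.06, 0.31) for the 1.5-4.0 band to be satisfiable at all; f ~ 0.1 puts
  lunges near z = 3.
* **Plume video.** Filament particles injected at the source, advected by
  mean flow plus a shared slowly-meandering cross-stream velocity and
  per-particle diffusion, rendered as Gaussian splats. This produces the
  two features the analysis uses — downstream widening of the time-averaged
  plume and intermittent pixel time series — and is deliberately not a
  turbulence simulation.

Validated recovery properties (all in the test suite): FAAM event-count
recovery is exact through the full cleaning/kinematics/z-score chain for
eye jitter up to 2 px; event boundaries match ground truth within +/-2
frames at 1 px jitter, degrading to ~+/-5 frames at 2 px because coordinate
smoothing spreads the speed ramp at the z-threshold crossing. Rendered arm
angles are recovered within one 3.6-degree bin across body orientations.

## Numerical choices

* Heading epsilon 0.05 px/frame; frames below it are excluded from offset
  statistics.
* Nearest-arm ties (exactly +/- the same offset) break positive.
* Degenerate inputs raise: zero speed SD, all-outlier tracks, all-zero
  image stacks, radius < 5 px rings, single-frame variance projections.
* A flat ring profile yields zero peaks, not an error.
* The demo pipeline runs at half camera resolution with a 300 px crop and a
  scaled background-exclusion distance; the tiny demo (< 500 frames) skips
  dynamic background subtraction because its track never leaves any
  frame's exclusion radius.

## Problem sizes

The test suite and acceptance script run on desk-scale problems chosen to
exercise every code path: 60 s tracks (600 frames) for FAAM recovery, ~300
frame demo videos at 960 x 602, 150-frame plume videos at 2 px/cm, 10^4
Monte-Carlo replicates for test calibration. The `desk` demo scale produces
a few minutes of video and runs the full pipeline in minutes on one CPU.

## Known limitations

* The arm detector reports directions, not identities; arms are not
  tracked across frames (the original attempt to do so was abandoned as
  unreliable).
* The plume polygon from variance projection is a convex hull; real plume
  boundaries are not convex, and the manual-polygon route remains the
  authoritative one.
* Condition labeling assumes non-overlapping bait placements and trusts
  the feeding annotations.
* The per-individual z-score window and the approach-reset time are
  configurable conventions, not measured properties.
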