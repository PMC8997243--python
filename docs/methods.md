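# Methods

This note documents the models and procedures implemented in `contourpose`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## Background estimation

A quasi-static scene is separated from the moving animal by a per-pixel
temporal projection: `max` removes a dark animal on a bright background,
`min` a bright animal on a dark one, `mean` trades residual animal traces
for robustness to slow lighting drift.  The projection is exact only when
the animal vacates every pixel it visits at some point of the clip; for a
clip shorter than (body length / speed), or for an animal that comes to
rest, a recorded animal-free reference image must be supplied instead
(`track_video(..., background=...)`).  Intensities are normalised to
[0, 1] at load time regardless of source bit depth, so all thresholds are
bit-depth independent.  Frames of an image sequence are ordered by natural
sort of their filenames; colour input is collapsed by Rec. 601 luminance.

## Segmentation

Six steps per frame: absolute difference against the background (absolute,
so dark-on-bright and bright-on-dark animals share one code path),
normalisation to the maximum, strict-greater binarisation at a fixed
threshold (default 0.25; ties go to background, deterministically),
optional ROI masking, disk erosion (default radius 1 px) to cut contact
bridges between touching animals, and outer-boundary tracing of the
8-connected components (holes ignored, components below
π·(min_major/4)² px² discarded as noise specks).  Boundary tracing on the
binary mask replaces a gradient edge detector; on binary input the traced
outer boundary is the edge set the downstream stages need.  Coordinates
are (x = column, y = row), 0-based.

## Ellipse detection

The classical five-parameter Hough accumulator is intractable, so the
detector uses the pair-sampling reduction: each pair of edge points whose
separation lies within the user's major-axis range [min_major, max_major]
is hypothesised to be the major-axis endpoints; every other edge point
then implies a semi-minor length b, voted into a 1-D accumulator with 1 px
bins.  The peak bin (after 3-bin box smoothing; ties resolve toward
smaller b) completes the candidate.  Design constants: pairs are
enumerated exhaustively for up to 400 edge points (anchor points are
subsampled with the caller's seed above that; all points still vote), at
most 6000 voting pairs per sub-image, votes require the third point to lie
strictly inside the major-axis circle, and b ≥ 0.5 px.

Vote counts rank the hypotheses; the reported quality q is the **boundary
coverage**: the candidate ellipse's perimeter is sampled at ~1 px arc
spacing and q is the fraction of samples with an edge pixel within 1.5 px.
Coverage is robust to the vote scatter that raster discretisation causes
near the major-axis endpoints, and it prevents degenerate thin-sliver
hypotheses grazing a dense arc from outranking the true partially-occluded
ellipse.  A complete ellipse scores q ≈ 1; deleting a fraction of its arc
lowers q by about that fraction.  Because the pair *is* the major-axis
hypothesis, detection degrades when a major-axis endpoint itself is
occluded — neighbouring chords then yield slightly biased candidates, and
the correction stages (not the raw detector) are responsible for those
frames.

Near-duplicate candidates are removed by greedy non-maximum suppression at
60 % intersection-over-smaller-area; suppressed candidates are demoted to
the sub-threshold pool rather than discarded, since the correction stages
draw replacements from exactly that pool.  Frames with several animals are
split into per-boundary sub-images first, so each Hough run sees one edge
set.  The default acceptance threshold on q is 0.3.

## Corrections and identity

The user states the animal count n; each frame is classified into problem
codes 0–7 (surplus overlapping / surplus disjoint / both; deficit without
or with an oversized "chain" detection; chain splits that still leave a
deficit; correct count with chaining) and repaired iteratively,
re-classifying after each rule.  Numerical choices: "overlaying" means
intersection-over-smaller-area ≥ 0.5 on the ellipse polygons; "oversized"
means the full major axis is at least 1.5× the expected single-animal
major axis, which is taken as (min_major + max_major)/2 everywhere a
single-animal size is needed; a chain of ratio r splits into
k = round(r) ≥ 2 children spaced evenly along the parent's major axis,
each with the expected mean major axis and the parent's minor axis.  Every
detection a rule introduces or modifies has its stored quality set to −1;
a separate rank quality (the pre-correction Hough q, inherited by split
children from their parent) drives all ordering decisions — otherwise the
freshly split children, being corrected, would always be deleted first and
the split would be pointless.  Deficit fill-ups skip candidates that
overlap an already-accepted detection, so a duplicate of a found animal is
never accepted in place of the missing one.

Frames still short of n animals after the within-frame rules are rescued
using the neighbouring frames: each sub-threshold candidate c is scored
S(c) = Σ wᵢ·sᵢ(c) / Σ wᵢ with bounded, dimensionless estimator scores
s_pos = 1/(1 + d/d₀) (d = distance to the reference, d₀ = expected major
axis), s_surf and s_cont the min/max ratios of ellipse area and perimeter
against the reference.  The reference is the unmatched neighbour detection
(averaged between previous and next frame when both exist).  A zero weight
omits an estimator; ties break on raw Hough quality, then candidate index.
Identities propagate frame-to-frame by Hungarian assignment on centre
distances; surplus detections found new identities.

## Midline (pseudo-skeleton)

100 evenly spaced points (by arc length, starting at the contour's first
point) seed a Voronoi tessellation.  Finite Voronoi edges with both
endpoints strictly inside the contour approximate the medial axis;
vertices closer to their nearest seed than 1.5× the seed spacing are
pruned, removing the spurious near-boundary branches that finite boundary
sampling creates.  The body ends are the geodesically extremal vertex pair
of the resulting skeleton graph, found with the deterministic two-sweep
rule seeded at the boundary-closest vertex — the extremal vertices are
where the medial axis runs out to the boundary, i.e. the body tips.  The
midline is the Dijkstra shortest path between them, and its summed edge
length is the raw body-length measure.  `skeletonize_contour` additionally
extends each end along its tangent to the contour (on by default), because
the medial axis terminates about half a body-width short of each rounded
tip; with the extension the skeleton length tracks the true snout-to-tail
length of synthetic crawlers at r ≈ 0.995 with ≈ 1.7 % relative RMS error.
Head/tail polarity is arbitrary per frame and made temporally consistent
by matching endpoints against the previous frame.  Accepted detections
that solely own their boundary are also re-centred on the contour's
moment-equivalent ellipse (Green's-theorem area moments), because raw
accumulator peaks live on a half-pixel grid and jitter frame-to-frame;
the refinement cuts centre jitter by an order of magnitude, which matters
at high frame rates where velocities multiply the jitter by fps.

## Kinematics

* **Contraction amplitude** A = (1 − L_min/L_max)·100 %, over an interval
  of forward crawling.  Being an extremum statistic it is noise-sensitive;
  analyses apply a 5-frame (≈ 0.15 s at 34 fps) moving average
  (`smooth_series`) to the length series first, which attenuates a 1 Hz
  peristaltic oscillation by under 4 % while suppressing single-frame
  outliers.
* **Curvature index** c = (∫|y| − ∫y)·(−sign(y_mid)) on the skeleton
  resampled to 101 equidistant points and rotated so the end-to-end axis
  is straight; integrals are trapezoidal over point index, and y_mid = 0
  yields c = 0.  As printed, the formula is one-sided: a bend lying
  entirely at positive y gives c = 0 while its mirror image gives 2∫|y|.
  The package therefore also exposes `curvature_components` — turn
  magnitude |∫y| and s-shape measure ∫|y| − |∫y| — as a clearly separate,
  symmetric decomposition (not part of the original index); turn-interval
  detection uses the symmetric magnitude.
* **Ego-centric velocities.**  Central differences (one-sided at the
  ends), no smoothing by default.  The axial ellipse orientation
  (mod 180°) is resolved to a directed heading by temporal continuity
  (nearest candidate to the previous heading, so the heading cannot flap
  during glides), with the overall polarity set by the sign of the mean
  velocity–heading dot product over frames faster than half the median
  speed.  Thrust² + slip² equals speed² identically.
* **Events.**  Saccades: |yaw velocity| peaks above 200 °/s; thrust
  strokes: forward-speed peaks above 10 cm/s; peaks closer than the
  minimum separation (default 0.1 s) keep the larger one.
  Event-triggered averages use complete windows only (default ±0.5 s) with
  either a pointwise standard-deviation band or a 95 % bootstrap CI of the
  median.
* **Permutation test.**  T = |median(A) − median(B)|; exhaustive
  enumeration of all C(n, n_A) relabelings when that count is ≤ 20,000
  (exact p = proportion of splits with T ≥ T_obs), else seeded sampling
  with the add-one estimator (count+1)/(N+1).  Under a continuous null the
  empirical type-I rate at α = 0.05 is 4.8 % over 1,000 simulations.

## Calibration

A marked line (2 points), rectangle (4 corners), or circle (centre+rim or
≥3 rim points, least-squares) of known physical size fixes a single
isotropic scale in m/px.  The rectangle's two independent side estimates
are averaged and their relative disagreement reported (warning above
10 %); anisotropic scaling is deliberately not modelled.  Rectangle and
circle marks move the world origin (designated corner / centre); a line
keeps the pixel origin.  World +y follows the image-down pixel convention
unless `flip_y` is set.

## Synthetic scenes: what they emulate, and what they do not

The generators produce the study conditions used throughout the tests: a
crawling larva (tapered capsule, tip-to-tail length 60 px oscillating with
programmable amplitude A*, 34 fps, raised-cosine turn windows that bend
the body into a C), an intermittently swimming fish (tapered silhouette,
200 fps, exponential burst–glide speed with time constant 0.35 s, Gaussian
yaw pulses of 40 ms width, travelling-wave undulation whose amplitude
scales with locomotor activity), and multi-animal scenes with scheduled
end-to-end chaining and path-crossing occlusion.  Two background regimes
instantiate the two recording situations the tool targets: `uniform`
(contact-imaging-like: flat field, contrast 0.7, Gaussian pixel noise
σ = 0.005) and `gradient` (backlit-tank-like: 20 % linear illumination
ramp, contrast 0.3, σ = 0.02).  Bodies are rendered as anti-aliased
distance fields around the programmed midline; identical seeds give
bit-identical frames and truth.

The scenes deliberately omit: shadows and reflections, non-rigid texture,
lens distortion, frame-rate jitter, animals leaving the arena, and
photorealistic optics.  Passing the recovery tests therefore demonstrates
the correctness of the algorithms under controlled contrast/noise/geometry
conditions — not performance on any particular laboratory's footage, where
threshold and size priors must be chosen per setup.

## Evaluation corpus

The detection-rate evaluation (`scripts/acceptance.py`,
`tests/test_acceptance.py`) uses 10 single-crawler videos of 200 frames
(224×224 px, A* = 15 %, speed 20 px/s — enough travel for the temporal max
projection to recover the background exactly), rendered once per regime
from identical trajectory seeds.  Detection runs with size prior
[40, 80] px and threshold 0.25.  Reported: the percentage of the 2,000
frames per regime with an accepted detection after the ad-hoc and post-hoc
stages.  Problem sizes were chosen so the whole evaluation completes in
about a minute on a single core.

## Known limitations

* The pair-sampling detector needs both major-axis extremities of a body
  visible; occlusion of a body end degrades the raw detection and shifts
  the burden to the correction stages.
* Chain detection through the size prior requires
  1.5·(min_major+max_major)/2 ≤ max_major, i.e. min_major ≲ max_major/3;
  with a tight size window a chained pair is instead resolved directly as
  two ellipses (which is usually preferable).
* The curvature index inherits the one-sidedness of its defining formula;
  use the symmetric components for direction-agnostic turn statistics.
* Identity maintenance is positional only; animals that swap positions
  within one frame interval while occluded can swap identities.
* The LPT job balancer guarantees a makespan within 4/3 of optimal, not
  optimality (e.g. durations {5,4,3,3,3} on two cores pack to 10 versus
  the optimal 9).
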