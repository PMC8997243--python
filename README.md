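# contourpose

Markerless midline pose estimation and locomotion kinematics for limbless
animals.

## The problem

Crawling fly larvae, swimming fish, and worms propel themselves by
deforming their whole body, so representing them as a single point (or a
rigid oriented blob) discards exactly the information that matters:
peristaltic length changes, lateral bending, undulatory waves.  At the same
time these animals offer no joints, limbs, or colour patterns on which
physical or in-silico markers could be placed, and aquatic or burrowing
lifestyles shed attached markers quickly.

`contourpose` builds the pose *de novo* from the animal's contour.  Each
frame is reduced to a difference image against an animal-free background,
the body is found as an ellipse by a Hough-transform voting procedure,
multi-animal occlusion errors are repaired by rule-based corrections and a
user-supplied animal-count prior, and the body midline ("pseudo-skeleton")
is reconstructed from the contour alone.  Calibrated tracks then yield the
standard undulatory-locomotion statistics.

## Method at a glance

**Detection.**  A temporal min/max/mean projection over the video gives an
animal-free background B; each frame F is segmented via the normalised
absolute difference |F − B|, a fixed threshold (default 0.25), optional ROI
masking and disk erosion, and outer-boundary tracing of the connected
components.  Each boundary's edge set goes to a pair-sampling ellipse Hough
transform: every pair of edge points at an admissible distance is
hypothesised to span the major axis, all other edge points vote for the
implied semi-minor length in a 1-D accumulator, and a peak yields a
candidate (centre, a, b, θ) with quality q ∈ [0, 1] — the fraction of the
candidate's perimeter supported by edge pixels.  Partially occluded bodies
are still found, with proportionally lower q.

**Correction.**  With the user's animal count n as a prior, each frame's
candidate set is repaired by seven rules covering duplicate fits,
spurious detections, missed animals (filled from the sub-threshold
candidate pool), and "chaining" — two animals aligned end-to-end fitted as
one ellipse at least 1.5× the expected size, which is split and refitted.
Frames still missing animals are rescued by scoring sub-threshold
candidates against the neighbouring frames with weighted position /
surface-area / contour-length similarity.  Every repaired detection carries
quality −1 so downstream analyses can see it.  Identities propagate by
minimum-cost (Hungarian) assignment on centre distances.

**Pose.**  100 evenly spaced contour points seed a Voronoi tessellation;
the tessellation's interior vertices trace the body's medial axis, and the
midline is the Dijkstra shortest path between the two end vertices of that
skeleton graph.  From the midline come the body length L, the mean
inter-segment bending angle (180° = straight), and the curvature index

    c = (∫|y| − ∫y) · (−sign(y_mid)),

computed on the skeleton rotated so its end-to-end axis is straight (y is
the lateral coordinate): turns and s-shaped postures separate cleanly.

**Kinematics.**  The peristaltic contraction amplitude is
A = (1 − L_min / L_max) × 100 %.  Ego-centric velocities decompose motion
into thrust (along the heading), slip (perpendicular), and yaw velocity;
saccades are yaw-velocity peaks above 200 °/s and thrust strokes are
forward-speed peaks above 10 cm/s, with event-triggered averages, event
frequencies, and a permutation test on group medians for comparisons.

Because real recordings cannot ship with ground truth, the package includes
first-class synthetic generators (`make_crawler`, `make_swimmer`,
`make_multianimal`) that render scenes with programmed peristalsis, turns,
saccades, thrust strokes, occlusion and chaining — under a high-contrast
uniform regime and a difficult backlit-tank-like regime — together with the
exact truth, so every pipeline stage is validated by parameter recovery.

## Worked example

```bash
python examples/01_track_crawler.py
```

```
frames tracked        : 200/200
midline length        : 49.5-59.9 px (true 51.0-60.0)
contraction amplitude : 15.1 %  (programmed 15.0 %)
length correlation r  : 0.994
median bending angle  : 175.5 deg (180 = straight)
```

Every frame of the 200-frame scene is tracked; the per-frame midline
length follows the programmed peristaltic oscillation (r = 0.994), and the
contraction amplitude recovered from the tracked skeleton matches the
programmed 15 % within 0.1 percentage points.  The other examples cover
intermittent swimming (`02`), multi-animal chaining (`03`), metric
calibration (`04`), group comparisons (`05`), and batch scheduling (`06`).

A thin CLI wraps the same pipeline for shell use:

```bash
contourpose synth crawler --seed 1 -T 200 --out scene/
contourpose run config.yaml
contourpose balance --durations 5,4,3,3,3 --cores 2
```

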