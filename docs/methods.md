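# Methods

This note documents the models, parameter choices and numerical details
behind `rowoptics`, in the order the data flows.

## Reference frames and units

All lengths are millimetres, angles degrees, internally converted once at
the boundaries. The platform frame has x along the travel direction
(driven by the ground-wheel encoder), y lateral toward the crop row and z
up; after height normalisation the lowest observed point defines z = 0.
All plant locations are along-track x coordinates, so "spacing" always
means along-track distance.

## Light-beam chain

The beam detector is modelled as a latched binary channel sampled once per
encoder pulse: the blocked state is asserted from the pulse during which a
stem's leading edge cuts the beam until the pulse after its trailing edge
clears it. Two consequences follow. First, a stem of diameter d produces
a blocked run of length in (d, d + 2p) for pulse resolution p, i.e. the
run length overestimates the diameter by one pulse on average — bench
calibration with 10-mm stems at 1.18 mm/pulse gives estimates near
11.2 mm. Second, the run's sample-mean distance is an unbiased stem
location, accurate to well under one pulse.

Stages and their parameters:

- `pulse_distance_relation` (mm/pulse): encoder calibration; 1.18 for the
  lab conveyor encoder, 0.98 for the field ground wheel.
- `detection_filter` = 4 mm: minimum along-track length of a valid
  detection. Removes leaf/weed blips, which in the generator are 1.5-mm
  obstacles whose latched runs stay below 4 mm at either calibration.
- merging: the nominal spacing carries a ±20 % tolerance. A candidate
  detection closer than `(1 − 0.2) × theoretical_plant_distance` to the
  previous potential plant is treated as another interruption of the same
  plant (leaves, split stems) and merged; the merged plant's location is
  re-chosen as the contributing interval midpoint closest to the previous
  plant's location plus one nominal spacing (for the first plant, its own
  seeding midpoint plus one spacing). Anything farther starts a new
  plant. The upper bound `expected_plant_distance`
  (= 1.2 × theoretical) flags suspiciously long gaps (missing plants) in
  diagnostics. The lower-bound form of the gate is what makes the rule
  self-consistent: with plants at the nominal spacing, the gate must sit
  below the spacing itself, otherwise every neighbour would merge; the
  20 % tolerance is symmetric about the nominal value.
- Streams must be monotone in distance; reverse travel raises an error
  rather than being folded.

## LiDAR chain

**Decoding.** Each scan is decoded in a horizontal-reference sensor frame
whose scan plane is x′ = 0, with α = 0 along +y′ and positive angles
toward +z′. Ranges at or below the 50-mm gate (sensor-window
reflections, dust, no-return markers) are dropped.

**Pose.** Points map to the platform frame as row vectors multiplied by
Rx(φ), Ry(θ), Rz(ψ) and a translation adding the per-scan encoder value to
x, in exactly that order and with the sign placements of the standard
row-vector convention. The lateral mount is (0, −180, 0). The chain is
verified against a hand-computed case (pitch −180°, translation 1000:
(100, 200, 300) → (900, 200, −300)) and by an isometry property test.

**Downsampling.** A box-grid filter with 3-mm cubic boxes anchored at the
cloud's minimum corner; each occupied box is replaced by the centroid of
its points. Centroid merging (rather than keeping one representative)
preserves surfaces' mean position under noise.

**Ground removal.** The cloud is cut into 80-mm along-track intervals;
the final interval absorbs the remainder, because a sliver narrower than
one interval can contain points from a single scan only — those lie in one
vertical plane, for which no admissible ground plane exists, and the whole
bed slice would leak through as phantom aerial points. Per interval, an
MSAC plane (3-point hypotheses, 500 iterations, truncated squared-distance
cost with a 40-mm cap, least-squares refinement on inliers) is fitted
subject to the normal lying within 5° of (0, 0, 1); hypotheses violating
the constraint are discarded before scoring. Inliers within 40 mm are
removed as ground. Intervals with fewer than 3 points, or where no
admissible plane exists, pass through unfiltered with a warning. Each
interval also stores its ground line: the plane's trace in the x–z plane
at the median y of its inliers.

**Clustering.** Aerial points are k-means clustered in 3-D (squared
Euclidean cost). The initial count is
`floor(travelled / theoretical_spacing + 1) × 2`, deliberately
over-segmenting; the first fit uses k-means++ seeding, best of 5
replicates. While any two cluster centres are closer *along-track* than
`min_distance_between_plants` = 0.2 × theoretical spacing, the count is
reduced by one and the clustering repeated, warm-started from the previous
iteration's centroids with the offending pair fused into its weighted
mean. Two choices matter here:

- the separation test uses x only. It is a plant-spacing criterion; two
  fragments of the same plant differ mainly in height, and a 3-D test
  would stop the reduction while plants are still split vertically.
- the warm start makes the reduction a deterministic coarsening of the
  over-segmented solution. Re-seeding each reduced k from scratch
  occasionally lands in local optima that split one plant and merge two
  neighbours, ending the loop with a missed plant.

Clusters with fewer than 5 members are discarded.

**Plant location.** Three estimates per cluster:

1. *Centre of the cluster*: centroid x. Tracks the canopy for leafy
   plants.
2. *Lowest point*: x of the minimum-z member (ties broken toward smaller
   x). Tracks the stem base, but inherits single-point noise.
3. *Stem/ground intersection*: member x values are histogrammed in 4-mm
   bins; the maximal-count bin (adjacent ties merged) gives an x window,
   and only points in the bottom half of the cluster's z range survive.
   An ordinary least-squares line of z on x through the survivors is the
   stem line; its intersection with the interval's ground line is the
   estimate. Near-vertical survivor sets — x spread under 1 mm, or
   |Pearson r(x, z)| < 0.3, since a vertical column's x scatter is pure
   measurement noise and gives OLS no leverage — use x = median(x)
   directly. The method falls back to the lowest point, with a warning,
   when fewer than 2 points survive, the stem line is parallel to the
   ground line, or the intersection lands more than half the nominal
   spacing from the survivors (a symptom of a contaminated fit).

On straight plants all three agree to a few mm; on leaning plants the
centre follows the canopy while the intersection and lowest point stay
near the stem insertion — the spread between them measures the lean,
which is what makes the three outputs useful for choosing between foliar
and stem-targeted treatments.

## Image chain

Plant segmentation keeps pixels whose green channel dominates red and
blue by a margin (default 10 digital numbers), cleans the mask by erosion
followed by morphological reconstruction (specks smaller than the
2-px-radius structuring element vanish; surviving shapes are restored),
and takes the stem column as the median x of the bottom 20 % of the
largest component's rows. White balance/saturation is reduced to an
optional linear per-channel gain; full camera colour pipelines are out of
scope.

The inter-frame displacement estimator is whole-image translational
registration by phase correlation — deterministic and dependency-light;
its contract (a signed pixel shift) is all the chain consumes, so a
keypoint-based estimator can be substituted. Registration is rejected
when the aligned overlap's correlation falls below 0.2 (structureless or
non-overlapping frames). The motion relation is
|encoder delta| / |pixel shift| mm per pixel; per-frame stem locations
are `encoder + offset_px × mm_per_pixel` with positive offsets toward
larger along-track x (mirrored rigs must negate the offset), and a
plant's estimate is the mean of its per-frame locations, grouped by
splitting sorted locations at gaps exceeding half the nominal spacing —
the same radius that defines a false positive.

## Synthetic rows (what the generator does and does not emulate)

The generator ray-traces a raised trapezoidal seedbed (flat top with
optional along-track tilt, sloped shoulders, lower base ground) carrying
a row of plants: vertical or leaning 10-mm stem cylinders, and for
tomatoes an ellipsoidal foliage shell (default radius 60 mm, centred at
0.75 of the 195-mm stem height, porous: each shell hit returns with
probability 0.5, as sparse leaf matter does). The sensor advances at
360 mm/s emitting 50-Hz scans with 0.5° beams over a 2–80° downward arc;
each beam returns its nearest intersection plus Gaussian range noise
(default σ = 5 mm). Plant positions are cumulative nominal-plus-jitter
draws: 300 ± 15 mm by default, 240 ± 10 mm for the 19-stick calibration
row, 290 ± 30 mm for field-like tomato rows, 100 ± 2 mm for the 11-plant
lab conveyor. The light beam crosses at 40 mm above the bed; frames fire
every second with exact pinhole offsets at 0.5 mm/px plus optional pixel
noise. All generators are deterministic under a fixed seed.

Not emulated: radiometric effects (intensity, sunlight, wet foliage),
encoder slip and vibration beyond Gaussian noise, wind motion, occlusion
between neighbouring plants' foliage, weeds in the LiDAR scene (weeds
appear only as beam blips). Passing tests on these rows therefore
demonstrates the algorithms' geometric correctness and noise tolerance,
not field robustness: on real recordings, foliage overlap and clutter
produce the few-percent false positive/negative rates that the synthetic
rows, with their separated plants, do not.

## Problem sizes and determinism

The standard scenarios are desk-scale: a 19-stick row is ~775 scans of
157 beams (~120 k raw points, ~1.2 k aerial), a 20-plant tomato row
~1000 scans; a full pipeline run takes about one second. Every random
stage (row jitter, range noise, foliage porosity, MSAC sampling, k-means
seeding) draws from generators seeded by the configuration, so identical
configurations reproduce identical outputs byte for byte.

## Known limitations

- The beam chain cannot separate plants closer than the merge gate
  (0.8 × nominal spacing) and will fuse them into one record.
- The stem/ground intersection degrades when foliage dominates the x
  histogram; the fallback chain (lowest point) bounds, but does not
  eliminate, the error.
- The reduction loop assumes plants are at least 0.2 × nominal spacing
  apart; true doubles (two transplants in one hole) are returned as one
  cluster.
- PLY support covers xyz vertex clouds (ASCII and binary little-endian)
  only.
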