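# Methods

## Scene model and preprocessing

The unit of all computation is a *scene*: an N × N matrix of integer gray
levels in [0, G−1] with every pixel strictly outside the inscribed circle of
diameter N set to level 0 (a circularized fisheye snapshot). The capture
pipeline, applied in this fixed order, is:

1. grayscale conversion (channel average),
2. centered square crop,
3. histogram equalization,
4. exact area-average downsampling to N × N,
5. uniform quantization of [0, 1] into G levels (floor-based, top edge
   inclusive),
6. circular masking.

Equalization maps intensities through the exact empirical CDF (one bin per
distinct input value) renormalized so the smallest occurring value maps to 0
and the largest to 1; a constant image maps to 0.5. This renormalization
guarantees that an image with G equally frequent values occupies all G
output levels. The choice is recorded in every manifest. Quantization is
idempotent on the level grid, so re-quantizing a stored scene changes
nothing.

The laboratory-style configuration is N = 100, G = 10; corridor traverses
default to G = 100.

### Rotation

Scene rotation is nearest-neighbor resampling about the matrix center.
Positive angles rotate content clockwise under the shared compass
convention (0° = +row/transect axis, 90° = +column/point axis), i.e. content
at image azimuth *a* moves to *a* − θ. Trigonometric coefficients are exact
at multiples of 90°, making quarter turns lossless permutations. Rim pixels
whose rounded source coordinate would fall just outside the circle fall back
to the nearest in-circle neighbor of the true rotated coordinate, so
rotationally symmetric scenes are exactly invariant at every angle.

Nearest-neighbor resampling quantizes small angles: a 1° turn moves pixels
at radius r by r·π/180 ≈ 0.3 px at r = 20, below the rounding threshold for
most of the image. Consequently (a) low-resolution RIDF curves are rough,
and (b) a plateau of angles around an exact planted rotation can all achieve
SAD 0; ties in `best_rotation_match` break toward the smallest angle, then
the smallest memory index.

## Information analyses

`sad` is a metric on equal-shape scenes. The familiarity landscape is the
mean unrotated SAD of each survey scene against all scenes (including
itself); a *volcano* is the same field for a single focal scene.

**IDF.** Per focal cell, the row and column slices of its volcano are folded
at the focal minimum into a falling and a rising half-slice — exactly four
half-slices per cell, counting the (possibly length-0 beyond the focal)
slices of boundary cells, so a T × P grid yields 4·T·P vectors. Values are
normalized by the landscape's single maximal pairwise SAD at that
resolution (per-focal normalization would force every volcano to peak at 1,
which the data do not support). The mean at distance d pools every
half-slice long enough to reach d; the curve therefore dips where only
wall-adjacent geometry contributes.

**RIDF.** Each scene's full-turn rotational difference curve is folded at
180° into rising (0→180°) and falling (360→180°, reversed) halves — 2·T·P
vectors — and normalized by the landscape's maximal rotational SAD.

**p50.** Both averaged curves are summarized by the first upward crossing of
half the curve's own maximum, located by linear interpolation between the
bracketing samples. Distances are reported in meters (grid points ×
0.127 m), angles in degrees. A landscape with zero maximal difference (all
scenes identical, or rotationally symmetric scenes for the RIDF) has a flat
zero curve and no p50.

**Path fields.** The trough field relative to a training path takes, per
cell, the minimum SAD over all path scenes *and* all rotations (the arrows
of the quiver field are directions recovered by rotational matching, so the
rotating definition is used for both). Quiver strength is
1 − value/max(value), clipped to [0, 1].

## Training paths

Waypoints are continuous grid coordinates. Bearings follow the compass
convention above. Each segment contributes the *supercover* of grid cells —
every cell whose unit square the segment touches, computed by exact
segment-vs-box clipping and ordered by entry parameter — so no intersected
scene is skipped. Consecutive duplicates are dropped; a cell at a segment
junction therefore keeps the earlier segment's bearing (one stored
orientation per path scene). Each selected scene is stored rotated by its
segment's bearing: what a traveler heading along the segment would see.
Externally captured paths take `count` evenly spaced frames (endpoints
always included, indices round(k·(F−1)/(count−1))), with bearings unknown
and stored as 0.

## The tracking agent

Per decision cycle the agent considers adjacent views in the fixed sequence
front, 45° right, 45° left, 90° right, 90° left (the three-view variant
stops after 45° left). Each view offset is added to the heading, quantized
to the nearest 45° sector, and mapped to the corresponding 8-neighbor cell;
off-grid candidates are dropped. Candidates are evaluated in order against
the unordered path memory via full rotational matching; the first whose
minimum SAD falls below the familiarity requirement is taken immediately
(later views are neither evaluated nor counted in T). If none qualifies,
the globally best candidate is taken (ties → earliest view order). The
chosen view's best rotation angle becomes the new heading — the path scenes
are stored pre-rotated to their bearings, so a good match re-aligns the
agent with the path direction.

The familiarity requirement is computed once per run as the mean scene
difference between all landscape and path scenes divided by the threshold
(≥ 2). The default mean uses unrotated all-pairs SAD — the cheapest
reading — with a `rotation-minimized` switch for sensitivity analysis.

Termination: reaching the path's end cell within a Chebyshev radius
(default 2 points) is success; exceeding `max_steps` (default 200) or
oscillating — the last `oscillation_window` (default 8) (cell,
heading-sector) states forming a strict 2-cycle, the agent rocking back and
forth — ends the run, counting as success only if it happens within the
success radius. The agent keeps no memory of its own trajectory, so
immediate backtracking is permitted. The whole algorithm is deterministic.

Metrics: **T** sums every candidate actually evaluated over the run (scenes
considered, a time proxy). **D** sums, over all visited cells including the
start, the Euclidean grid distance to the nearest path cell times the grid
pitch (meters).

## Aliasing analysis

The cross-SAD matrix of an ordered traverse is symmetric with zero
diagonal. The neighborhood profile pools matrix(i, i+o) for signed offsets
−12…+12 (25-scene window, truncated at the ends), reporting mean and sample
SD per offset. Local minima are offsets |o| ≥ 2 strictly below both
neighbors on the focal-averaged curve (one index per sequence). The
aliasing index is the lowest local-minimum value minus the nearest-scene
value (mean of offsets ±1); no local minima → no index (the visually rich
case). Larger is safer; a negative index means some distant scene pair is
more similar than adjacent scenes are.

`rank_neighbors` sorts a multi-setting scene stack by SAD to a focal scene
(focal first at SAD 0, ties by index) and reports whether each of the k
most similar scenes is a true within-setting path neighbor.

## Synthetic worlds

The generator emulates a survey of a rectangular room by an upward-looking
360° camera at 1.28 m on a 12.7-cm grid. Landmarks are Gaussian gray splats
on the walls and ceiling, projected by an equidistant fisheye model (image
radius ∝ polar angle from the zenith; the simplest omnidirectional-lens
stand-in) and composited far-to-near. Scenes are evaluated on a
supersampled grid (~100 px across; factor round(100/N)) and block-averaged
down to N before quantization, emulating capture-then-pixelate: coarse
sensors therefore see a genuinely blurred world, which is what gives them
wider catchments. Because heading enters only as an exact rotation of the
pixel-offset grid, rendering at a quarter-turn heading is bitwise identical
to rotating the heading-0 image.

The rich-room generator places 120 landmarks (richness 1.0) with
multi-scale angular sizes — 60 % fine texture at 2.5–10°, 40 %
furniture-scale at 10–30° — because a single-scale world has no
resolution-dependent information content, and the resolution trade-offs
under study require both features a fine sensor resolves and a coarse one
blurs. Corridor worlds optionally tile one landmark motif at a repeat
distance to plant periodic scenery. All randomness is fixed by the world
seed.

What the generator does **not** emulate: illumination and shadows, depth
occlusion beyond painter's ordering, lens distortion beyond the ideal
equidistant model, photorealistic clutter, or temporal change between
training and recall. Passing tests therefore demonstrate the algorithms'
behavior on controlled, information-rich panoramas, not performance on
real imagery.

## Problem sizes and study conditions

The test suite runs at desk scale, chosen to keep the full suite around a
minute while preserving every qualitative contrast:

- fold-count checks render the full 40 × 45 (1800-scene) survey at N = 10;
- resolution trends use a seeded 10 × 10 grid of one room at
  N ∈ {10, 20, 40, 80} with RIDF steps of 3°;
- the tracking trade-off uses a two-curve path, 40 grid starts, threshold 4
  (the reference setting for simple-path trials), 15° rotation interval,
  and a 60-step budget. The success-region claim is asserted as dominance
  of the coarse sensor in both success count and maximum successful start
  distance; mean D is compared over the starts where *both* resolutions
  succeed, because comparing each resolution's own success set would
  confound tracking accuracy with the coarse sensor's wider catchment
  (its extra, farther successes enter only its own mean);
- aliasing uses 50-scene traverses at G = 100, with a 2.0-m motif period
  (10 scenes) for the repetitive corridor.

## Known limitations

- Agent positions are grid cells; there is no continuous movement,
  path integration, or sequence-aware matching.
- The supercover rasterizer orders corner-touching cells by (entry
  parameter, row, col); paths that cross themselves re-store revisited
  cells with their own segment bearings.
- The PNG store supports G ≤ 256.
- `best_rotation_match` is exact but exhaustive (O(rotations × memory ×
  N²) per candidate); large surveys at 1° steps are better analyzed with
  coarser steps first.
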