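# Methods

## The model

`phantomtract` separates a tractography protocol into five testable stages
operating on a shared voxel grid (RAS-like world mm; a voxel's world
position is the affine image of its 0-based integer index, voxel-center
convention).

**Fiber field.**  The substrate for tracking is a per-voxel crossing-fiber
model: each voxel holds 0–3 fiber populations, each with an axial (sign-free)
unit mean orientation, a volume fraction (per-voxel sums ≤ 1), an angular
dispersion, and a set of pre-drawn unit orientation samples emulating
posterior draws from a fitted multi-fiber diffusion model.  The package
*generates* such fields from phantom geometry; it does not fit them from
diffusion data.

**Tracking.**  From every seed voxel, `n_samples` streamlines start at
uniformly jittered positions inside the voxel.  At each step the tracker
looks up the populations of the voxel containing the current position
(nearest voxel, no interpolation), keeps those with volume fraction ≥ the
fraction threshold (default 0.01), selects the population whose mean is
angularly closest to the heading (axially, by |cos|; at seeding the choice
is instead random, weighted by volume fraction), draws one stored
orientation sample and flips its sign so it agrees with the heading.  A
proposed direction with cos(new, previous) below the curvature threshold
terminates that end without resampling; leaving the grid or reaching a voxel
with no passing population also terminates.  Tracking is bidirectional by
default: a second pass starts from the seed with the initial direction
negated, and the two half-paths are concatenated with the seed appearing
once.  Default parameters are the human protocol (10,000 samples/voxel,
≤3200 steps, 0.25 mm steps, curvature threshold 0.2); the macaque protocol
changes only the step to 0.1 mm.

**Mask semantics.**  Exclusion (and CSF) contact anywhere on the full
concatenated path rejects the whole streamline; otherwise every waypoint
volume must be intersected by at least one point; otherwise the streamline
is retained.  The visitation map counts, per voxel, the number of distinct
retained streamlines with at least one point there (a streamline counts at
most once per voxel).

**Normalization.**  `norm = log(1+counts) / P75`, with `P75` the 75th
percentile (linear interpolation) of `log(1+counts)` over *nonzero* voxels;
zero voxels stay zero.  `log(1+x)` keeps zeros finite; restricting the
percentile to nonzero voxels avoids degenerating to 0 on sparse maps.  After
the operation the nonzero 75th percentile is exactly 1, which is the
calibration property the tests assert (the operation is deliberately not
idempotent because of the log).  Display thresholding ([0.5, 2], floor to 0
below, clamp above) is visualization-only; statistics use unthresholded
maps.  Group templates are voxelwise means of normalized maps.

**Gradient.**  Two source-specific runs (seed in the source region, waypoint
= the bundle's original seed mask, then log-normalization) give maps A and
B; the gradient ratio is (A−B)/(A+B) within the bundle mask, in [−1, 1].
Voxels with A+B = 0 are invalid and carry NaN — never 0, since 0 means
"balanced origin" — and are excluded from all summaries.  A source run that
retains nothing returns an all-zero map flagged empty rather than erroring,
so a source that feeds the *other* bundle yields a well-defined ratio of ±1.

**Fingerprints.**  Per ROI of a label atlas, the mean *raw* visitation count
over the ROI's voxels; the per-tract vector is divided by its maximum.  Raw
counts (not log-normalized values) are used because the quantity is a
streamline count per ROI; groups are means of normalized fingerprints and
are not renormalized.  Cross-species comparison is the Manhattan distance
for every tract pair, columns aligned to the row species' tract order; the
diagonal best-match rate counts rows whose strict minimum is the diagonal,
with ties counting as non-matches.

## The phantom generator

Phantoms are tubes of radius r around polyline centerlines in world mm.  A
voxel is inside a tube if its center is within r of the densified centerline
(sampling step = voxel/4); its population mean is the tangent of the control
segment nearest to it.  Tangents are deliberately segment-wise, not smoothed
across corners: an L-shaped centerline is a genuine 90° orientation flip, so
the curvature threshold is actually exercised (a smoothed tangent would let
streamlines round the corner in two 45° steps and the threshold would gate
nothing).  Where k tubes overlap, each population receives fraction 1/k
(single-tube voxels keep the bundle's own fraction, default 0.7); an
optional porosity interval multiplies a bundle's fraction by a factor
(default 0.5) over part of its arclength, emulating passage through porous
heterogeneous tissue.  Orientation samples rotate the mean by a
folded-normal angle (SD = dispersion) about a uniformly random perpendicular
axis — a simple, controllable stand-in for a fitted orientation posterior;
zero dispersion reproduces the mean exactly.  Default dispersion in the demo
phantom is 8°, a mid-range choice for coherent white matter; it is an
exercise parameter, not an estimate of any fitted posterior's width.  32
samples per population balance orientation diversity against memory.

Mask recipes are rasterized per tract: the seed slab is the bundle tube
intersected with an interval on the anterior axis (seeding in coherent
"high-anisotropy" white matter), the waypoint is a full coronal slab in the
frontal-analog region, exclusions are the posterior slab behind the seed
plus a one-voxel boundary rind standing in for CSF; an opposite-hemisphere
exclusion would be just another exclusion volume.  ROIs are spheres
rasterized by exact Euclidean distance; overlapping spheres are a
construction error.  With volumetric ROIs the white/gray-border versus
interior distinction of surface-based ROIs is collapsed — an acknowledged
approximation.

The demo phantom (64×48×32 voxels at 1 mm) encodes the study's geometric
motif: a medial tube fed by an amygdala-analog source and a lateral tube fed
by a temporal-pole-analog source run anteriorly and converge into a merged
rostral segment; a dorsal control tube and four prefrontal-analog ROI
spheres (medial, mid, lateral, dorsal; the mid ROI is reached by both
ventral tracts, giving overlapping fingerprints like real ventral-prefrontal
bundles) complete the scene.  The merged segment is defined as the union of
the two ventral tubes beyond 75 % of the anterior extent, split into medial
and lateral halves at its mean y coordinate.  The species pair scales all
world coordinates (centerlines, radii, sources, ROIs, recipe slabs) by 0.5
with a proportionally finer grid, gives the macaque-analog its own RNG seed,
and attaches the species tracking configs (0.25 vs 0.1 mm steps); scaling
that would push a tube radius below one voxel is rejected.

## What the phantom does and does not show

Passing tests establish that the *protocol logic* is correct: mask
filtering, curvature gating, normalization calibration, the sign and
organization of the gradient ratio, and fingerprint matching behave exactly
as specified on fields whose connectivity is known.  The phantom does not
emulate imaging physics — no diffusion-signal simulation, no noise floor, no
partial-volume fitting error, no registration error, no gyral geometry — so
green tests say nothing about whether a fitted model on real data supports
these inferences; they say the chain from orientations to conclusions
introduces no errors of its own.

## Numerical choices

* Exact step lengths: every step is exactly `step_size_mm` (asserted to
  1e-6 mm); float64 positions throughout tracking.
* Sign alignment at cos = 0 keeps the drawn sample's stored sign (relevant
  exactly at orthogonal junctions, where the curvature check then decides).
* Population choice is deterministic given the heading (argmax |cos|); ties
  resolve to the first slot in voxel-table order.
* Percentiles use numpy's linear-interpolation convention.
* Normalized maps and written volumes are float32; this bounds the
  calibration check at ~1e-6 rather than 1e-9 when read back from float32
  storage (in-memory float64 calibration is exact to 1e-9).
* Determinism: one generator per tracking run, seeded from the config; every
  per-step random draw covers the whole streamline batch whether or not each
  streamline is still active, so trajectories are independent of when
  neighbours terminated.  The pipeline derives per-(stage, species, tract)
  substream seeds from the global seed via `SeedSequence` spawn keys, so any
  stage re-run is byte-identical.
* Zero retained streamlines is an explicit empty result (flagged map), not
  an exception; an all-zero map is however an error for normalization, and
  an all-zero fingerprint ("tract reaches no ROI") is an error for
  max-normalization.

## Design choices that were genuinely open

* **Streamline container**: TCK (world-mm, grid-free) via nibabel — the
  simplest well-defined standard for point sequences; visitation maps are
  int32 NIfTI, normalized maps float32 NIfTI.
* **Bidirectionality**: whether the protocol seeds both directions per
  sample and how waypoint crossings are counted is not fixed by the protocol
  parameters; here both half-paths are launched and all mask logic applies
  to the full concatenated path.
* **Gradient masking**: ratio maps are reported on the full support of the
  normalized source maps intersected with the bundle mask.
* **Fingerprint counting**: per-voxel-mean of visitation counts implements
  "average number of streamlines hitting the voxels of each ROI"; counting
  unique streamlines per ROI would be an alternative reading and can be
  built from the retained streamline set if needed.
* **Overlap fractions**: 1/k per population in k-tube overlaps is a neutral
  default that guarantees the ≤1 sum invariant.

## Problem sizes

The shipped tests and the acceptance script run the same analyses at
phantom-appropriate sizes: grids up to 64×48×32, 100 samples per seed voxel
for the mask-semantics checks, 30–50 for the junction, gradient and
fingerprint analyses (a few thousand streamlines per run), 20 reseeded runs
for the gradient-organization check, and 15 samples/voxel for the end-to-end
determinism rerun.  At these sizes the full suite and the acceptance script
each complete in about a minute on one CPU; the protocol-default 10,000
samples/voxel remains the library default for real use.

## Known limitations

* No diffusion-signal simulation or model fitting; the phantom *is* the
  fitted model.
* Nearest-voxel orientation lookup (no interpolation), matching the
  per-voxel sample substrate; trackers that interpolate orientations will
  disagree near boundaries.
* Single-hemisphere phantoms; hemisphere averaging is out of scope.
* Volumetric sphere ROIs, not surface-derived discs; no geodesic geometry.
* The dispersion model (folded-normal rotation about a random perpendicular
  axis) is isotropic about the mean; real orientation posteriors can be
  anisotropic (fanning).
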