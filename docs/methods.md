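# Methods

## Model

`ecmflock` couples two layers. The *cell layer* is a nematic variant of the
Vicsek flocking model: N self-propelled rod-shaped agents on a continuous
2-D domain with periodic boundaries (reflecting available), updated
synchronously in discrete time. The *matrix layer* is a lattice of grid
points, each holding non-negative fiber counts in `n_bins` = 8 apolar
orientation bins partitioning [0, π) in π/8 increments; bin b covers
[(b−1)π/8, bπ/8) and its left bound is the orientation cells flock with.

Each step proceeds in three phases:

1. **Orientations.** For every cell, three unit-vector terms are built from
   the time-t state — noise (cos/sin of θ + η, η ~ N(0, Var(η))), cell-cell
   guidance (mean of nematically folded contact headings; a contact is any
   bead pair of two cells closer than the sum of bead radii), and matrix
   guidance (nematically folded left bound of a fiber bin under the head,
   drawn with probability ∝ fiber count). The terms are combined with
   weights (w_p, w_c, w_m), absent terms zeroed, the sum renormalized by the
   applied weights, and the new heading taken by atan2 (previous heading
   kept if the resultant is numerically zero). Cell-cell guidance strength
   is independent of the number of contacts.
2. **Matrix updates**, at each cell's head grid point with the *new*
   heading (orientations are computed before matrix updates in the step
   sequence): deposition adds `deposition_rate` fibers to the heading's bin;
   degradation floors every bin at zero after subtracting
   `degradation_rate`; rearrangement moves up to `rearrangement_rate`
   fibers from *each* cyclic neighbour bin into the heading's bin (chosen
   per-neighbour for symmetry; total count is conserved). The phases apply
   in that order; ordering only matters when deposition and degradation hit
   the same bin in the same step.
3. **Positions.** Each cell advances by s·v_e along its new heading, with
   v_e = 0.25 while its head bead overlaps another cell's bead within 75% of
   the combined radii, else 1. Speeds are per-cell constants drawn from a
   zero-truncated Gaussian.

With density feedback enabled, w_m is replaced by f(d)·w_m (and the
normalizer adjusted accordingly), where d is the fiber count of the selected
bin and f is the piecewise-linear ramp with f(d ≤ 5) = 0, f(d ≥ 10) = 1.
Density feedback is off by default and enabled in the remodeling protocol,
where a thin young matrix should steer cells weakly.

### Nematic folding

Both guidance terms use the apolar representative: the element of
{φ, φ + π} within circular distance π/2 of the cell's heading (ties keep φ).
An antiparallel neighbour therefore reinforces alignment instead of
reversing it — the defining property of nematic flocking — and every
emergent statistic is invariant to flipping any subset of orientations by π.

## Time base, geometry and density calibration

The free constants not fixed by the published model description were set
once, jointly, so that the model's internal density scale is consistent
with the two landmarks that are stated: the density-feedback way-points
(mean guidance-bin density ≈ 5 after four days and ≈ 10 after seven days at
deposition rate 1) and the rendering cut-off (25 fibers = full intensity).

| parameter | default | rationale |
|---|---|---|
| domain | 1 × 1 mm | mesoscale field of view |
| bead radius r | 4 µm | projected cell area ≈ 500 µm², so 800 cells ≈ 40% confluence and 200 ≈ 10% |
| grid | 100 × 100 (10 µm spacing) | one grid cell ≈ cell-body width; a 200 × 200 "twice as fine" option serves the in-vivo presets |
| dt | 30 min (48 steps/day) | with deposition 1/step and 800 cells, mean deposits/point pass ~15 (day 4) → ~27 (day 7), putting the guidance-bin density on the 5 → 10 trajectory of the feedback ramp |
| speed | 10 ± 2 µm/step (0.33 µm/min) | ≈ one grid cell per step: the head samples consecutive grid points, which is what lets a cell follow (and reinforce) an individual fiber track |
| rates | deposition 1, degradation 0, rearrangement 0 | the sweep defaults; the remodeling and organization experiments use 2/10 and 1/5/10 variants |

Noise phenotypes are quoted as η ∈ {0, 0.07, 0.14, 0.21} and interpreted as
the per-step *standard deviation* of the angular perturbation
(`noise_variance_from_eta`, variance = η²; an alternative reading of the
values as variances is selectable). The SD reading is the one under which
the canonical phenomenology appears: alignment degrades gradually along the
η grid instead of collapsing at the first non-zero value, cell-cell guidance
measurably raises alignment for η = 0.14 cells, and matrix feedback gives
noisy cells high short-range order. Persistence-based calibration of a real
cell population's Var(η) is a separate workflow on its own scale and is
validated by parameter recovery, not by a fixed constant.

## Matrix metrics

All five metrics operate either on an `OrientedFiberField` (grid-derived:
one weighted entry per nonzero bin per grid point; image-derived: structure
tensor orientations of above-threshold pixels) or on a grayscale image
(for simulations, the rendered matrix).

- **Alignment (LRA/SRA).** Per focal fiber, the weighted median acute angle
  (∈ [0, π/2]) to all fibers within the neighbourhood length (200 µm / 20
  µm); the image value D̄ is the weighted mean over focal fibers, reported
  as 1 − D̄/(π/2). The weighted median is interpolated (midpoint
  convention), which removes the small-sample bias of a lower-median rule;
  uniform-random orientations then score 0.500 ± 0.03. For fields above 400
  fibers, focal fibers are a weight-proportional subsample of 400 drawn
  from a fixed seed (estimator noise ~0.003, far below condition
  differences).
- **Rendering.** Each occupied grid point draws a segment along its densest
  bin (selection history is not stored, so "densest" stands in for "most
  recently selected"; identical for the common single-dominant-bin case),
  centred on the cell, spanning twice the grid spacing so collinear
  neighbours join, 5 µm wide (2 px at the 2.5 µm/px default — a plausible
  fiber-bundle width that also keeps pixel coverage, and hence HDM, from
  saturating geometrically), intensity min(d/25, 1).
- **HDM.** Percentage of pixels above a threshold: Otsu for external
  images, and a fixed 0.5 for rendered grids — the render intensity scale
  is anchored to the cut-off 25, so 0.5 means "at least half the full-line
  density", keeping simulated HDM comparable across conditions (Otsu on a
  rendered image would adapt to whatever faint matrix is present and score
  diffuse and dense matrices alike).
- **Curv.** Gaussian blur (σ = 8 px) → Otsu mask → skeletonize → decompose
  the skeleton into branch/cycle pixel paths (junctions break paths) →
  resample each path at equal *arclength* increments of the window (10 px
  default; index-based sampling would inflate diagonal-heavy paths by up to
  ~20%) → mean absolute turning angle between consecutive chords, degrees.
  A circle of radius R reproduces the chord formula (window/R)·(180/π)
  within the stated 10%.
- **Frac.** Gaussian blur (σ = 2 px) → Otsu mask → crop to the occupied
  bounding box (translation invariance) on a square canvas → nearest-
  neighbour resample to a dyadic square (removes partial-box distortion at
  coarse scales; a filled square scores exactly 2) → occupied-box counts at
  dyadic sides from half the image down to 2 px → minus the slope of the
  log-log least-squares fit. For strictly geometric masks (single-pixel
  lines, space-filling rasters) the blur is disabled in the reference
  checks, since thickening a 1-px line pushes fine scales into the area
  regime.
- **Starplot normalization** is per-axis min-max over the compared
  collection, constant axes mapping to 0.5.

## Synthetic patterns

The `fixtures` module generates deterministic grids/images with known
metric values: aligned stripe bands (alignment exactly 1, curvature ≈ 0),
seeded isotropic fields with continuous uniform orientations (alignment
0.5 ± 0.03), concentric swirls (SRA > LRA), orientation-domain
checkerboards, circles (curvature from chord geometry), Hilbert-curve
rasters of order 7 (fractal dimension → 2), blank and filled frames. These
are the ground truth for the metrics suite. They emulate the *geometry* of
matrix patterns, not the texture of second-harmonic microscopy — intensity
noise, uneven illumination and out-of-plane fibers are absent — so passing
them validates the estimators' geometric behaviour, not robustness to
imaging artefacts.

## In-silico experiments

- **Sweeps.** The guidance grid (η × w_c, w_m = 0) and the feedback grid
  (η × w_m at w_c = 0.03), 16 conditions each, seven simulated days,
  metrics at the final frame. Replicates are seeded from a master seed via
  per-(condition, replicate) substreams, so changing the replicate count
  never perturbs earlier replicates. PCA is fit on the per-run z-scored
  metrics; constant columns are dropped with a warning. The confluent sweep
  runs 800 cells with 3 replicates (a scaled-down replication; the value is
  stable to ~1 point against 5 replicates), the sub-confluent sweep 50
  cells with 10.
- **Persistence.** Directionality ratio per sliding window: net
  displacement over path length, per-cell median over windows, population
  mean over cells; zero-path windows score 1. An alternative published
  denominator (sum of displacements to all earlier window points) is
  available behind `literal_denominator`. Tracks can be lowess-smoothed
  (span 0.5) before analysis, mirroring how measured trajectories are
  splined; smoothing is applied in the calibration workflows only.
- **Calibration.** Var(η) is estimated by least squares between observed
  persistence (1 h and 2 h windows) and simulations of sparse guidance-free
  cells over a candidate grid; w_m likewise on a thick aligned substrate
  with matrix-update rates zeroed so the substrate stays fixed. Both are
  validated by recovering the generating parameter from synthetic
  observations.
- **Remodeling.** Phase 1 deposits a dermal matrix (dermis preset, 200
  cells, fine grid, deposition 1, density feedback on) for seven days.
  Phase 2 re-seeds zero-noise cells on that grid at deposition 10 under
  four conditions (w_m ∈ {0, 0.2, 0.4}; at w_m = 0.2 with degradation and
  rearrangement rates 5 versus 0) for ten further days; the endpoint
  compares final-day LRA of the remodeling-on and remodeling-off conditions
  with a Welch two-tailed t-test (N = 25). Heavy phase-2 deposition against
  a rate-1 phase-1 matrix is what makes the hand-off meaningful: with equal
  deposition in both phases the inherited mass swamps anything the new
  cells lay down.

## Known limitations

- No cell division/death, chemotaxis, matrix mechanics, cross-linking or
  3-D; fibers do not diffuse between grid points.
- The step length ≈ grid spacing coupling means changing one without the
  other detunes track-following and the density scale; `dt`, speed and
  grid are exposed but should be moved together.
- LRA/SRA on rendered *images* depend on structure-tensor orientation
  estimates and are noisier than the grid-derived path used everywhere in
  the analyses.
- At sub-confluence the cell-cell guidance axis is nearly inert (contacts
  are rare) and HDM is zero outside corralled conditions, so the metric
  table is more degenerate than at confluence; summary statistics derived
  from it (e.g. PCA variance concentration) sit correspondingly higher.
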