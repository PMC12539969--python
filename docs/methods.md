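# Methods

This note documents the models, conventions and numerical choices behind
carcingeo, and what its synthetic benchmarks do and do not demonstrate.

## Shell model

Shells are generated by Raup-type isometric logarithmic coiling: a circular
generating curve (the aperture) is swept around a vertical axis with

- radius `r(θ) = r0·W^(θ/2π)`, expansion ratio `W > 1` per revolution
  (default 2.0);
- centre distance `d = k·r` with fixed offset ratio `k` (default 3.5);
- axial drop `z(θ) = −T·(W^(θ/2π)−1)/(W−1)`, i.e. `T` length units over
  the first whorl (default 1.6·r0), scaling like every other dimension so
  the coil stays self-similar;
- an aperture inclination `β` (default 45°): the generating circle lies in
  the plane spanned by the radial direction and `cos β ẑ + sin β e_t`.

Two deliberate departures from typical gastropod geometry:

- **Open coiling** (`k = 3.5` leaves a gap between whorls). Real shells
  have whorls in contact; open coiling keeps the surface free of
  self-intersection so that every surface point is exposed, which the
  ground-truth construction and the voxelisation path both rely on.
- **Inclined aperture** (`β = 45°`). Real apertures are inclined against
  the coiling axis; here the inclination also couples the lip-tip
  landmarks C/D to the surface-normal field so that the full published
  range of attachment orientations is geometrically realisable on one
  shell.

The final rim is stored as an exact analytic circle (one vertex per
aperture sample), the apex point and coiling axis alongside. The mesh is a
watertight capped tube; the default resolution (96 sweep steps/revolution,
40 aperture samples) bounds the chord sagitta — and hence every
mesh-discretisation error in the pipeline — below ~0.4% of the local
radius.

## Ground-truth anemone placement

`place_anemone` inverts the measurement. Angle 2 equals, by construction
of landmark F, the elevation-complement of the surface normal at the
pedal-disc footprint over the aperture plane G, with the sign set by which
side of G the oral point A lies on. The placement therefore searches the
analytic surface for a footprint whose normal realises the requested
Angle 2 as the pipeline will measure it (including the plane-side term),
then solves for the point E on line CD that makes ∠CBE equal the requested
Angle 1 (the angle is monotone in the position of E along the line, so a
bracketed root solve is exact), and finally lays the synthetic
siphonoglyph cloud as a flat ellipse whose plane contains A and E, with
its two major-axis extremes straddling A so the derived "upper-tip
midpoint" recovers A exactly.

Steeply dorsal-facing placements (Angle 2 well below 90°) combined with
large Angle 1 have no smooth-surface solution on a coiled tube; for these
the footprint is placed on a vertex of the aperture rim, where the crease
between the swept tube and the aperture cap widens the closest-point
direction cone to cover the whole dorsal quadrant. Every candidate is
verified by running the actual mesh-path measurement before the placement
is accepted; the generator guarantees recovery of the requested angles
within 1° at default resolution (measured worst case on the ±40°/120° ×
20–150° grid: ≈ 0.4°).

The only noise source is an isotropic Gaussian jitter on the siphonoglyph
cloud (default s.d. 0.005·r0); mesh vertices stay exact, because in the
emulated workflow the fitted planes come only from the segmented
siphonoglyph region of interest.

## Landmark measurement

- **Plane fits** are total least squares (smallest eigenvector of the 3×3
  scatter matrix), anchored at the centroid, with the normal sign
  canonicalised (largest component positive); orientation-sensitive steps
  re-orient against an explicit dorsal reference vector. Collinear inputs
  (second eigenvalue below 1e−10 of the largest) are rejected.
- **Closest point on mesh** scans all triangles with the exact barycentric
  region algorithm, vectorised; the global minimiser over faces, edges and
  vertices is returned. Tests verify it against an independent
  edge/face-projection oracle.
- **Line–plane intersections** treat lines as infinite and reject
  directions within 1e−9 (relative) of parallel, flagging the specimen
  rather than aborting a cohort.
- Angles are computed with `atan2` forms (stable near 0° and 180°),
  reported in degrees, rounded to 2 decimals only at the reporting
  boundary. Angle 1's sign keys on E's position along line CD relative to
  C (aperture side positive); this is one consistent reading of a
  convention whose published verbal descriptions conflict, chosen so that
  "axis toward the aperture" is positive and E = C gives exactly 0°.
- The dorsal reference for synthetic shells is the outward growth
  direction at the aperture (the direction the opening faces); for real
  data it is an operator input.

## Mock CT path

Voxelisation fills a binary occupancy grid (no attenuation physics — the
analysis consumes segmented surfaces); extraction smooths the grid with a
1-voxel Gaussian before marching cubes at level 0.5, recovering sub-voxel
surface placement (sphere surface area to ~2% at 20 voxels per radius
versus ~6% biased without smoothing). At the enforced minimum of 10 voxels
across the smallest aperture, attachment angles degrade by ~1° relative to
the mesh path (bound: 5°).

## Synthetic dataset conditions

Defaults are the published summary statistics of the study system:

- attachment cohort: 25 specimens, Angle 1 ~ N(19.38°, 41.95°), Angle 2 ~
  N(57.93°, 28.60°), draws rejected outside the representable ranges
  (Angle 2 inside (2°, 178°), Angle 1 inside (−175°, 175°); under the
  default distributions ~2% of draws are redrawn, almost all of them
  Angle 2 values below 0° which no real specimen could show);
- isotope pairs: n = 15, anemone δ¹³C ~ N(−19.2, 0.6), δ¹⁵N ~ N(10.5,
  0.4); crab δ¹³C ~ N(−19.0, 0.5), δ¹⁵N ~ N(9.7, 1.4), per-mil;
- shield lengths: focal-species group means/s.d. as published (this-study
  males 5.49 ± 0.56 mm, etc.); the 23 congeners get generic means of
  2.6–3.4 mm (s.d. 0.45–0.6) and group sizes of 5–8, values chosen as
  typical for the genus since per-species numbers are not printed. The
  per-species availability matrix is engineered so the eligibility rule
  (> 2 individuals per group) yields exactly 14, 13, 15 and 20 comparison
  species for non-ovigerous females, ovigerous females, all females and
  males — the published Bonferroni divisors.

What passing tests on these data do **not** show: robustness to real CT
artefacts (beam hardening, partial volume), to mis-segmented siphonoglyph
clouds, to shells deviating from logarithmic coiling, or to non-normal
size distributions. The generator's noise model is deliberately minimal.

## Statistics

Welch's unpaired two-sided *t* (Welch–Satterthwaite df) is one shared
routine used by both the isotope and the size comparisons; samples need
n ≥ 2 and at least one positive variance, otherwise the test is flagged
as undefined. The eligibility rule reads "more than two individuals"
literally as n ≥ 3. Bonferroni thresholds are exact `family_alpha/m`
internally and printed at 3 decimals. Sample s.d. uses the n−1
denominator throughout. The expected Welch *t* for δ¹³C on synthetic
tables (≈ −1.0) is larger in magnitude than the published −0.73: the
generator conditions are the *rounded* printed group means (−19.2 vs
−19.0), which overstate the true mean separation behind the published
statistic; this is inherent to emulating from printed summaries and is
left as is.

## Determinism

Every generator is a pure function of its configuration and a seed; cohort
and table generators derive child seeds through `numpy` `SeedSequence`, no
stage touches global random state, and the pipeline report excludes paths
and rounds floats before serialisation, so identical seeds give
byte-identical artifacts.

## Problem sizes

Default benchmarks use a 12.5k-vertex shell (25k triangles), 25-specimen
cohorts, 15 isotope pairs, a 439-record shield-length table, and voxel
volumes of ~10⁶ cells; these sizes keep the full suite and the
reproduction script fast while leaving every error bound dominated by the
method, not the discretisation.
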