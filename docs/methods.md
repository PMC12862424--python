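# Methods

## Problem and scope

`tfccmorph` quantifies the insertion footprint of the triangular
fibrocartilage complex (TFCC) on the ulnar head from multi-label 3D
segmentation volumes.  The input is a voxel grid with labels for radius,
ulna and TFCC at millimetre spacing (typically an isotropic, super-resolved
segmentation of wrist MRI); the output is the extracted deep (foveal) and
superficial (styloid) contact patches with their area, dorsal-volar (DV) and
radial-ulnar (RU) maximal lengths, and a three-way shape classification,
plus the agreement and power statistics used to compare measurement methods.
Producing the segmentation itself (network inference or training) is out of
scope; only the segmentation quality metrics (Dice, Soft IoU loss) are
implemented.

## Extraction pipeline

1. **Label smoothing.**  Each label's one-hot indicator is blurred with an
   isotropic Gaussian (`smoothing_sigma`, default 1 voxel) and the voxel is
   reassigned to the arg-max, ties toward the lower label code.  This is the
   simplest label-consistent smoother; σ = 0 is the identity.
2. **Boundary delineation.**  The 3D Sobel gradient magnitude of each
   structure's indicator (per-axis derivatives divided by spacing) is
   normalized to [0, 1] and thresholded (`sobel_threshold`, default 0.1 of
   the peak); the result is restricted to the structure, i.e. its inner
   surface layer.  Voxels with a 6-connected background neighbour are always
   included, because the centred gradient vanishes on flat faces and
   isolated voxels.
3. **Overlap detection.**  Both boundaries are dilated by an ellipsoidal
   ball of physical radius `dilation_radius_mm` (per-axis voxel radii, so
   anisotropic grids behave isotropically in mm), intersected, eroded by one
   voxel to suppress single-voxel bridges, and restricted to voxels within
   one voxel of *both* original boundaries.  The default radius is the
   smallest that bridges two facing one-voxel boundary layers (two voxels
   per axis); explicit radii are floored there because a thinner overlap
   slab cannot survive the erosion.  Lateral bleed of a dilation-based
   overlap grows with the radius (≈ radius − one voxel beyond the true
   contact edge), which is why the default stays minimal.
4. **Component selection.**  Connected components (6/18/26-connectivity,
   default 26) below `min_component_voxels` (default 30) are dropped; the
   component whose centroid is nearest the region seed is kept.  The seed is
   a world point or a landmark label: fovea for the deep insertion, styloid
   apex for the superficial one.  (The source study separated the two
   regions manually in a viewer; landmark proximity is the scripted
   equivalent.)
5. **Plane refinement.**  Classical 3-point RANSAC (default 1000
   iterations, explicit seed, inlier threshold 0.15 mm) with the best
   candidate chosen by inlier count, ties by smaller mean absolute
   residual, followed by total-least-squares re-estimation (centroid +
   smallest-variance direction, two rounds) and recomputed inlier flags.
   RANSAC runs on voxel centres, not a meshed surface.  Inside the full
   chain the effective inlier threshold is floored at 1.05 × the largest
   voxel spacing: a 3-point sample plane lies *on* one boundary layer of the
   lattice, and a band narrower than one voxel cannot reach the facing
   layer, which truncates the patch at coarse spacing.
6. **Footprint definition.**  The final patch is the largest connected set
   of RANSAC-inlier voxels lying on the soft-tissue boundary — the
   ligament-surface voxels in contact with bone.  Restricting to the
   ligament side removes the lateral bleed ring of step 3 entirely (those
   voxels sit on the bone surface beyond the ligament outline), and it is
   the natural reading of an insertion footprint.  Without it the measured
   area carries a positive bias of roughly perimeter × spacing (8–16% for a
   43 mm² footprint at 0.1–0.15 mm spacing).

The chain is bit-deterministic for a fixed seed, and equivariant under
axis-aligned 90° rotations of the volume.

## Morphometry

Area is the planar projected area on the refined plane: inlier points are
projected, rasterized at `raster_resolution_mm` (default: the smallest voxel
spacing) with nearest-pixel assignment, closed with a one-pixel
morphological closing, and counted.  Curved-surface area is deliberately not
measured; on the phantom the contact is planar, so the conventions agree.
DV/RU maximal lengths are extents of the inlier points along the declared
`AnatomicalFrame` axes (axes are supplied, never inferred from the image).
Because extents run between voxel centres they under-read by up to one
voxel; at 0.1–0.15 mm spacing this is below the 5% recovery band.

Shape classification uses two dimensionless descriptors of the projected
patch: *elongation* (maximal in-plane extent over the extent at 90° to it,
scanned at 1° steps) and *solidity* (raster area over the convex-hull area
of the occupied pixel squares; using pixel-corner hulls keeps solidity ≤ 1
by construction).  Rules: solidity < 0.80 → semilunar; else elongation
≥ 2.5 → ribbon; else irregular quadrilateral.  The source taxonomy was
visual; these thresholds are this package's operationalization, chosen so a
13.40 × 3.98 mm convex band (the cohort mean deep footprint) classifies as
ribbon, a compact convex outline as irregular quadrilateral, and a crescent
(solidity ≈ 0.4–0.6) as semilunar.  Both thresholds are configurable and
echoed in every record.

`center_thickness` ray-casts the sheet mask along the plane normal at its
in-plane centroid and adds one spacing unit, so an n-voxel slab at spacing h
measures n·h.

## Segmentation metrics

Dice is the standard per-class overlap 2|A∩B| / (|A|+|B|) with macro
averaging over classes (a pooled reduction is also reported, since published
summary values do not always state the reduction).  Dice of two empty masks
is defined as 1 with a warning (agreement on absence).  The Soft IoU loss is
1 − Σyŷ / (Σ(y + ŷ − yŷ) + η) with η ≥ 0 (default 1; the smoothing constant
is conventionally left unspecified).  For binary predictions at η = 0 the
loss equals 1 − IoU and Dice = 2·IoU/(1+IoU); both identities are tested.

## Synthetic phantom

The phantom is the validation substrate: cadaver volumes are not publicly
deposited, so every pipeline stage is exercised on geometry with closed-form
truth.  The ulna is a cylindrical shaft (radius 0.45·R) plus a spherical
head (radius R, default 9 mm) truncated by a planar foveal facet at height
0.45·R, plus a truncated-cone styloid with a flat tip.  The distal radius is
an offset slab (scenery for label hygiene, not measured).  The TFC is a
0.60 mm sheet suspended 0.8 mm above the facet, carrying a contact boss
whose in-plane outline is the footprint template, laid flat on the facet:

* ribbon — stadium, area (L−W)·W + π(W/2)²;
* irregular quadrilateral — convex quadrilateral (radially scaled rectangle
  corners), shoelace area;
* semilunar — crescent, disc minus an equal offset disc, lens-formula area.

Because the patch is planar on the facet, the truth area *is* the template
area with zero projection distortion.  (Projecting a 13.4 mm template
radially onto a proportionate spherical head would distort area far beyond
acceptable bounds — patch half-length ≈ 0.75 of the head radius — which is
why the facet construction is used.)  A disc pad on the styloid tip is the
superficial insertion; its default area is 10 mm², the capacity of a
proportionate styloid (the cadaver cohort mean, 20 mm², would require a
styloid that overhangs any realistic head).  DV/RU truth extents are
computed from densely sampled template boundaries after placement.

Defaults: 128 × 154 × 84 voxels at 0.15 mm isotropic (≈1.7 M voxels), the
package's stand-in for super-resolved 0.1 mm volumes at a size that keeps a
60-phantom validation sweep on one CPU in a few minutes.  Per-seed geometry
jitter (template dims ±5%, in-plane rotation ±10°, centre shift ≤0.4 mm)
makes a seed cohort behave like a specimen cohort while the truth tracks
each realization.  Boundary noise is i.i.d. Gaussian jitter of the
signed-distance threshold, magnitude `noise_level` voxels.

What the phantom does *not* emulate: MRI intensities and segmentation
errors, curved (non-planar) insertion surfaces, anatomical population
variation, or connectivity between the superficial pad and the main sheet.
Passing recovery tests therefore demonstrates the correctness of the
extraction and measurement chain on known geometry, not segmentation
robustness on real scans.

## Agreement and power statistics

* **ICC.**  ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — computed from the two-way ANOVA mean squares; the standard
  model for method comparison with the conventional bands
  poor < 0.5 ≤ moderate ≤ 0.75 < good ≤ 0.9 < excellent (boundary values
  0.5 and 0.75 are "moderate", 0.9 is "good").  A consistency variant,
  ICC(3,1), is available behind a flag.  Zero total variance raises a
  distinct undefined-ICC error.
* **Regression.**  OLS through statsmodels with standardized betas
  (z-scored fit), VIF per predictor, Cohen's f² = R²/(1−R²), and exported
  residual/Q-Q tables.  Rank deficiency raises an error naming the
  dependent columns.
* **Post hoc power.**  Overall-model F test: critical value from the
  central F(k, n−k−1), power from the noncentral F with λ = f²·n — the
  fixed-model "R² deviation from zero" convention of the G*Power tool.  The
  alternative λ = f²·(n−k−1) is rejected as it corresponds to a different
  effect-size referent.  Note that with this convention, f² = 2.62, n = 11,
  k = 6, α = 0.05 gives power 0.539 (verified against an independent
  Monte-Carlo simulation of the noncentral-F ratio); no standard
  noncentrality convention gives a materially larger value for these
  inputs, and the package always reports the computed number.
* Sample SD uses the n−1 denominator throughout; tests are two-sided.

## Numerical choices and degenerate inputs

* Voxel indexing is 0-based; world coordinates are voxel centres,
  `world = origin + index·spacing`, axis-aligned.  Default orientation tag
  LPS; readers accept only axis-aligned affines/directions (up to per-axis
  sign flips) and record the tag — anything else must be reoriented first.
* Nearest-neighbour is the only label interpolation (labels are
  categorical); resampling can never invent a label.
* Component ties break to the component containing the lexicographically
  smallest voxel; smoothing ties break to the lower label code; RANSAC ties
  break to smaller mean inlier residual; plane normals are sign-canonical
  (largest-magnitude component positive).
* The overlap erosion treats the grid border as filled, so structures
  touching the volume edge are not eroded from that side.
* Collinear point sets, empty masks, missing labels and empty overlaps
  raise typed errors carrying the failing stage; the CLI maps them to
  distinct exit codes (2 usage, 3 input, 4 extraction).

## Validation problem sizes

The shipped test suite measures: template areas against Monte-Carlo
rasterization oracles; every pipeline stage against brute-force oracles
(erosion surface counts, exhaustive nearest-neighbour and pairwise-distance
checks, convolution + arg-max smoothing, planted-plane RANSAC, normal
equation OLS, hand ANOVA ICC and a pingouin cross-check); full-chain area
and shape recovery over 20 seeds × 3 shape classes of noise-free phantoms
(mean |area error| < 5%, class recovery ≥ 18/20); and ICC recovery over
200 simulated tables per reliability level at n = 50 (mean within ±0.05).

## Known limitations

* Area is planar-projected; on strongly curved real insertions it will
  under-read relative to a surface-mesh area.
* Extents are voxel-centre based and quantized to one voxel.
* The dilation-erosion overlap resolves contact only to about one voxel;
  sub-voxel gaps count as contact.
* ICC confidence intervals and bootstrap variants are not provided.
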