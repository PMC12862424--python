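# tfccmorph

Morphometry of ligament insertion footprints from multi-label 3D joint
segmentations, built around the distal radioulnar joint: the contact patch
between the triangular fibrocartilage complex (TFCC) and the ulnar head.

## Who this is for

Researchers quantifying where the deep (foveal) and superficial (styloid)
radioulnar ligament fibers insert on the ulna, from segmented wrist MRI or
comparable label volumes — and anyone who needs the accompanying
method-comparison statistics (ICC agreement bands, regression diagnostics,
post hoc power) in scripted, reproducible form.

## What it computes

Given a label volume (NIfTI or NRRD; labels 0 background, 1 radius, 2 ulna,
3 TFCC) with voxel spacing in mm:

1. Gaussian one-hot **label smoothing**;
2. Sobel **boundary delineation** of TFCC and bone;
3. dilation–erosion **overlap detection** → the preliminary footprint;
4. largest-connected-component selection near an anatomical landmark
   (fovea = deep, styloid = superficial);
5. **RANSAC plane fitting** → the articular plane and its inlier patch;
6. **morphometry**: projected area A (mm²), dorsal-volar and radial-ulnar
   maximal lengths (mm), and a shape class from two descriptors —
   elongation e (max in-plane extent over its orthogonal extent) and
   solidity s (patch area over convex-hull area):
   s < 0.80 → *semilunar*, else e ≥ 2.5 → *ribbon*, else
   *irregular quadrilateral*.

Segmentation quality metrics are included: per-class Dice
2|A∩B|/(|A|+|B|) and the differentiable Soft IoU loss
1 − Σyŷ / (Σ(y + ŷ − yŷ) + η).

The statistics layer provides ICC(2,1) from two-way ANOVA mean squares with
the conventional bands (poor < 0.5 ≤ moderate ≤ 0.75 < good ≤ 0.9 <
excellent), OLS regression with standardized β, VIF and Cohen's
f² = R²/(1−R²), and post hoc power of the overall F test from the
noncentral F(k, n−k−1) distribution with noncentrality λ = f²·n.

Because real cadaver volumes are not publicly deposited, the package ships a
**synthetic phantom generator**: a seeded wrist phantom (ulna with foveal
facet and styloid, radius slab, thin TFC sheet) whose contact footprint is a
closed-form 2D template — stadium, convex quadrilateral, or crescent — so
extracted area, lengths and shape class can be checked against exact truth.
See `docs/methods.md` for the model and its assumptions.

## Worked example

Generate a coarse phantom, extract and measure both footprints, and run a
power analysis:

```sh
cat > spec.yaml <<EOF
grid_shape: [76, 94, 52]
spacing: [0.25, 0.25, 0.25]
seed: 7
EOF
tfccmorph phantom --spec spec.yaml --output-dir pout --format nrrd
tfccmorph extract pout/phantom.nrrd --landmarks pout/truth.json \
    --output-dir eout --seed 7
cat eout/morphometry.csv
tfccmorph stats power --f2 2.62 --n 11 --k 6 --alpha 0.05 --output-dir sout
```

which prints

```
region,area_mm2,dv_length_mm,ru_length_mm,elongation,solidity,shape
deep,52.5,13.25,4.75,2.9016971568995764,0.9459459459459458,ribbon
superficial,10.0,3.25,3.25,1.000000065975565,0.9467455621301774,irregular_quadrilateral
power=0.539 at alpha=0.05 (f2=2.62, n=11, k=6)
```

The deep footprint measures 52.5 mm² against a generated ground truth of
52.47 mm² (this seed jitters the nominal 13.40 × 3.98 mm ribbon template),
with its DV/RU lengths quantized to the 0.25 mm lattice; the elongated,
solid outline classifies as a ribbon.  The superficial patch recovers its
designed 10 mm² pad (a small disc is compact and solid, hence
"irregular quadrilateral").  The power line reads: an effect of f² = 2.62
tested with k = 6 predictors on n = 11 observations at α = 0.05 has a 53.9%
chance of rejecting the null of zero R².

The same operations are available as a library:

```python
from tfccmorph import (default_spec_for_shape, generate_phantom,
                       PipelineConfig, extract_footprint, measure_patch,
                       AnatomicalFrame)

spec = default_spec_for_shape("semilunar", seed=1)
volume, truth = generate_phantom(spec)
patch = extract_footprint(volume, soft_label=3, bone_label=2,
                          cfg=PipelineConfig(seed=1),
                          region_seed=truth.landmark_positions["fovea"])
record = measure_patch(patch, AnatomicalFrame())
print(record.area, truth.deep_area, record.shape)
```

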