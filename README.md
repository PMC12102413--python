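# wsicoloc

Hierarchical, stain- and scanner-independent **colocalization of point
annotations between whole-slide images** (WSIs).

When the same histological section is re-stained (say H&E → an IHC marker
like PHH3) and re-scanned — possibly on a different device with a
different resolution, scan extent and orientation — annotations made on
one scan (mitoses, nuclei, any point set) need to be mapped onto the
other with nucleus-level precision.  Classical registration optimizes one
transform for a whole image and smears residual error over the regions
that do coincide; `wsicoloc` instead refines the mapping hierarchically
down to the neighborhood of every annotation, trading computation time
for sub-micrometer accuracy.  Typical users are computational-pathology
groups building ground truth across stains/scanners for training and
validating detection models.

## Method

For a fixed image `I_F` (the annotation source) and moving image `I_M`,
the pipeline estimates an ordered transform chain `T: I_F → I_M`:

1. **Preprocess** — apply a configured right-angle rotation/flip, segment
   tissue on an overview level (Otsu + morphology, particle relevance
   filter), derive tight ROIs (manually overridable).
2. **Coarse registration** — a 4-parameter similarity transform
   `p ↦ s·R(θ)(p − c) + c + t` on ROI overviews at the level where
   `magnification / 2^L ≈ 2.5×` (80× → L=5, 40× → L=4), optimized by
   adaptive stochastic gradient descent (ASGD) over Mattes mutual
   information (Parzen-window joint densities, random intensity
   sampling, cubic B-spline interpolation), then extrapolated to the
   base layer.
3. **Refinement** — *Strategy I*: rigid re-registration of grid tiles
   covering clustered annotations (the chain is reusable for new point
   sets); *Strategy II*: an affine correction from a small patch
   (128–256 px) centered on each individual annotation.
4. **Transformation** — the chain is applied to arbitrary point sets,
   decoupled from registration, and discretized half-to-even.

Registration quality without ground truth is evaluated photometrically:
patches centered on mapped coordinates, rescaled to the coarsest
scanner's patch dimensions, first/last rows and columns cropped, and
pairwise SSIM reported per annotation (minimum over slide pairs).

A first-class synthetic-data module generates re-stained/re-scanned slide
pairs (H&E-like vs IHC-like appearance, mpp differences, orientation
ops, similarity misalignment, smooth local deformation) with exact
closed-form ground-truth point mappings for quantitative benchmarks.
See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

```python
import numpy as np
from wsicoloc.synthetic import (SlideScenario, generate_tissue_slide,
                                derive_moving_slide, generate_annotations)
from wsicoloc.pipeline import register_pair
from wsicoloc.pyramid import Rect
from wsicoloc.evaluation import colocalization_error

# an H&E-like slide and its re-stained, re-scanned counterpart
slide = generate_tissue_slide(1024, 1024, n_nuclei=150, seed=1, magnification=10)
scenario = SlideScenario(angle_deg=8, scale=1.02, translation=(30, -18),
                         mpp_ratio=1.05, stain_model="ihc",
                         deformation_amplitude=1.5, seed=2)
moving, ground_truth = derive_moving_slide(slide, scenario)

annotations = generate_annotations(12, "clustered", Rect(300, 300, 400, 400), seed=3)
result = register_pair(slide.pyramid(), moving, annotations, strategy="2", seed=5)
err = colocalization_error(result.points_out.astype(float),
                           ground_truth(annotations), mpp=0.25)
print(f"mean {err['mean_um']:.3f} um  median {err['median_um']:.3f} um  "
      f"max {err['max_um']:.3f} um")
```

Output:

```
mean 0.146 um  median 0.129 um  max 0.323 um
```

Every annotation landed within a third of a micrometer (about 1.3 px at
0.25 mpp) of its exact ground-truth position on the re-stained slide,
despite the 8° rotation, 5 % resolution difference, stain change and
1.5 px local tissue deformation.

The same pipeline is available from the shell:

```bash
wsicoloc synthesize --out pair/ --angle 8 --stain ihc --deformation 1.5
wsicoloc register --fixed pair/fixed.tiff --moving pair/moving.tiff \
    --annotations pair/annotations.csv --strategy auto --out run/
wsicoloc transform run/chain.json more_points.csv --out mapped.csv
wsicoloc evaluate --fixed pair/fixed.tiff --moving pair/moving.tiff \
    --annotations pair/annotations.csv --chain run/chain.json
```

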