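# ecmarch

Quantification of extracellular-matrix (ECM) architecture from scanning
electron micrographs, for labs that decellularize tissue (e.g. xenograft
tumors) and ask how a perturbation changed the matrix: fiber caliber,
porosity, fiber alignment, bulk viscoelasticity, and the accompanying
expression changes.

`ecmarch` implements the full image-analysis chain as a tested library
plus CLI:

- **Segmentation** — trainable per-pixel classification (multiscale
  intensity/gradient/Hessian features, seeded random forest) or
  deterministic thresholding, turning a micrograph into a fiber mask.
- **Fiber diameter** — axial thinning to 1-px centerlines, exact
  Euclidean distance transform (EDT), diameters read off the centerline
  as `2·EDT − 1` px, with removal of centerline pixels near branch
  points where crossing fibers corrupt the EDT.
- **Pore census** — connected clusters of non-fiber pixels fully
  surrounded by fiber; components touching the image border or below a
  minimum size are excluded; per-pore area, perimeter and
  moment-ellipse axes; group comparison by Welch's *t* (Satterthwaite
  df) with Bonferroni correction across metrics.
- **Orientation** — per-pixel structure tensor smoothed in a Gaussian
  window (σ = 7 px); fiber angle = minimal-variation eigendirection,
  coherence = (λ₁−λ₂)/(λ₁+λ₂); angles sampled on centerlines dilated by
  2 px; alignment summarized by the nematic order parameter
  S = |⟨(cos 2θ, sin 2θ)⟩| ∈ [0, 1].
- **Morphometry** — cell circularity c = 4πA/P², aspect ratio from the
  minimum-area rotated bounding rectangle, and calliper tumor volume
  V = 4/3·π·L·S².
- **Rheology** — G′/G″ crossover frequency of an oscillatory sweep by
  log-linear interpolation; lower crossover ⇒ weaker cross-linking.
- **Expression screen** — biotype filter (protein-coding retained),
  Benjamini–Hochberg FDR, up/down calls at fold change > 1.5 / < 0.5
  with adjusted p < 0.05, shared-gene intersection across cell lines;
  duplicate-spot cytokine normalization
  (mean(duplicates) − background)/reference.
- **Synthetic data** — generators for every input (fibrous images with
  von Mises–distributed orientations and exact ground-truth masks,
  elliptical cell outlines, Maxwell-model sweeps, planted-effect gene
  tables, cytokine arrays), so each estimator is validated against
  known truth.

## Worked example

```python
from ecmarch import (fiber_architecture as fa, orientation_analysis as oa,
                     pore_analysis as pa, segmentation as seg,
                     synthetic_data as sd)

spec = sd.FiberImageSpec(image_size=(256, 256), pixel_size=20.0, n_fibers=40,
                         diameter_mean=5.0, diameter_sd=1.0,
                         orientation_mu=30.0, orientation_kappa=8.0,
                         blur_sigma=1.0, noise_sd=0.05, seed=42)
image, truth = sd.generate_fiber_image(spec)

mask = seg.threshold_segment(image, method="fixed", fixed_value=0.5)
skeleton = fa.skeletonize(mask)
diameters = fa.estimate_fiber_diameters(mask, skeleton)
pores = pa.detect_pores(mask, min_size=10)
summary = pa.summarize_porosity(pores, mask)
field = oa.structure_tensor_field(seg.adjust_contrast(image))
angles = oa.centerline_orientations(field, skeleton)
score = oa.alignment_score(angles)
```

prints (via the f-strings in `examples` style usage):

```
fiber diameter: 6.26 px (125 nm) over 2273 centerline px
pores: 31, pore area fraction 0.219
dominant orientation: 28.7 deg, alignment S = 0.97 (n = 11128)
ground truth: porosity 0.516, mean width 5.05 px
```

Reading: the dominant angle recovers the generator's 30° mean within
~1°, and S = 0.97 flags a strongly aligned network (κ = 8).  The mean
diameter (6.3 px) exceeds the per-fiber truth (5.05 px) because at this
density strongly *parallel* fibers overlap into wider ribbons — the
estimator measures the structures actually present in the mask.  The
pore area fraction counts only enclosed, above-threshold pores, so it
is smaller than the total non-fiber fraction (0.516).

The same chain is available from the shell:

```bash
ecmarch simulate --out img.png --kappa 8 --seed 42
ecmarch segment img.png --out mask.png --method fixed --fixed-value 0.5
ecmarch fibers mask.png --out diameters.csv --pixel-size 20
ecmarch pores mask.png --out pores.csv
ecmarch orient img.png --mask mask.png --out orientation.csv
ecmarch run --config pipeline.yaml          # all stages + manifest
```

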