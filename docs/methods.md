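# Methods

This note records the models behind each stage, the conventions and
defaults that matter, and what validation on synthetic data does and
does not establish.

## Coordinates and conventions

Pixel coordinates are (row, col), 0-based, origin top-left, ranges
half-open. Angles are degrees in [−90, 90), 0° along the +x (column)
axis, counter-clockwise positive in mathematical convention (y up);
because image rows grow downward, row-gradients are negated before any
angle is formed. Fibers are undirected, so every angular statistic is
computed on doubled angles and folded back.

## Synthetic fibrous images

The generator emulates secondary-electron micrographs of decellularized
matrix: bright fibers on a dark background, finite beam blur, detector
noise. Fibers are straight constant-width bars crossing the frame; a
pixel is fiber when its perpendicular distance to a centerline is at
most width/2, with centers snapped to pixel rows (half-integer for even
widths) so an axis-aligned bar of integer width w occupies exactly w
rows. Orientations are drawn from a von Mises law on doubled angles
(concentration κ; κ = 0 isotropic, κ ≥ 10⁶ treated as exactly aligned),
respecting the 180° ambiguity of undirected fibers. Intensity is
two-valued (defaults 0.85 fiber / 0.15 background), then Gaussian blur
(σ = 1 px) and additive Gaussian noise (σ = 0.05) are applied and the
result clipped to [0, 1]. Ground truth (per-fiber angle and width, the
binary mask, and porosity as the exact non-fiber pixel fraction) is
recorded *before* blur and noise.

Default scene: 40 fibers of width 5 ± 1 px in a 256 × 256 frame at
20 nm/px — a density at which fibers overlap and cross, as in tissue,
while single-fiber validation scenes use one fiber per frame so truth
is unambiguous. What the generator does **not** model: fiber curvature
and branching, depth layering/occlusion shading, charging artifacts,
non-Gaussian detector noise. Passing tests therefore demonstrate
correctness of the estimator chain on networks of straight fibers with
known truth, not performance on arbitrary real micrographs.

## Segmentation

The trainable route computes per-pixel features — raw intensity plus,
at each scale σ ∈ {1, 2, 4} px, Gaussian-smoothed intensity, Gaussian
gradient magnitude, and the largest Hessian eigenvalue (a ridge
detector, computed from scipy Gaussian-derivative filters, which vanish
on constant images) — and fits a seeded 100-tree random forest to
sparse annotations. Training is deterministic given the seed.

The deterministic route thresholds (Otsu or fixed). Otsu's variance
criterion is biased when the two classes are extremely unbalanced: on a
single-fiber frame (< 5 % fiber pixels) it lands far below the contrast
midpoint and dilates the mask by ~1 px per side. Validation scenes with
known rendered intensities therefore use the fixed midpoint threshold
(0.5); Otsu is the default for images with roughly balanced phases.
Default contrast stretch maps the 1st/99th percentiles to 0/1 (robust
to saturated pixels). Default polarity: fibers bright; a flag inverts.

## Fiber diameters

Centerlines come from topology-preserving axial thinning
(`skimage.morphology.skeletonize`) after dropping fiber components
below 10 px (segmentation noise; the floor is configurable). Branch
points are skeleton pixels with ≥ 3 skeleton neighbors
(8-connectivity). The distance map is the exact Euclidean distance
transform, not a chamfer approximation.

Diameter convention: for a rendered bar of odd pixel thickness t the
centerline EDT is (t + 1)/2, so plain doubling overestimates by 1 px;
diameters are `2·EDT − 1`, which recovers t exactly on noiseless
axis-aligned bars. Oblique digitized bars read up to ~0.5–1 px thin
under this convention (the nearest background pixel center sits beyond
the continuous band edge and the digital skeleton is up to half a pixel
off the continuous centerline); this stays inside the ±1 px validation
window.

Intersection correction: for each branch point b, all centerline pixels
within Euclidean distance EDT(b) of b are removed (ties removed) before
summarizing, because the EDT near a crossing reflects the union of the
crossing fibers. The correction removes crossing contamination; it does
not (and cannot) correct the oblique digitization bias above. Its
validation therefore compares the corrected estimate against the
estimator's *crossing-free reading* of the same fibers (each fiber
rendered alone, estimates pooled): on seeded crossing scenes the
corrected mean is always at least as close to that reference as the
uncorrected mean. Comparing against the rendered truth width instead
would conflate the two effects — crossing inflation partially cancels
the digitization bias, so removing it can move the truth-referenced
mean slightly away from truth while still being the right thing to do.

## Pore census

Pores are 4-connected components of non-fiber pixels (fiber uses
8-connectivity — the standard digital-topology pairing). Components
touching any border are open space, not pores, and are excluded, as are
components below the minimum detectable size (default 10 px²,
configurable; it filters single-pixel segmentation errors). Axes are
the moment-ellipse major/minor lengths; perimeter is the outer-boundary
pixel-edge length with diagonal correction (conventions follow
`skimage.measure.regionprops`; absolute perimeters are
convention-dependent and should only be compared within one pipeline).

Group comparisons use Welch's unequal-variance t with Welch–
Satterthwaite df (implemented by formula so the df is reported;
cross-checked against scipy in tests), appropriate because two
conditions rarely yield equal pore counts or spreads. Raw p-values are
Bonferroni-adjusted across the ≤ 4 requested pore metrics.

## Orientation

Gradients are centered differences after 1-px Gaussian pre-smoothing;
the gradient outer products are smoothed with a Gaussian window of
σ = 7 px (the window parameter is the tensor-averaging scale: larger
windows pool more texture, raising robustness and lowering angular
resolution) and eigen-decomposed in closed form. The dominant
eigendirection of an intensity structure tensor points *across* a
fiber; the reported angle is the perpendicular, minimal-variation
direction, i.e. the physical fiber axis. Coherence (λ₁−λ₂)/(λ₁+λ₂)
is 1 on a perfect grating and decays toward 0 on isotropic texture as
the window grows; energy λ₁+λ₂ separates structured pixels from flat
background (angle is NaN at zero energy).

The centered-difference gradient is slightly anisotropic: on a
period-8 px grating the recovered angle is biased by up to ~1.3° at
oblique orientations (exact at 0°/45°/90°), within the ±2° validation
window. Angles are sampled on centerlines dilated by 2 px, keeping only
pixels with tensor energy above the image median so that background
swept in by dilation does not dilute the sample. Alignment is the
nematic order parameter S = |⟨(cos 2θ, sin 2θ)⟩|; no fixed S cutoff for
"aligned" vs "random" is asserted — the score is reported and cohorts
are compared.

## Morphometry

Circularity uses full-precision π (c = 4πA/P²; 1 for a circle, π/4 for
a square). Polygon area is the shoelace area and perimeter the
vertex-chain length (inputs are polygons, not pixel sets); length and
width are the side lengths of the minimum-area rotated bounding
rectangle — a reproducible operationalization of calliper length/width.
Tumor volume is the modified ellipsoid V = 4/3·π·L·S² with L ≥ S;
swapped inputs are reordered with a warning. Two groups are compared by
unpaired t (equal-variance by default, Welch by flag), more by one-way
ANOVA with Tukey HSD.

## Rheology

The synthetic sweep is a single-mode Maxwell element,
G′ = Gω²τ²/(1+ω²τ²), G″ = Gωτ/(1+ω²τ²), on the instrument grid
0.628–62.8 rad/s (21 log-spaced points); its crossover is exactly at
ω = 1/τ. Optional noise is multiplicative log-normal (keeps moduli
positive). Crossovers are sign changes of log G′ − log G″, refined by
log-linear interpolation (moduli span decades; linear interpolation
would bias the estimate); exact ties report the grid frequency; all
crossings are reported with the first flagged primary, and a sweep with
no crossing reports none rather than extrapolating.

## Expression screen and cytokine arrays

The screen consumes fold changes as given (it does not fit a
differential-expression model). Five non-coding biotypes (lincRNA,
miRNA, 3′ overlapping ncRNA, processed pseudogene, antisense) are
removed; unknown biotypes are retained with a warning rather than
silently dropped. FDR control is Benjamini–Hochberg (via statsmodels;
a hand-written step-up recomputation serves as the test oracle). Calls
use strict inequalities: up iff fold > 1.5 and adjusted p < 0.05, down
iff fold < 0.5 and adjusted p < 0.05; the class labels (up, down,
unchanged, not_significant, excluded_biotype) partition the table.
Cytokine levels are (mean of duplicate spots − background)/reference,
floored at 0 (background exceeding signal is noise); the synthetic
array records the floored formula value as truth.

The synthetic gene table plants n_up/n_down effects among
protein-coding genes only, with fold changes at or beyond the effect
fold and raw p in [10⁻⁸, 10⁻⁴]; nulls are log-normal folds (σ = 0.2)
with uniform p. At the default conditions (2,000 genes, 50 + 50 planted,
effect fold 3) recovery is essentially perfect; the screen's behavior
near the 1.5/0.5 boundaries is exercised by dedicated boundary tests,
not by the planted cohort.

## Pipeline and problem sizes

The `run` pipeline chains contrast → segmentation → skeleton/diameter →
pores → orientation and writes a manifest (package version, config
hash, seed, per-stage outputs); deterministic stages are bitwise
reproducible, and the test suite asserts this end to end. Validation
problem sizes — 128–256 px frames, 3-seed cohorts, 20-image pore
cohorts, 2,000-gene tables, 50 oracle masks ≤ 40×40 — were chosen so
ground-truth recovery is unambiguous while the whole suite and the
acceptance script each run in seconds.

## Known limitations

- Straight-bar scenes cannot probe curvature-induced diameter or
  orientation error; real matrix fibers curve and branch.
- Equivalence with any specific interactive segmentation tool's masks
  is not claimed (feature menus and hyperparameters differ).
- Per-fiber instance tracing across crossings is out of scope; diameter
  statistics are per-centerline-pixel, not per-fiber.
- Absolute pore perimeters depend on the boundary convention; compare
  only within one pipeline.
- The alignment score has no universal "aligned" threshold; interpret
  relative to matched controls.
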