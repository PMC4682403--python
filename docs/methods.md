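# Methods

This note records the modelling choices behind `copepodid`: what each
stage computes, the conventions that had to be fixed where the
classical toolboxes disagree, what the synthetic data generator does
and does not emulate, and the known limitations.

## Image model and pre-processing

Images are handled internally as float64 intensity grids in [0, 1],
row-major with the origin at the top-left, regardless of source bit
depth; RGB input collapses to luminance with BT.601 weights normalised
to sum exactly to one (so neutral gray is preserved bit-for-bit). The
grayscale conversion formula is a convention of this package — any
fixed luminance weighting would serve.

Noise suppression is a 10×10 median filter; edge detection is the
local range (window maximum minus minimum) over the same 10×10 domain.
Two conventions are fixed here:

* **Even-window anchoring.** A k×k window at output pixel (r, c)
  spans rows r−k//2 … r+k−k//2−1 (for k = 10: r−5 … r+4), the
  floor-centred convention of `scipy.ndimage` at origin 0.
* **Padding.** Replicate (edge-value) padding by default. Zero padding
  is available but manufactures a dark frame around the image that the
  range filter then reports as an edge; replicate padding avoids this
  artefact, at the cost of a (documented, tested) deviation from
  toolboxes that zero-pad by default.

## Segmentation

The edge map is binarised with Otsu's threshold (between-class
variance maximisation over a 256-bin histogram; a fixed threshold can
be supplied instead), then cleaned: components touching the border are
removed, holes are filled (with complementary connectivity: 8-connected
foreground implies 4-connected background), and components below
`min_area` are removed using a strict `< min_area` rule, so a component
of exactly the cutoff size survives. Foreground connectivity is
8-connected throughout. If several components survive, the largest is
kept with a warning — scenes are assumed to contain one specimen.

**Halo compensation.** A local-range edge detector with a k×k window
responds at every pixel whose window straddles the body boundary, so
the filled edge mask is exactly the true silhouette dilated by the
window's reflected support. The pipeline therefore erodes with the
same window (reflected anchoring) after hole filling. For convex
boundary stretches this inverts the dilation exactly; in general it
yields the morphological closing of the silhouette. Without this step
the recovered area would be biased upward by roughly half the window
size all around the boundary — immaterial at full micrograph scale,
but a double-digit relative error on desk-scale test images. The
binarise-the-edge-map route (rather than thresholding the
median-filtered grayscale directly) was chosen because it is robust to
absolute illumination level; the grayscale route is reachable by
passing the median-filtered image straight to `binarize`.

**Orientation.** The region's orientation is the angle of the major
axis of the ellipse with the same second moments as the pixel set,
measured against the x-axis with y pointing up, in (−90°, 90°]. The
normalised central moments carry a +1/12 per-pixel variance correction
(the variance of a unit square), which makes a single-pixel region
well-defined and matches the regionprops convention. The specimen is
rotated by (90° − orientation) about its centroid with canvas
expansion — nearest-neighbour for the mask (preserves binarity),
bilinear for the grayscale — then tightly cropped. Orientation is an
axial quantity: a rotated mask re-measuring at −89.9° is 0.2° from
vertical, not 179.8°, and tests use the axial difference.

## Shape features

Eleven descriptors per specimen. Conventions that needed fixing:

* **Perimeter**: length of the 8-connected outer boundary polygon from
  Moore neighbour tracing, diagonal steps counting √2. This
  overestimates smooth contours by ~5% (a known property of the chain
  estimator) but is exactly reproducible and oracle-testable. A
  single-pixel region has perimeter 0.
* **Convex area**: hull over pixel-corner coordinates, rasterised by
  pixel-centre inclusion.
* **Axis lengths**: 4·√(eigenvalue) of the corrected second-moment
  matrix, so a rasterised ellipse with semi-axes (a, b) measures
  (2a, 2b).
* **Anterior-up flip**: the posterior end is not annotated, so the
  bounding-box half with the greater pixel mass is declared anterior
  (the copepod prosome is bulkier than the urosome) and flipped to the
  top; for odd heights the middle row belongs to neither half, and an
  exact tie means no flip.
* **Lower-ROI percentage**: with the tight crop anterior-up and
  bounding-box height H, the lower band is the bottom ⌈ratio·H⌉ rows
  (boundary row assigned to the band), and the feature is 100·q/p with
  q the band's true pixels and p all true pixels. The default ratio
  0.60 is kept as the established choice for this feature; the ratio
  is exposed as a parameter but no attempt is made here to re-derive
  the best value. The feature is invariant to horizontal mirroring and
  canvas padding, monotone non-decreasing in the ratio, and reaches
  100 as ratio → 1.
* The **orientation feature** records the pre-rotation pose: after
  normalisation every specimen sits at 90°, so the post-rotation value
  carries no information (and the selector duly discards it).

## Feature selection

Forward stepwise discriminant analysis. Wilks' Λ for a column subset
is det(W)/det(T) with W the pooled within-group SSCP and T the total
SSCP; the F-to-enter of a candidate given p entered features is
F = ((n−g−p)/(g−1))·(1−Λp)/Λp with Λp the partial Λ, which is
F(g−1, n−g−p)-distributed under the null of no added discrimination
(verified by simulation in the tests). Selection is purely forward —
no backward elimination pass — with entry threshold 3.84 (the 5%
χ²₁ heuristic; the threshold is configurable because the classical
packages do not agree on a default), deterministic name-order
tie-breaking, and an exactly-collinear candidate short-circuits to
F = 0 rather than erroring. The final model takes the top k (default
7) entered features ranked by F at entry. Λ is monotone non-increasing
along the path and invariant to affine rescaling of any column; both
are asserted as properties.

## Network and training

Architecture: n_inputs → 10 logistic hidden units → one logistic
output per class, trained on mean squared error against hard 0/1
one-hot targets (no softmax/cross-entropy variant, and no target
softening — the MSE-on-sigmoid design is deliberate). Inputs are
min-max normalised to [−1, 1] using bounds from the training partition
only; unseen values clip at ±1.2 after mapping so outliers cannot
drive the sigmoids far into saturation. Weights initialise uniformly
in [−0.5, 0.5] scaled by 1/√fan-in, from a seeded generator.

The optimiser is Møller's scaled conjugate gradient with σ = 1e−4 and
initial λ = 1e−6, full-batch gradients, and a periodic
steepest-descent restart every n_params iterations. Early stopping
tracks validation MSE every accepted epoch and stops after 6 epochs
without a new validation minimum (a patience parameter — "stops when
validation error starts to rise" needs one to be meaningful); the
returned weights are those of the best-validation epoch, never a later
one. Training restarts 5 times from derived seeds and the restart with
the lowest validation MSE wins; all restarts are logged in the
training record. A NaN loss rejects the step (the λ safeguard then
grows) rather than propagating.

The 70/15/15 split computes global validation and test sizes as
round(fraction·n) with the remainder to training (240 → 168/36/36),
then meets those totals per class by largest-remainder allocation,
assigning leftover validation slots to the first classes in label
order and leftover test slots to the last, so no class is shorted on
training twice. Splitting a class of fewer than 3 samples is refused.

Reported percentages are computed on exact integer ratios and rounded
half-away-from-zero to 2 decimals (149/160 → 93.13), avoiding
float-representation artefacts. The genus collapse sums species rows
and columns into genera (order of first appearance) and recomputes
accuracies; it conserves the total count, and genus-level overall
accuracy can never be below species-level (within-genus confusions
land on the genus diagonal).

## Synthetic data

The generator emulates the situation the pipeline is built for: one
large dark body (~0.25 intensity) on a light background (~0.85), salt
and pepper noise (rate 0.002), and a few small distractor particles,
rendered on a 612×480 canvas — a quarter of the 2448×1920 micrograph
frame linearly, with the minimum-area cutoff scaled by the same factor
squared (50 000/16 ≈ 3125 px²). A silhouette is a prosome ellipse plus
a tapered urosome trapezoid (posterior/anterior width ratio 0.80) plus
two splayed caudal rami blades, placed at uniform random pose.
Per-class shape parameters are drawn from 3σ-truncated normals; every
(class, role, index) triple has its own derived random stream, so
datasets are reproducible and individual specimens independent of how
many others are generated.

The 8 default classes mirror the taxonomic structure of a mangrove
copepod assemblage: two large distinctive species (As, Bs), two
within-genus look-alike pairs (Od/Os and Tb/Tf, separated mainly by
body length), and one cross-genus pair (Os/Pc) that overlaps in body
size and differs chiefly in prosome/urosome proportions — hence in the
lower-ROI feature, which is what that feature exists to resolve. Class
parameters were designed against two self-tests: every pair of classes
differs in at least 2 of the 5 shape parameters by ≥ 2 pooled SD, and,
on extracted features, every pair differs in at least 2 of the 7
candidate descriptors by ≥ 2 pooled SD. Urosome width grades inversely
with prosome fraction across classes; this keeps the lower-ROI
percentage monotone in the urosome's share of the body within the
parameter range used (the band-partition geometry makes the feature
non-monotone in prosome fraction globally, because a sufficiently long
prosome ellipse reaches deep into the posterior band).

What the generator does **not** emulate: optical blur and focus
gradients, uneven illumination, appendages (antennae are deliberately
absent — in practice they are removed before imaging because arbitrary
antenna poses corrupt the shape features), touching or overlapping
specimens, and intra-specimen texture. Passing the end-to-end tests
therefore demonstrates that the pipeline's stages compose correctly
and that shape-based discrimination works under the stated geometry
and noise model — not that the stated accuracy transfers to real
micrographs.

## Problem sizes and numerics

The end-to-end study uses 8 classes × (30 training + 20 test) images —
400 micrographs per seed — and the test-suite runs it for three master
seeds; feature extraction (dominated by the 10×10 median filter) takes
about a minute and a half per seed on one core. Degenerate inputs have
defined behaviour throughout: a constant image has no Otsu threshold
("degenerate histogram"), an empty mask raises "no region" / "no
specimen found", a single-pixel region has a well-defined orientation
and zero perimeter, and duplicate feature columns yield F = 0 rather
than a singular-matrix error.

## Limitations

* Selection is greedy forward only; a feature pair jointly informative
  but individually weak can be missed.
* The perimeter and convex-hull conventions are internally consistent
  and tested, but other toolboxes will produce slightly different
  absolute values for the same mask.
* The published headline accuracies of the original 8-species study
  can be recomputed from its printed confusion tables (and are, in
  `scripts/acceptance.py`), but the image-level experiment cannot be
  reproduced because the micrograph collection was never deposited;
  the synthetic study replicates the experimental design, not the
  images.
* One specimen per scene is assumed; no watershed splitting of
  touching objects.
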