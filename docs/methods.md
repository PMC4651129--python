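# Methods

`tmascore` re-creates, on fully synthetic data, a comparison study design
from diagnostic digital pathology: how much do automated tumour
segmentations of breast tissue-microarray (TMA) spots differ from
pathologists' hand-drawn ones, and does that difference matter for the
oestrogen-receptor (ER) immunohistochemistry (IHC) scores computed inside
the segmented tumour regions?  This note records the models, the parameter
choices and their rationale, the places where the design was genuinely
open, and the limits of what the synthetic experiments demonstrate.

## The synthetic spot generator

A TMA spot is a circular tissue core imaged in RGB.  The generator emulates
one ER-stained spot per seed:

* **Geometry.** The validity region is the disc inscribed in a
  `diameter_px` square; everything outside is OUTSIDE and excluded from all
  statistics.  Library defaults mirror ×40-equivalent scanning
  (`diameter_px=3000`, `pixel_size_um=0.25`); the test suite and the
  bundled study run at `diameter_px=600`, `pixel_size_um=1.0` — a 0.6 mm
  core at reduced resolution — which keeps a full study affordable on one
  CPU while preserving physical densities and cell sizes.  All sizes are
  specified in micrometres, so the pipeline is scale-invariant by
  construction.
* **Compartments.** Smooth seeded Gaussian random fields are thresholded at
  exact quantiles to carve the disc into `n_tumour_regions` irregular
  tumour regions covering `tumour_fraction` of the spot (default 0.30),
  lymphocyte fields (10%), normal epithelium (10%) and stroma (the rest).
  Quantile thresholding makes the realised tumour fraction match the
  programmed one almost exactly.
* **Nuclei.** Placed by seeded dart throwing per compartment at realistic
  densities (tumour 3000/mm², normal epithelium 2000/mm², lymphocyte fields
  8000/mm², scattered stromal cells 800/mm²) with a minimum separation of
  2.2 nuclear radii, so nuclei are well separated and the detector's
  watershed split is exercised but not overwhelmed.  Radii are conventional
  values (tumour 5 µm, normal 4 µm, lymphocyte/stromal 3 µm) exposed as
  configuration, not derived from any measurement.  The candidate list is
  the retry budget: an infeasible density raises an error naming the
  compartment.
* **Staining.** The forward model is Beer–Lambert in optical density (OD):
  each nucleus adds an elliptical kernel (flat core, linear taper over the
  outer 15% of the radius) normalised to unit mean over its support, so the
  kernel scaled by a target OD has exactly that mean OD.  Negative nuclei
  get haematoxylin (mean OD 0.70); ER-positive tumour nuclei get DAB at the
  midpoint of the programmed intensity bin (0.275 / 0.55 / 0.95 for bins
  1–3) over a reduced haematoxylin counterstain (0.35).  Overlaps sum in
  OD, keeping the forward model linear and exactly invertible by colour
  deconvolution.  Exactly `round(pct/100 * n_tumour)` tumour nuclei are
  positive; non-tumour nuclei are always ER-negative (a simplification —
  real normal epithelium can express ER).
* **Background.** A low-amplitude smooth texture (haematoxylin OD ≤ 0.04
  plus a pinkish RGB tint) gives stroma non-degenerate statistics, and
  epithelium-bearing compartments receive a small extra background
  absorbance (tumour +0.10, normal epithelium +0.08, lymphocyte fields
  +0.05 OD, edge-smoothed at σ=1.5 px).  This mirrors the fact that
  confluent epithelium is visibly darker than collagenous stroma even
  between nuclei, and it is what gives region boundaries a real image edge
  for superpixels to adhere to.
* **Noise and determinism.** Gaussian RGB noise (σ = 2 counts by default)
  is added before 8-bit quantisation; OUTSIDE pixels carry the clean
  background sentinel.  One `numpy` Generator seeded per spot drives
  everything; identical configurations are bit-identical.

What the generator does **not** emulate: tissue folds, out-of-focus blur,
scanner compression, stain variation between slides, nuclear pleomorphism,
overlapping/clustered nuclei, or ER-positive normal epithelium.  Passing
tests therefore demonstrate internal correctness and robustness of the
pipeline under controlled conditions, not clinical performance.

### Simulated annotators

`perturb_mask` fabricates annotator variation from the ground truth:
boundary jitter (a smooth random displacement field, clipped so no boundary
moves more than `magnitude_px`; designed to yield thin Type 1
disagreements), whole-component dilation/erosion (extent disagreements,
Type 2) and whole-component addition/deletion (presence/absence, Type 3).
In the bundled study, "annotator A" is ground truth + 3 px jitter;
"annotator B" additionally receives a region resize or an added component
on every third spot, so inter-annotator differences exhibit all three
types.  Study-level component flips only *add* components: deleting a
component can remove an entire merged tumour region, which is a far larger
perturbation than the inter-annotator variation being modelled.

## Stain separation and the open IHC scorer

Colour deconvolution uses the published Ruifrok–Johnston haematoxylin and
DAB OD triplets (normalised), completed by their cross product as the
residual channel, and inverts the 3×3 basis exactly per pixel.  Negative
projections are clipped to zero (the clipped mass is logged); zero-valued
pixels are clamped to one count before the log.  Rendering followed by
deconvolution recovers programmed ODs to within ≈0.02 OD over the
generator's working range; at much higher combined densities 8-bit
quantisation dominates the residual.

The nuclear scorer is an open stand-in for commercial nuclear IHC
algorithms, whose internals are proprietary:

1. candidate raster = Gaussian-smoothed (haem + DAB) OD, thresholded at
   0.30 OD;
2. touching blobs split by watershed on the Euclidean distance transform,
   seeded at its local maxima;
3. components kept only if their centroid lies on a tumour (T) pixel and
   their area is inside configured bounds;
4. per-nucleus stain means are taken over the **eroded core** of each
   component — the watershed boundary includes partial-volume rim pixels
   that would otherwise dilute the nuclear OD by 20–30% and bias intensity
   bins downward;
5. intensity bins 0–3 at mean DAB OD thresholds (0.15, 0.40, 0.70) —
   calibration constants of this scorer, not measured values; the generator
   programs nuclei at bin midpoints precisely so that round-trips do not
   sit on a threshold;
6. spot intensity = bin of the mean DAB OD over positive nuclei (a modal
   alternative is available); percent positive is per-nucleus, not
   per-pixel.

Allred (intensity 0–3 + proportion 0–5; positive if total > 2, the 1%
rule) and Quickscore (intensity 0–3 + proportion 1–6; positive if
total > 3) use the standard published proportion bins, half-open
`[lower, upper)` with the top bin closed.  A spot with zero detected nuclei
scores all-zero (Quickscore proportion 1 by construction) with a logged
warning.

## Superpixel tumour segmentation

SLIC k-means superpixels (target edge length 16 px, compactness 5 — chosen
for boundary adherence on this imagery; both exposed in configuration) are
described by: mean/sd of R, G, B and of deconvolved haem/DAB OD; mean/sd of
a small Gaussian-derivative filter bank (gradient magnitude and Laplacian
at σ = 1, 2, 4 µm, converted to pixels via the image's pixel size); area,
eccentricity and solidity; and the mean colour/texture of the adjacent
superpixels on the region-adjacency graph.  Training labels are the
majority {N, T} label of each superpixel's pixels under the annotator's
mask; exact 50/50 ties go to N, and prediction calls T only above score
0.5 — both tie-breaks deliberately conservative, never over-calling
tumour.  The classifier is a random forest (200 trees, min leaf 2, fixed
seed): robust to mixed feature scales with little tuning.  Evaluation uses
spot-level k-fold cross-validation (seeded shuffle, contiguous blocks);
no superpixel of a test spot ever enters its model's training table.  An
optional minimum-component-area filter is available but off by default.

## Disagreement taxonomy

Two comparable masks (same shape, same OUTSIDE set) yield a 2×2 in-spot
contingency table over {(T,T),(T,N),(N,T),(N,N)}.  Disagreement pixels are
classified in fixed order:

1. **Type 1** — removed by morphological opening of the disagreement
   raster with a disc of one minimum epithelial cell diameter (default
   8 µm, converted to pixels and recorded in the map): strips too thin to
   contain a cell.
2. **Type 2** — remaining pixels whose own-mask 8-connected T component
   overlaps (≥ 1 shared pixel) the other mask's T raster: extent
   disagreements about a tumour region both masks contain.
3. **Type 3** — everything else: presence/absence disagreements.

The structuring element is an octagonal disc approximation built as an
alternating cross/square dilation chain.  A pixel-grid Euclidean disc
family is *not* nested across diameters, which would let the Type 1 set
occasionally shrink as the assumed cell diameter grows; the dilation-chain
family is nested by construction, making Type 1 monotone in the cell
diameter.  One consequence of the opening rule worth knowing: an isolated
square disagreement region keeps its rounded core after opening (Type 3)
while its sharp corners are removed (Type 1) — the taxonomy is exactly the
operational rule, not a per-region vote.  The test suite holds the
implementation equal, pixel for pixel, to a brute-force implementation of
the three rules built from shift-based morphology and BFS components.

Cohort summaries average per-spot type proportions (unweighted mean ± sd
over spots); spots with zero disagreement are excluded from the average
and counted.  Difference images colour Type 1 red, Type 2 green, Type 3
blue, agreement neutral (or the underlying image), OUTSIDE black.

## Agreement statistics

Pixel-level agreement is reported both as observed agreement (diagonal
mass of the normalised contingency table) and Cohen's chance-corrected κ.
In the study design this package reproduces, the quoted pixel-level
"kappa" figures numerically equal the *observed agreement* of the printed
tables, not the chance-corrected statistic (0.787 for a table whose
diagonal sums to 0.908); both are always reported side by side rather than
deciding which was intended.

Ordinal score agreement uses the two-rater quadratic-weighted kappa
(Fleiss–Cohen weights `((i−j)/(k−1))²`; linear weights available), the
standard reading of a "weighted kappa-squared" statistic; for two
categories it reduces exactly to unweighted Cohen's κ.  Confusions are
built over the full category range (intensity 0–3, Allred totals 0–8,
Quickscore totals 1–9) even when categories are unobserved, so weights and
expectations are well defined across cohorts.  Undefined cases (both
raters constant, degenerate marginals) return NaN with a logged warning
rather than raising, keeping cohort tables rectangular.  Bland–Altman
analysis of percent positive reports bias and 95% limits of agreement
(bias ± 1.96 × sample sd of source1 − source2).

## The bundled study

`run_study` generates a cohort whose programmed (percent positive,
intensity bin) pairs cycle through (0,0), (0.5,1), (5,2), (25,3), (50,2),
(90,3), (10,1), (70,3) — spanning ER-negative through strongly positive
spots and all intensity bins — simulates both annotators, cross-validates
the segmenter trained on each, and emits: per-pair mean normalised
contingency tables, disagreement-type summaries, per-source IHC scores,
quadratic-weighted-kappa matrices, ER-status concordance per cut-off, and
Bland–Altman tables.  The default study and `scripts/acceptance.py` use 16
spots with 8-fold CV (fold size 2) at the 600 px test scale.  Everything
derives from one seed through per-stage `SeedSequence` spawning; reruns
are byte-identical.

## Numerical and degenerate-input choices

* Exact quantile thresholding with deterministic tie trimming for region
  fractions; ties in majority labels and classifier scores go to N.
* Boundary jitter flips a pixel only if its distance to the T/N boundary
  is below the displacement field, which is clipped at `magnitude_px` —
  the spatial bound is exact, not statistical.
* Masks with no T pixels: jitter is the identity; resize/delete raise.
* Empty tumour regions score zero nuclei, not an error; empty contingency
  tables raise.
* All file round-trips (PNG masks with the 0/1/2 encoding, score CSVs)
  are bit-exact; unknown mask values are rejected with the offending
  values listed.

## Known limitations

* Synthetic appearance is far simpler than real histology; the reported
  CV agreements (≈0.96 at the test scale) should be read as an upper bound
  of what the architecture achieves when tumour differs visibly from
  stroma, not as expected clinical accuracy.
* The scorer's intensity thresholds and aggregation are calibration
  constants of this open implementation; absolute intensity bins are not
  comparable to any commercial scorer's output.
* The Type 1 rule is one documented operationalisation of "too thin to
  contain a cell"; the cell diameter is a parameter recorded in every
  disagreement map, and conclusions can be checked for sensitivity to it.
* Kappa confidence intervals and multi-rater (> 2) generalisations are out
  of scope.
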