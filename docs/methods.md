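# Methods

## Problem and pipeline

The package quantifies the trophic state of fish intestinal mucosa
from two kinds of micrographs: immunostained sections (PCNA for
proliferation, TUNEL for apoptosis, DAB brown chromogen with
haematoxylin counterstain) and H&E sections from which the one-pixel
outline of the mucosal fold interface is traced. Three measurements
are produced per field/section: the PCNA index, the apoptotic index,
and the box-counting fractal dimension (FD) of the interface, followed
by group comparisons and regressions.

## Colour segmentation

Each pixel of a field is assigned to the nearest of four reference
colours — DAB-positive nucleus, haematoxylin-negative nucleus,
enterocyte cytoplasm, white background — chosen by the operator
(`ClassPalette`). Distances are computed in CIELAB under D65 by
default: raw-RGB distance conflates luminance with the brown/blue hue
contrast that actually separates DAB from haematoxylin, while Lab
spreads the four anchors more evenly; plain-RGB distance remains
available (`color_space="rgb"`). Ties resolve to the earliest class in
the fixed order positive, negative, cytoplasm, background, so
classification is fully deterministic. No spatial regularisation is
applied by default; a minimum-blob filter (`min_blob_size`, default
off) can reassign speckle in the nucleus classes to each pixel's
second-nearest colour.

Lamina propria (whose stromal and immune cells would contaminate the
enterocyte counts) is excluded by a binary mask file (0 = keep,
255 = exclude) rather than by interactive erasure; masked pixels are
flagged, never recoloured, and all area percentages are computed over
non-excluded pixels only.

## Indices

With `%pos` and `%neg` the nuclear area percentages of a field,

* PCNA index = 100·%pos/(%pos+%neg) — the area-weighted proliferative
  fraction of the epithelial nuclei;
* n_neg = field_area·(%neg/100)/mean_nucleus_area — a stereological
  conversion of area share into a (real-valued) nucleus count. It is
  invariant under any common rescaling of the two areas, so px² and
  µm² are both acceptable as long as they match;
* apoptotic index = 100·n_apo/(n_neg+n_apo).

`mean_nucleus_area` is a per-staining-batch calibration constant;
`estimate_mean_nucleus_area` averages connected-component areas of the
negative class on calibration fields (components below 5 px² are
treated as colour-noise speckle). Apoptotic events are counted from
operator annotation CSVs (field_id, x, y; 0-based, origin top-left);
points inside the exclusion mask are rejected and reported. An
automatic small-blob counter exists for closing the loop against the
synthetic generator only — it is not suitable for real TUNEL slides,
whose nonspecific cytoplasmic signal is the reason counting is manual
in the first place. Indices are stored unrounded; rounding is a
display concern.

## Outline extraction

The mucosal interface is extracted from a tissue image or mask as:
threshold (manual grey level by default, mirroring the blinded manual
operation; Otsu's histogram criterion as the automatic fallback) →
fill holes below `min_hole_area` (default 256 px²) → keep the largest
8-connected component (warning when it holds < 90% of the foreground)
→ boundary = tissue pixels with at least one lumen 4-neighbour →
thinning. Canvas-border pixels are treated as interior tissue, so the
image frame is never traced and the curve is the luminal interface
only. Thinning is applied *conditionally*: a raster already free of
solid 2×2 blocks is one pixel wide and is left untouched. This
preserves exact counting identities (the boundary of a filled n×n
square has exactly 4n−4 pixels; unconditional thinning would shave the
four corners, which are 8-simple) while staircase boundaries of curved
shapes still get thinned.

## Box-counting dimension

`box_count` overlays a single fixed grid of boxes of edge s for every
s in the ladder 2, 3, 4, 6, 8, 12, 16, 32, 64, 128, 256, 512, 1024,
2048 px and counts boxes containing at least one curve pixel; partial
boxes at the far edges count. `estimate_fd` fits ln N(s) on ln(1/s) by
unweighted OLS; the slope is the FD, with the intercept and r² kept as
fit diagnostics. Natural logs (the slope is base-invariant).

Numerical choices:

* **Grid anchor.** The grid is anchored at the top-left corner of the
  curve's bounding box, not the image corner. Anchoring at the object
  makes the counts — and hence the FD — exactly invariant under
  translation of the outline within the canvas; with an image-corner
  anchor, the grid phase at the coarsest scales moves the estimate by
  up to ~0.1 for the same curve. An optional tight-covering mode
  (`n_offsets > 1`, minimum count over a lattice of sub-box offsets)
  is provided but off by default.
* **Trimming.** Two classes of ladder points carry no scaling
  information and are dropped before the fit: saturated sizes (N = 1)
  beyond the first one, and sizes where the curve occupies fewer than
  4 boxes (applied only when ≥ 3 points remain). Coarse near-empty
  scales measure grid phase rather than the curve, and for closed
  curves they approach plane-filling (any curve spanning a 2×2 coarse
  grid occupies all 4 boxes), which biases the slope upward. With both
  rules the closed-form anchors agree simultaneously: rasterized
  straight line 1.0001, iteration-6 Koch within 0.05 of log4/log3,
  circle outline within 0.01 of 1, and the translation/rotation/scale
  robustness checks in the test suite.
* Sizes exceeding the curve extent are still *evaluated* (the counts
  table reports the full ladder); the trimming rules then remove them
  from the fit.
* At least 3 usable sizes and 2 distinct counts are required;
  otherwise the input is degenerate (e.g. a single pixel) and an error
  is raised rather than a number invented.

The ladder above reads the published size list's "1216" as the
typographic fusion of the two sizes 12 and 16, the only reading under
which the list is monotone.

## Statistics

Each variable is gated once, over the pooled sample, by Shapiro–Wilk
at α = 0.05 (one gate per variable, matching how such workflows report
a single W per measure). Normal variables: one-way ANOVA F with
Fisher-LSD pairwise t-tests on the pooled within-group MSE. Non-normal
variables: tie-corrected Kruskal–Wallis H on midranks with Dunn-type
pairwise z-tests (unadjusted by default; Bonferroni/Holm switches
provided — the precise flavour of "Kruskal–Wallis multiple comparison"
is a documented choice, not an asserted fact). Pairwise outcomes are
rendered as a compact letter display via the insert-and-absorb
algorithm, so groups sharing no letter differ at p < 0.05.

The post-hoc is *protected*: letters split only when the omnibus test
itself rejects at 0.05. Unprotected pairwise letters at 0.05 would
split the display in roughly a fifth of null datasets (six pairwise
tests among four groups), destroying the workflow's type-I
calibration; with protection the family-wise false-split rate equals
the omnibus level, and the measured null rejection rate is 4–5% at
the study's 4 × 27 design.

Simple regression reports the standardized slope (equal to the Pearson
correlation for one predictor) and the two-sided t-test p-value of the
raw slope.

## Synthetic data

`generate_ihc_field` renders an elliptical fold cross-section: white
lumen background, a cytoplasm annulus carrying non-overlapping
elliptical nuclei (rejection-sampled; overlap disallowed so counts are
unambiguous; an explicit packing error if requests exceed ~60% of the
epithelial band), and a lamina-propria core recorded in the exclusion
mask and seeded with distractor nuclei that must never reach the
counts. Apoptotic events are 1–3 small brown fragments each — distinct
from whole-nucleus PCNA-like staining — with centres exported as
annotation points. The per-pixel class map is stored losslessly before
Gaussian RGB noise (σ = 8 by default, clipped to [0, 255]) is applied,
so the reported area fractions are an exact census of the render, and
`mean_nucleus_area` is the realized mean area of the negative
epithelial nuclei. Identical parameters and seed give byte-identical
images.

Defaults are desk-scale choices, not calibrated claims: 512×512 px
canvas (test suites use 256–384 px), nucleus semi-axes uniform in
3.5–7 px, ~180 epithelial nuclei per field. Real slides differ in ways
the generator does not emulate — stain intensity gradients, chromatin
texture, overlapping and sectioned nuclei, out-of-focus regions,
uneven illumination — so passing recovery tests demonstrates that the
pipeline arithmetic and classification logic are correct under
controlled noise, not that segmentation accuracy on real material is
guaranteed.

`generate_outline` produces one-pixel 8-connected curves: straight
line, circle, triadic Koch (similarity dimension log4/log3 ≈ 1.2619)
and quadric Koch (log8/log4 = 1.5) via L-system turtles rasterized as
polylines, and `fold_curve` — a midpoint-displacement perturbation
(Hurst-like decay 0.55) of a gentle sine baseline (amplitude 0.06·h),
whose displacement scale is proportional to the `roughness` knob, so
mean contour complexity rises monotonically with roughness. Fractal
generators validate that the smallest segment stays ≥ 1 px on the
requested canvas and raise otherwise. Reference canvases used in the
validation suites: 2048×2048 for the line, 2187×1024 for the
iteration-6 Koch (3-px smallest segment), 1025×1025 for the
iteration-3 quadric Koch, 1024×1024 for fold curves.

## Study runner

`mucofract simulate` emits a complete synthetic study — by default 36
fields (one per sampled animal, 9 per diet group MM0/MM25/MM50/MM75
with intestinal segments cycled), each with an IHC image, exclusion
mask, annotation CSV, fold outline, and sidecar truth table, plus a
manifest and a config echo with the package version. The built-in
diet gradients (proliferative fraction and fold roughness declining
with mussel-meal inclusion) can be switched off (`--null`) for
calibration runs. `mucofract study` validates the manifest up front
(missing files are listed and the run aborts before computing
anything), then writes per-field indices, per-outline FD with
box-count sidecars, comparison tables with letters, regression tables,
and a plain-text report. Re-running on identical inputs yields
byte-identical CSVs.

## Known limitations

* Nearest-colour classification has no notion of stain mixing; heavily
  counterstained DAB nuclei can split between the two nucleus classes.
  Stain deconvolution is deliberately out of scope.
* The stereological count conversion assumes the calibration
  `mean_nucleus_area` matches the field's true mean; a biased
  calibration biases n_neg and hence the apoptotic index
  proportionally.
* FD estimates on curves whose extent spans few ladder sizes rest on
  a short log-log range; r² is reported so short-range fits can be
  screened.
* The comparison workflow treats fields as independent observations
  (as the study design it mirrors did); tank/fish nesting is not
  modelled.
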