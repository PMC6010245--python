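# Methods

This note records the model, the tunable parameters, the synthetic-data
design and the numerical choices behind `shgfib`, including the places
where the published description of SHG-based fibrosis staging leaves the
design open and this package had to decide.

## Imaging model and geometry

A tile is a pair of co-registered 512×512 intensity grids covering
200×200 μm, i.e. a pixel pitch of 200/512 ≈ 0.3906 μm. Tiles are grouped
into 5×5 multi-tile fields (1 mm²); sampling ten fields per specimen
gives the standard 10 mm² analysis area. All areas are reported in μm²
via pixel_size², lengths in μm; pixel coordinates are 0-based row-major.

## Preprocessing

*Noise removal* is a 3×3 median filter followed by subtraction of the
modal background intensity, clipped at zero. The background mode is
estimated over the lowest quarter of the intensity range only, so the
bright tissue mode of the TPEF channel is never subtracted. The source
method names no filter; a median was chosen because it removes
single-pixel speckle without eroding strings wider than one pixel. The
operation is idempotent only up to the median filter's boundary
behaviour: a second pass leaves piecewise-constant content unchanged
except for residual rounding at object corners (tested as
almost-everywhere equality), and on raw noise fields a median is not a
projection at all.

*Collagen segmentation* uses Otsu's threshold on a 256-bin histogram
spanning `[min, max]` of the (noise-removed) SHG channel. Binning over
the observed range makes the mask exactly invariant under a constant
intensity offset. Ties in the between-class variance are broken toward
the lower threshold — deterministic and inclusive of faint collagen. The
returned threshold is the upper edge of the best split bin and the mask
is strictly-greater-than. Whether the original analysis thresholded per
tile, per field or per specimen is unstated; the implementation
thresholds whatever array it is given, and the pipeline applies it per
tile.

## Region segmentation

Holes are dark connected components (8-connectivity) fully inside the
tissue, at least 10 μm² in area; components touching the field border
are discarded because their truncated shape features are biased. Each
hole carries five features: density, width and length (minor/major axis
of the best-fit ellipse), solidity, and the collagen area in a
surrounding annulus. "Density of hole" is not defined in the source
description; neighbour-count-within-a-radius (default 100 μm) is adopted
and flagged as an interpretation. The surrounding-collagen annulus is
15 μm.

The two classifiers are CARTs (Gini impurity, maximum depth 4, minimum
leaf size 5, fixed seed) trained on synthetic ground truth, because the
original trees were never published: this reproduces the *method*, not
its unpublished parameters. The fitted trees ship as JSON fixtures and
`scripts/train_default_carts.py` regenerates them (the shipped fixtures
were fitted on ten tiles per stage; ~98% hole training accuracy, 100%
structure training accuracy). Prediction traverses the serialised node arrays with feature
lookup by name, so records may present features in any order.

Structures are single-linkage groups of vessel-type holes: two holes
link when their centroids are within 50 μm, or when one contiguous
collagen component touches both of their annuli *and* they are within
100 μm. The cap is a deliberate addition: without it, the long bridging
septa of advanced fibrosis weld portal tracts and central veins into a
single structure, destroying the PT/CV distinction the classifier needs.

Classified structures are painted into the region map as their holes
plus a 25 μm halo; overlapping halos resolve to the nearer structure
(ties to the lower structure index), and all remaining tissue is
perisinusoidal. CV + PT + PS is an exact partition of the tissue by
construction. All radii and distances above are configuration fields.

## Morphometry

A collagen string is an 8-connected mask component of at least 4 pixels
(smaller components have no meaningful skeleton and are treated as
noise). Skeleton length counts inter-pixel steps (1 per orthogonal pair,
√2 per diagonal pair) and is floored at one pixel pitch; width is
area/length — a ribbon model that keeps the thickness rule scale-free.
Classes:

* aggregated ⇔ the skeleton has ≥ 1 branch point (a pixel with ≥ 3
  skeleton neighbours), operationalising "cross-linked";
* thick ⇔ width/length > 0.25, strictly (a ratio of exactly 0.25 is
  thin);
* long ⇔ length > cutoff; the default cutoff is the subject's median
  string length (the source defines thickness relatively and never
  defines short/long; the relative default mirrors that and an absolute
  μm cutoff is available).

The 100-feature vector is three 28-feature region blocks plus 16
whole-tissue features. Per-scope collagen percentages are computed from
string areas, so aggregated% + distributed% = collagen% holds exactly
and the three region shares sum to the global collagen percentage.
Counts are normalised per mm² of scope area; string statistics are plain
means (zero for an empty scope, with the missing region flagged).
Subject-level vectors are tissue-area-weighted means over tiles — equal
to the plain mean for full-tissue tiles. The complete list of 100
feature definitions was never published; the registry reconstructs names
from the 14 selected features' naming scheme, and the historical
spelling `StrLengthSFD` is treated as the PS-distributed string length
(`StrLengthPSD`), kept as an accepted alias.

Feature counts and percentages are exactly invariant under translation
and 90° rotation; mean string statistics can shift slightly under
rotation because thinning is not perfectly rotation-equivariant.

## The fibrosis index

Sequential forward selection greedily adds the feature that minimises
the residual sum of squares of an intercepted OLS fit, stopping at
k = 14 by default (the published selection size; no stopping criterion
was stated, so an RSS-improvement tolerance is available as an
alternative). RSS of an OLS fit is invariant to column scaling, so
internal z-scoring changes conditioning only; reported coefficients are
always on the original feature scale. Candidates that would make the
design singular are skipped with a warning. Inside OLS the design is
column-equilibrated to unit norm before the rank test — feature scales
in this problem span five orders of magnitude (percentages vs per-mm²
counts) and would otherwise masquerade as rank deficiency.

The index is the OLS prediction clamped at zero; there is no upper
clamp. Leave-one-out cross-validation refits per fold; by default the
feature subset is selected once on the full table (mirroring the
original two-phase select-then-validate protocol, which leaks the
selection step) and `reselect_per_fold=True` gives the leakage-free
variant. A fold whose training design is singular — typically because a
selected feature was non-zero for exactly the held-out subject — yields
NaN and is flagged; downstream reports exclude non-finite scores with a
warning. The clamp is applied per prediction, before any aggregation.

## Diagnostics

AUROC is the Mann–Whitney probability with half-credit for ties,
computed from midranks; the 95% CI uses DeLong structural components
(no CI method was named in the source; a stratified bootstrap is
available by flag). The Youden cutoff maximises sensitivity +
specificity over the observed score values with a strictly-greater
positive rule, matching the published "index > cutoff" phrasing; the
objective is evaluated in exact integer arithmetic so ties are true ties
and resolve to the smallest cutoff. Likelihood ratios with zero
denominators are reported as infinite with a warning. Exported tables
round percentages to one decimal and likelihood ratios to two; full
precision is kept internally.

## Synthetic data

The image generator emulates exactly the structures the pipeline must
recognise, following the Brunt progression: stage 0 draws collagen only
as vessel-wall rims; stage 1 adds short thin distributed strings in PS;
stage 2 adds branched (aggregated) periportal strings; stage 3 adds long
branched strings bridging PT and CV; stage 4 adds thick septa enclosing
a nodule. Strings are dilated polylines at least 3 px wide (so they
survive the median filter); aggregated strings get explicit side
branches, and if clipping against a hole erases the junction the string
is relabelled distributed — ground-truth labels always describe the
emitted pixels. Hole classes are constructed to be separable on the five
CART features: vessels and bile ducts are rimmed, steatosis vacuoles are
rimless circles kept clear of PS strings, cracks are elongated
low-solidity shapes. Portal tracts and central veins are placed ≥ 280 px
(≈109 μm) apart — they sit at opposite ends of the lobule — which also
keeps bridging septa from welding their structures together. The
ground-truth region map is built with the same hole-plus-25 μm-halo rule
the analysis uses. Noise is additive Gaussian on both channels plus
0.08% salt speckle on SHG at 1.6× the collagen amplitude; defaults
(noise sd 120 against a collagen amplitude of ~5500–9500 and a TPEF
tissue level of 7500, steatosis density 75/mm², crack probability 0.3)
were chosen once as plausible for well-prepared biopsy imaging.

What the generator does **not** model: real SHG optics (point-spread,
depth attenuation, polarisation), anatomically correct lobule geometry,
partial tissue coverage and ragged biopsy edges, staining artefacts, and
the natural covariance structure of collagen features. Passing tests
therefore demonstrate that the algorithms implement their contracts and
that the pipeline recovers a known stage signal under the stated
conditions — not clinical accuracy on real biopsies.

The tabular simulator generates subject × 100 tables directly: stages
are drawn from the observed cohort distribution
(22.9/30.1/8.4/16.9/21.7%), each of the 14 informative columns is
bⱼ·stage + subject variation with bⱼ = 1/(14cⱼ), and the variation
matrix is projected orthogonal to the coefficient direction so that
stage = Σ cⱼxⱼ holds exactly at zero noise while the design stays full
rank — this makes noiseless OLS recovery of the generating coefficients
exact rather than approximate. Nuisance columns are independent standard
normals. The source reports no per-stage collagen quantities, so the
generating coefficients and noise level are free parameters fixed once
in `DEFAULT_INFORMATIVE_COEFFICIENTS` (magnitudes 0.3–0.9, mixed signs,
default table noise sd 0.02).

## Problem sizes

The test suite and `scripts/acceptance.py` run the image pipeline at
reduced scale — 5-subject schema checks, a 15-subject cohort (3 per
stage, 2 tiles each) for the monotonicity and region-accuracy
experiments, and 100-instance oracle sweeps — sizes chosen so the full
validation runs in well under a minute of pipeline time while every
stage of the method is still exercised end to end. Tabular experiments
use the full 83-subject, 100-feature scale throughout.

## Known limitations

* The shipped CARTs are only as good as the synthetic hole taxonomy;
  real bile ducts, fat droplets and cracks are far more varied.
* Width = area/length understates the width of strongly curved or
  branched objects (skeleton length includes branches).
* Fixed-selection LOOCV inherits the selection-leakage optimism of the
  original protocol; use `reselect_per_fold=True` for honest error
  estimates.
* DeLong intervals are asymptotic and can exceed [0, 1] before
  truncation at extreme AUCs with few subjects.
* Otsu segmentation assumes a bimodal SHG histogram; tiles that are
  nearly all collagen or all background degrade gracefully (degenerate
  histogram → empty mask with a warning) but are not meaningful.
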