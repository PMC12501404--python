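# Methods

This note documents the models and procedures implemented in `imcpatch`,
the parameters that matter, the design choices made where several
reasonable options existed, and what the synthetic-data experiments do and
do not demonstrate.

## Coordinate and unit conventions

Images are 1 µm/pixel, so areas in µm² equal pixel counts and pixel
indices double as micrometre coordinates. Cell positions are centroids:
mean pixel index + 0.5 µm (pixel centres). All pairwise distances are
Euclidean distances between centroids, not mask boundaries — after
segmentation the analysis treats cells as points, which is the convention
of neighbourhood-based multiplexed-imaging toolkits.

## Synthetic tissue generator

The generator emulates the structure the analysis assumes rather than the
physics of acquisition:

- **Compartments.** A rectangular tissue with a background margin, an
  epithelial band, a submucosal band, circular follicles and lamina propria
  (LP) as the remainder. Follicle geometries must be disjoint and inside
  the tissue; violations raise a layout-conflict error.
- **Cell placement.** Homogeneous Poisson sampling per compartment at
  configurable densities (defaults: follicle core B cells 0.008 cells/µm²,
  mantle T cells ~0.006 total, scattered LP populations ~0.004 total,
  epithelium 0.01 — cell-every-10–16-µm spacings typical of dense lymphoid
  versus looser connective tissue). A minimum centre separation (default
  4 µm) is enforced by greedy thinning so rendered discs form a proper
  partition. Planted *attraction* follows a Thomas-process construction: a
  fraction of child-type cells is re-placed at a random parent plus an
  isotropic Gaussian displacement (scale < the 20 µm interaction cutoff by
  validation, otherwise the planted signal would be undetectable by
  design). Children are placed after thinning and re-draw their
  displacement rather than being deleted when they would violate the
  separation constraint — deleting them would silently remove the planted
  signal. Planted *avoidance* re-samples child positions until they are
  beyond an exclusion distance from every parent. Planted small patches
  are laid out deterministically on concentric rings so their graph
  connectivity is exact by construction.
- **Intensities.** Each cell contributes its signature mean × one
  lognormal factor per (cell, marker) (σ default 0.3) over its disc;
  channels add a constant background (default 0.5 counts) and optional
  Gaussian read noise, floored at 0. Lognormal multiplicative noise gives
  the right-skewed, zero-inflated ion-count-like distributions that the
  arcsinh transform is designed for. Nuclear channels are positive in all
  cells by construction of the default signature matrix.
- **Not emulated:** isotope spillover (channels are spillover-free),
  ablation artefacts, nucleus/cytoplasm texture, irregular cell shapes,
  and segmentation errors. Tests passing on this generator therefore
  validate the analysis logic, not robustness to segmentation or spillover
  problems in real data.

One master seed fans out (via `numpy.random.SeedSequence.spawn`) to
per-stage child seeds recorded in output metadata; every fixture is
reproducible bit-for-bit.

## Background correction (SMO)

The silver mountain operator scores each pixel by the coherence of local
gradient directions: smooth with a Gaussian (σ = 1.3 px), compute the
gradient, normalize each gradient vector to unit length, average the unit
vectors over a 7×7 window, and take the norm — a value in [0, 1] that is
low where gradient directions are random, i.e. in background. Pixels below
the 0.1 quantile of the statistic form the background sample; the scalar
estimate is the median intensity over that sample, and the corrected image
is `max(image − estimate, 0)`. Borders use replicate padding to avoid an
artificial high-coherence frame. A constant image is degenerate (all
gradients zero): the estimate is the constant, with a warning. The
estimate is a scalar per channel per image — the minimal faithful contract
for a method that estimates the background *distribution* — not a
pixel-wise surface. Images of any shape are accepted; the shape is simply
recorded.

## Normalization and filtering

Raw per-cell means are transformed as `asinh(x / cofactor)` with cofactor
1, then clipped channel-wise to the [1, 99] percentile interval computed
**per sample**: batch-to-batch intensity variation is the motivation for
this stage, so the clip scope follows the batch. Percentiles use
order-statistic interpolation (`lower`/`higher`), which makes the clip
exactly idempotent. The size filter keeps cells with 15 ≤ area ≤ 250 µm²,
both bounds inclusive (conventional closed-interval reading of a printed
range). Raw values are preserved next to transformed ones.

## Phenotyping

Gating is two-level and deterministic: CD45⁺ → immune, else E-Cadherin⁺ →
epithelial, else other; within immune, CD3 vs CD20 splits T from B, with
double positives resolved by the larger margin over threshold and double
negatives as "other immune". Thresholds are fixed values from config, or
per-image Otsu on the arcsinh scale when unspecified — manual gating needs
an automated stand-in, and Otsu on a bimodal arcsinh-scale marker is the
standard one.

The hard T-cell splits use a random-forest classifier over the classes
{CD4 T, CD8 T, non-T, epithelial} trained on an annotated subset (in the
synthetic pipeline the generator truth plays the annotator on a 25% random
subset); its per-cell class probabilities are appended as features. This
re-casts pixel-level probability maps as cell-level probability features
with the same contract: probabilities sharpening the separation of closely
packed lymphocytes. Optional neighbour-context features (mean marker values
over spatial neighbours) mimic the pixel-context a pixel classifier sees.

Within each gate, k-means (k-means++ init, 10 restarts, fixed seed) on
branch-specific markers produces clusters that a total merge map renames to
populations from a controlled vocabulary; a suggested map can be derived by
cosine-matching cluster mean profiles to arcsinh-scaled signatures, but the
user map wins when given. Frequencies are per (sample, segment) fractions;
densities divide counts by segment areas from the tissue mask.

## Spatial graphs

Interaction tests run on the **Delaunay triangulation pruned to ≤ 20 µm**;
neighbourhood profiles use the plain **20 µm radius graph** — the two
constructions named for those two purposes, kept distinct. Radius-graph
edges are a superset of pruned-Delaunay edges on the same points. Fewer
than 3 points or degenerate (collinear) configurations fall back to the
radius construction with a warning; duplicate centroids are jittered by
< 0.01 µm before triangulation.

## Interaction permutation test

For ordered pair (A, B): T(A,B) = (1/|A|) Σ_{a∈A} #{neighbours of a
labelled B} — the "classic" mean over all source cells (the default of the
histoCAT-style method family), not the conditional has-a-neighbour
variant. The null shuffles labels uniformly over the tested region's nodes
with the graph fixed; region-restricted runs shuffle only within the
region, conditioning on compartment composition. P-values use the add-one
estimator, p = (1 + #{T\* ≥ T_obs}) / (1 + n_perm), so p ∈ (0, 1]; since
type counts are permutation-invariant, the comparison is done on integer
co-occurrence counts, avoiding float ties. Defaults: n_perm = 1000,
α = 0.01, both configurable. A pair is *attraction* if the upper-tail p
< α, *avoidance* if the lower-tail p < α (at most one can fire for
α ≤ 0.5). Pairs whose source type is absent are emitted as undefined with
no call. Region log₂ ratios compare mean observed statistics between two
regions with a pseudocount ε = 0.01 neighbours/cell in numerator and
denominator. Both orderings of every pair are always emitted.

Calibration: on label-randomized images the attraction-call rate at
α = 0.01 sits inside the 99% binomial interval around 0.01 provided the
co-occurrence counts are fine-grained enough; the calibration experiment
uses 400-cell images at follicle-like density (0.008 cells/µm²) for that
reason — with very few edges the discrete null makes the test
conservative, which is the expected direction of error.

## Cellular neighbourhoods

Per-cell profiles are neighbour-type counts divided by degree (simplex
vectors); zero-degree cells get their own one-hot vector plus a flag, so
every cell stays assignable to patches downstream. k-means uses k-means++
with 10 restarts and a fixed seed; the default k = 40 follows the
many-centres-then-annotate strategy. The cluster sweep reports WSS and
subsampled silhouette over a k range, anchors the curve at k = 1 (total
sum of squares), and suggests the elbow (largest second difference of
WSS) — a declared default, not an inference of any particular prior
choice; the suggestion is overridable. Annotation is two-level: level 1 =
populations with centre fraction > 0.4 (arg-max fallback, ties broken by
population order and flagged); level 2 = populations above 2× the global
mean centre fraction. Stored centres reproduce stored labels under the
nearest-centre rule.

## B-cell patch detection

All B-lineage subpopulations are pooled; the B–B edge-induced subgraph of
the pruned Delaunay graph is decomposed into connected components, and
components with ≥ 10 cells become patch cores (strict: a 9-cell component
is rejected). The patch region is the convex hull of core centroids
buffered outward by 1 µm — the 1 pixel ≘ 1 µm expansion — and expanded
membership is centroid-in-region (boundary inclusive) for cells of any
population. Patch area is the buffered-hull area; class is *large* iff
area > 12,000 µm², strictly, so exactly 12,000 µm² is small. Hull-based
area ignores concavity — a deliberate simplification (robust without mask
access); strongly non-convex aggregates are over-measured, a documented
limitation. Patch tissue localization is the majority segment of core
members. Patch ids order by image, then smallest core cell id, making
detection invariant to cell relabelling.

## Group statistics

PCA always centres; unit-variance scaling is the default (and
configurable) since frequency features live on different scales. Component
signs are fixed by making each component's largest-magnitude loading
positive; feature contributions are squared-loading shares, summing to 1
per component. Constant features are dropped with a warning.

Rank-sum comparisons use the exact null for combined n ≤ 20 without ties
(cohorts of 3–6 samples per group make exactness matter) and the normal
approximation with continuity and tie correction otherwise; all-tied data
reports p = 1 with a warning. Benjamini–Hochberg correction is applied
across one analysis panel (all features × group pairs displayed together).
Stars: \*p ≤ 0.05, \*\*p ≤ 0.01, \*\*\*p ≤ 0.001, \*\*\*\*p ≤ 0.0001.
Boxplots show median, IQR and 1.5·IQR whiskers.

## Problem sizes in tests and the reproducibility script

The validation experiments run at desk scale on one CPU: 500 calibration
images of 400 cells; 50 power images per planted condition (320–360 µm
squares at LP-like densities); exhaustive-enumeration comparisons on ≤ 6
cells (all n! orderings); graph oracles at 200 points; a 2-sample
end-to-end determinism run on 400×400 µm images. These sizes give stable
Monte-Carlo estimates (binomial SEs of a few per mil on calibration, a few
percent on power) while keeping the whole suite in minutes.

## Known limitations

- The generator's circular follicles, disc-shaped cells and per-cell
  (rather than per-pixel) noise are idealizations; no spillover,
  segmentation error, or tissue deformation is modelled.
- Patch areas assume convexity; the 1 µm expansion admits cells by
  centroid, not mask overlap.
- Interaction p-values are Monte-Carlo; with the add-one estimator the
  smallest attainable p is 1/(n_perm + 1), so α must exceed that.
- The probability classifier in the self-contained pipeline trains on
  generator truth; on real data it requires user annotations covering all
  four classes.
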