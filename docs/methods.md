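# Methods

This note documents the models, conventions and defaults behind
`histocascade`, the design choices made where several reasonable options
existed, and what the synthetic benchmark does and does not demonstrate.

## Stain model and colour deconvolution

Light transmitted through a stained section obeys the Beer-Lambert law:
per channel, the optical density `a = -log10(I / I0)` is linear in the
amounts of absorbing stain. Each stain contributes a characteristic unit
OD colour vector; the rows of the normalized 3x3 stain matrix `M` are
those vectors for hematoxylin, eosin and a residual third material, and a
pixel with stain amounts `C` shows `a = C @ M`. Deconvolution inverts
this: `C = a @ inv(M)`.

Conventions and defaults:

* **Log base 10** (the standard OD convention). The choice only rescales
  stain amounts globally, so downstream thresholding is unaffected.
* **Default stain vectors**: the widely published H&E calibration
  H = (0.650, 0.704, 0.286), E = (0.072, 0.990, 0.105) (unit-normalized),
  overridable from YAML as nine row-major numbers plus `I0`. True stain
  vectors vary between laboratories and scanners; a production deployment
  would calibrate `M` per site.
* **Residual row**: the normalized cross product of the H and E rows —
  the standard completion when only two stains are specified.
* **Zero-intensity clamp**: intensities below `eps = 1/I0` are clamped
  before the log, bounding the OD of saturated dark pixels at
  `2*log10(I0)` (≈ 4.81 for 8-bit).
* A stain matrix with condition number above 1e8 is rejected with the
  condition number reported.

## Nuclei detection

The hematoxylin plane is binarized with Otsu's threshold (256-bin
histogram; foreground is the stain-dense side). The boundary set is the
8-connected exterior border of the foreground, and the Euclidean distance
transform `d(r)` measures the distance of each foreground pixel to the
nearest boundary pixel (0 on boundary and background; `d` is 1-Lipschitz).
Watershed floods `-d` from markers placed at the 8-connected regional
maxima of `d`; a maximum plateau contributes one marker at its centroid
(snapped to the nearest foreground pixel), and markers closer than
`min_distance` are merged to suppress over-segmentation caused by
discretization ridges.

Parameters (at the package's nominal scale — nucleus radii of 3-4 px,
emulating 20x-magnification tiles):

* `min_distance` = 5 px: merging radius for watershed markers.
* `min_area` = 12 px^2: segments smaller than this are discarded. The
  Otsu footprint of a 3-4 px-radius nucleus measures roughly 18-40 px^2,
  so 12 px^2 removes threshold speckle without deleting true nuclei; a
  larger cutoff (e.g. 30 px^2) silently discards most genuine nuclei at
  this scale.
* 8-connectivity throughout; 0-based (row, col) coordinates with pixel
  centres at integers.

Degenerate inputs: a constant hematoxylin plane admits no Otsu threshold
and the full `detect` pipeline returns an empty centroid set with a
warning rather than failing.

Detection quality is evaluated by optimal one-to-one bipartite matching
of detected to planted centroids within a 3 px radius
(`nuclei.match_centroids`), reporting matched / missed / spurious counts.

## Nuclear architecture features (48)

All pools are summarized by the mean `B`, the **population** standard
deviation `A` (the population convention keeps the summary defined for a
single measurement), the disorder `1 - 1/(1 + A/B)` — defined as 0 when
either `A` or `B` vanishes — and, for the graph families, the min/max
ratio (1 for an all-zero pool).

* **Voronoi (12)**: each centroid's cell is the set of pixels nearer to
  it than to any other centroid. Unbounded cells are clipped to the image
  rectangle by *reflecting* the centroid set across each of the four
  rectangle edges before tessellating: every original centroid then owns
  a finite convex polygon and the cell areas sum exactly to the image
  area (partition conservation, verified to 1e-6 relative). Measured per
  cell: area (shoelace), chord lengths — defined as **all pairwise
  distances between the polygon's vertices**, a convention chosen because
  a "chord" most naturally spans the polygon — and perimeter.
* **Delaunay (8)**: triangle areas and perimeters of the dual
  triangulation (every triangle's circumcircle is empty of other
  centroids).
* **MST (4)**: branch lengths of the minimum spanning tree, computed on
  the Delaunay edge set (of which the MST is always a subgraph). Tests
  verify the total weight against exhaustive enumeration of all labelled
  spanning trees via the Prufer bijection for n ≤ 8.
* **Density (24)**: per-centroid neighbour counts within radii of 10, 20,
  30, 40, 50 px (inclusive `<= radius`, with a 1e-9 slack so ties are
  deterministic), each summarized by mean/std/disorder (15 features); and
  the **mean** distance to the k nearest neighbours for k = 3, 5, 7,
  summarized the same way (9 features). The mean-of-k convention (rather
  than the k-th distance) was chosen as the smoother statistic.

Duplicate centroids are de-duplicated with a warning before graph
construction (coincident points break the underlying qhull
triangulations). Fewer than 4 non-collinear points (Voronoi), 3
(Delaunay) or 8 (density) raise degenerate-geometry errors.

## Texture features (540)

Channels: hue and saturation from the standard hexcone (HSV) model and
intensity = (R+G+B)/3, each rescaled to [0, 255]. Co-occurrence operates
on the rounded integer planes; first-order and Gabor use the float
planes. 15 + 21 + 24 feature images per channel, each aggregated by
(mean, population std, mode), give 135 + 189 + 216 = 540 features.

**First-order (15)**, default 3x3 sliding window, reflected boundary:
windowed mean, median, std, range; Sobel responses in the vertical,
horizontal and both diagonal orientations; Kirsch compass responses N,
NE, E (three of the eight classic kernels — the count is fixed at three,
the selection is a documented convention); central-difference gradients
along rows and columns; their difference; and the diagonal derivative
`(f(r+1,c+1) - f(r-1,c-1))/2`.

**Co-occurrence (21)**, default 9x9 window with the four unit
displacements (0°, 45°, 90°, 135°) accumulated symmetrically into one
256-level GLCM per pixel. A displaced pair is counted when its anchor
pixel lies in the (image-clipped) window and its partner inside the
image. The statistics, on the normalized symmetric matrix `p(i,j)` with
marginal `px`, `mu = E[i]`, `sigma^2 = Var[i]`, `s = i+j`, `d = |i-j|`
and natural-log entropies:

| # | feature | formula |
|---|---------|---------|
| 1 | autocorrelation | `E[ij]` |
| 2 | contrast | `E[(i-j)^2]` |
| 3 | correlation | `(E[ij] - mu^2) / sigma^2` (0 if `sigma^2 = 0`) |
| 4 | cluster prominence | `E[(s - 2 mu)^4]` |
| 5 | cluster shade | `E[(s - 2 mu)^3]` |
| 6 | dissimilarity | `E[d]` |
| 7 | energy | `sum p^2` |
| 8 | entropy | `-sum p ln p` |
| 9 | homogeneity | `E[1 / (1 + (i-j)^2)]` |
| 10 | maximum probability | `max p` |
| 11 | variance | `sigma^2` |
| 12 | sum average | `E[s]` |
| 13 | sum variance | `Var[s]` |
| 14 | sum entropy | entropy of `p_{i+j}` |
| 15 | difference variance | `Var[d]` |
| 16 | difference entropy | entropy of `p_{|i-j|}` |
| 17 | information measure of correlation 1 | `(HXY - HXY1) / max(HX, HY)` |
| 18 | information measure of correlation 2 | `sqrt(1 - exp(-2 (HXY2 - HXY)))` |
| 19 | inverse difference | `E[1 / (1 + d)]` |
| 20 | inverse difference normalized | `E[1 / (1 + d/256)]` |
| 21 | inverse difference moment normalized | `E[1 / (1 + d^2/256^2)]` |

Two implementation facts matter:

* For *any* joint distribution, `HXY1 = -sum p(i,j) ln(px(i) py(j))`
  separates into `HX + HY`, and `HXY2 = -sum px py ln(px py)` does too.
  The two information measures therefore need only the joint entropy and
  the marginal entropy (equal marginals, by symmetry).
* Statistics that are linear functionals of the GLCM are windowed
  averages of per-pair images and are computed exactly with box filters.
  Only the entropy family (7, 8, 10, 14, 16 and `HX`) needs the local
  histogram; a compiled kernel slides the window incrementally across
  each row, maintaining the joint and marginal histograms together with
  running values of `sum c^2` and `sum c ln c`, so each pixel costs a
  constant number of histogram updates instead of a full rebuild. The
  engine is validated against a dense 256x256 reference implementation
  at individual pixels (agreement to ~1e-12 relative).

**Gabor bank (24 planes)**: `G = exp(-((x'/sx)^2 + (y'/sy)^2)/2) *
exp(i 2 pi k x' / W)` on a 17x17 kernel (half-width 8), with
`x' = x cos t + y sin t` and — deliberately — `y' = y cos t + x sin t`,
an improper rotation kept as published, with a `printed_rotation=False`
switch for the conventional form (with `sx = sy`, the default, the
envelope is isotropic at t = 0 and t = pi/2, so orientation-swap
covariance under 90° rotation still holds there). The frequency `k` is
interpreted as **cycles across the kernel width** `W = 17`; a literal
`cos(2 pi k x')` with k = 5 px^-1 would alias far above Nyquist. Bank:
k in {5, 9} x t in {0, pi/6, ..., 5 pi/6} = 12 filters, real and
imaginary response planes each. `sx = sy = half_width/2 = 4 px`; kernels
are applied as correlation templates on reflect-padded input and the real
part is zero-mean adjusted so flat regions give no response.

**Aggregation**: mean and population std over all pixels; the mode is the
centre of the most populated of 256 equal-width bins spanning
[min, max] on the raw float plane (ties resolve to the lowest bin; a
constant plane's mode is its value).

Determinism: the full 540-vector is bit-for-bit reproducible for a given
image.

## Classification strategies

Base learner: a CART-style decision tree with the entropy criterion,
`min_samples_leaf = 2`, no depth limit, no pruning (scikit-learn
implementation; the closest open analogue of the C5.0 family of
entropy-based trees). Hyperparameters are exposed via `tree_params`.

* **CAS**: six binary trees on the default group hierarchy
  (cancer/non-cancer, then {G3,G4} vs G5 and confounder vs normal, then
  the three remaining pairs). Each node trains only on samples whose
  label belongs to its groups and selects its own splits, so features are
  effectively chosen per task. Prediction routes root-to-leaf (at most
  three classifier calls); a sample's final label always lies within the
  group chosen at every ancestor.
* **OSC**: one multi-leaf tree over the seven labels.
* **OVA**: seven independent target-vs-rest trees, each scored on its own
  binary task so errors in one class do not affect another; an optional
  fused argmax-of-probability mode produces a single 7-way label.

Evaluation is per class from the TP/TN/FP/FN contingency of each test
fold. `ACC = (TP+TN)/total`, `PPV = TP/(TP+FP)`, `NPV = TN/(TN+FN)`;
a metric with a zero denominator is reported as missing and excluded from
averaging. The experiment runs stratified 3-fold cross-validation
(stratification guarantees every class appears in every cascade training
fold) repeated for 20 trials, re-shuffling folds each trial with seed
`master_seed + trial`; summaries report the mean and standard error over
the 60 fold-evaluations.

## AdaBoost feature ranking

The weak learner is a single-feature threshold stump, both polarities
searched over all midpoint thresholds. At iteration t the stump with the
lowest weighted error is selected, `eps_t` is clamped to
`[1e-10, 0.5 - 1e-10]`, `alpha_t = ln((1 - eps_t)/eps_t)/2`, and sample
weights are updated multiplicatively and renormalized (the weight vector
sums to 1 after every iteration; selected stumps always do at least as
well as chance on the weighted sample, so `alpha_t >= 0`). A feature
selected at several iterations accumulates its alphas; weights are also
summed across repeated trials (stratified two-thirds subsamples). The
ranking is sorted by cumulative weight with lexicographic tie-breaks, so
reported weights are non-increasing in rank by construction — note that
raw per-iteration alphas need not decrease monotonically; only the sorted
report is.

Default T = 10 iterations, 20 trials.

## Synthetic tissue generator

Each tile is built from the same physical model the deconvolution stage
inverts: per-nucleus hematoxylin density blobs (2D Gaussians, sd =
radius/2, truncated at 3 sd, peak amount 0.85 OD units — Gaussian rather
than hard discs so the distance map has smooth, realistic watershed
basins) plus a uniform eosin background, pushed through the forward
model `I = I0 * 10^(-C M)`, plus Gaussian intensity noise, quantized to
8-bit RGB. Deconvolving a noise-free tile therefore recovers the planted
density to numerical precision (< 1e-6 before quantization).

Arrangements: `gland_ring` places nuclei on jittered circles (radius
9-18 px) emulating glandular epithelium; `dense_random` /
`sparse_random` / `dispersed` use rejection sampling with a minimum
centre separation of 1.2x the mean nucleus radius (1.0x for dense).
Placement failures beyond an attempt budget raise an explicit error.

The seven default class specifications are calibrated for 128x128 tiles
(nucleus counts scale with tile area) and encode the clinical similarity
hierarchy in their numeric parameter vectors (nucleus count, radius,
noise, eosin level): G3 and G4 are mutual nearest cancer classes and far
from G5; the confounder pair {AT, PIN} and the normal pair {BE, BS} are
each tighter than any cancer-to-non-cancer distance (asserted in tests on
range-scaled coordinates). Cancer classes are nucleus-dense and
eosin-poor; normals and confounders are sparser and eosin-rich.

A separate four-class benchmark set (`detection_benchmark_specs`) uses a
3x-radius minimum separation so nuclei never overlap, giving an exact
target for detection benchmarking (≥ 95% of planted centroids matched
within 3 px; in practice ~100% with no spurious hits).

Per-tile seeds derive from the master seed through a counter-based
`SeedSequence` scheme, so datasets are reproducible and generation order
is irrelevant.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical images: real nuclear chromatin texture and shape
variation, lumen and intra-luminal protein, stromal fibre texture,
staining gradients and batch variation, scanner optics and compression
artefacts, and mis-calibrated stain matrices (the generator composes with
the same matrix the pipeline inverts, so deconvolution is exact by
construction rather than approximately correct as on real slides). The
cross-validated CAS/OSC/OVA comparison on synthetic data demonstrates
that the machinery measures what it claims and that the cascade is not
harmed — and is typically helped, most visibly against OVA — by nested
class structure; absolute performance numbers on this synthetic cohort
say nothing about clinical performance.

## Problem sizes used by the test suite and acceptance script

Synthetic cohorts use 128x128 tiles; the strategy-comparison experiment
runs on 60 tiles per class (420 total) with 20 trials x 3 folds; the
detection benchmark uses 40 tiles; oracle checks use 100 seeded point
sets (MST) and 50 (Voronoi/duality); boosting sanity uses 50 seeds.
These sizes were chosen so the whole suite completes in a few minutes on
a single CPU while keeping every per-class mean an aggregate of 60
fold-evaluations.

## Known limitations

* The cascade hierarchy is fixed by domain knowledge, not learned; a
  data-driven grouping (e.g. clustering class centroids) might order the
  bifurcations better.
* OVA is scored per binary task by design; its fused mode exists but is
  not part of the headline comparison.
* The Voronoi chord-length convention, the Kirsch kernel subset, the
  GLCM window/offset geometry and the Gabor envelope parameters are
  documented conventions; other choices would change feature values (but
  not the counts or the comparison protocol).
* Architecture features require at least 8 detected nuclei; essentially
  empty tiles raise degenerate-input errors rather than returning
  padding values.
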