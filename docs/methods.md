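# Methods

Measurement conventions, parameter rationale and scope of validity for
`myofiberquant`.

## 1. Tissue detection and tiling

Sections are screened at a working resolution of 7 µm/px (area-averaged
downsampling). The per-pixel score is max(R, G, B); a pixel is tissue iff
score < 190 (H&E background is near-white, so its maximum channel is
high). Optional Gaussian prefiltering (`gaussian_sigma`) is off by
default. Connected tissue components (4-connectivity) are mapped back to
full-resolution bounding boxes; the box is quantized to the working grid,
so it may miss or overshoot a tissue edge by up to one working pixel
(14 full-resolution px at 0.5 µm/px).

Tiles are 712 × 712 px with 200 px overlap (step 512 px). The overlap
must exceed the largest expected fiber extent; at 0.5 µm/px, 200 px =
100 µm comfortably exceeds normal fiber diameters. The last row/column of
tiles is shifted inward so that every tile is full-sized and in-bounds;
this gives the final pair of tiles a larger overlap, which the
reconstruction handles by nested-duplicate resolution (below).

## 2. Segmentation backends

A backend is any callable `(tile, params) -> LabelImage`. The package
never trusts backend output: shape, type and non-mutation of the input
are checked at the call site. Three backends ship:

* **oracle** — crops the planted ground truth of a synthetic scene,
  optionally degraded by a seeded perturbation (per-tile seeds are
  derived from the tile origin, so outputs are reproducible and
  overlap-consistent across calls). This is the reference backend for all
  testing.
* **none** — background everywhere (pipeline plumbing tests).
* **cellpose** — thin adapter around the optional `cellpose` package,
  treated as an opaque model; default tuned parameters are 50 px expected
  diameter on the blue channel, flow threshold 0.5, resampling on.
  `gray` is the rounded unweighted RGB mean.

## 3. Whole-slide reconstruction

Each fiber in an overlap strip appears (possibly cut) in two or four
tiles. Reconstruction makes each survive exactly once:

* **stripe rule** — a mask entirely inside the top (left) 200 px overlap
  stripe is removed, *unless* it reaches row (column) `overlap − 1`. The
  one-pixel keep band is what makes the rule exhaustive: a fiber whose
  extent is smaller than the overlap either touches the previous tile's
  last row (removed there by the border rule, kept here) or does not
  (kept there whole, removed here). This is why the exactly-once property
  is provable rather than statistical, given fiber extent < overlap.
* **border rule** — a mask touching the tile's last row/column is removed
  when a neighbor exists on that side; the neighbor sees the fiber whole.
* Both rules are suppressed at slide edges (no neighbor), so genuine
  tissue-edge fibers are kept.
* Surviving masks are offset into slide coordinates (tile origins are
  encoded in the tile filename, `{slide}_x{X}_y{Y}.tif`). The
  inward-shifted last tiles can still duplicate a fiber; pairs whose
  pixel intersection covers ≥ 95 % of the smaller mask are resolved by
  keeping the larger. Remaining partial overlaps are settled at
  rasterization, where contested pixels go to the larger mask.

The placed-mask raster patch is the source of truth; polygons are derived
lazily for vector export.

## 4. Evaluation

Matching is by IoU with a strict threshold (IoU > t, t ≥ 0.5), which
guarantees at most one prediction matches a ground-truth object. The
production matcher gates candidate pairs by label co-occurrence (a joint
histogram, equivalent to bounding-box gating) and runs in three stages:
import, per-prediction best-IoU promotion to TP, per-ground-truth FN
clearing. Its independent cross-check is a brute-force all-pairs matcher;
the two are verified to agree exactly on randomized scenes.

Detection scores: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean, each 0 when its denominator is 0. Contour quality:
RMSE = sqrt(mean((pred − gt)²)) of the minimal Feret diameter over TP
pairs, in µm. Threshold sweeps report F1 (analytically non-increasing in
the threshold — the TP set can only shrink) and the number of non-empty
5 µm diameter classes among matched ground-truth fibers.

## 5. Morphometry

**Minimal Feret diameter.** The minimum caliper width of a convex shape
is attained with the caliper flush against one convex-hull edge, so the
exact value is the minimum over hull edges of the maximum vertex distance
to the edge's supporting line. This is the rotating-calipers result
computed directly; it is exact (no angular sampling) and verified against
a 0.1° projection sweep and under rotation. Concave outlines use their
convex hull, matching the physical caliper.

**Nuclei and the CNF rule.** A fiber is centrally nucleated when at least
one of its nuclei lies strictly farther than 2.2 µm from the fiber
boundary. The default distance is nucleus boundary to fiber boundary
(`distance_statistic="min"`: any part of the nucleus within the threshold
keeps it peripheral); `"centroid"` is available. A distance of exactly
2.2 µm is peripheral under the strict rule. Nuclei are assigned to the
fiber whose label lies under their centroid pixel.

The reference nucleus detector (hematoxylin channel by fixed stain-vector
deconvolution, Gaussian smoothing at 0.5 µm, threshold 0.07, watershed
splitting, 4–120 µm² area gate, with near-black pixels excluded as debris
since dust mimics hematoxylin in the deconvolution) stands in for
interactive detectors; tests that target the CNF logic itself use planted
oracle nuclei.

**Section summaries.** CNF ratio, mean minimal Feret diameter, VC
(population SD / mean by default), and a 5 µm histogram on [0, 100) µm
with right-open bins; fibers ≥ 100 µm are counted separately as overflow.

## 6. Artifact filtering

A binary random forest (100 trees, seeded, single-threaded for
reproducibility) classifies pixels tissue vs artifact from 9 features: per
RGB channel, the Gaussian smooth G, the Laplacian of G, and the
Gaussian-weighted local deviation sqrt(max(0, G(c²) − G(c)²)), all at a
physical scale of 1 µm. Training labels are 0/1/2 =
unlabeled/tissue/artifact; classes are balanced and capped at 50 000
pixels each. A mask is removed when its artifact pixel fraction exceeds
0.5 (majority rule). Models serialize with their feature parameters and
refuse to load under mismatched parameters.

## 7. Synthetic sections

The generator emulates the statistics that matter to the pipeline, not
photorealism:

* **geometry** — a jittered square lattice is tessellated (Voronoi),
  cells are clipped to the frame and eroded by half the boundary
  thickness (1.5 µm total). Minimal Feret targets are drawn from a
  lognormal (median 40 µm, log-SD 0.3 by default) and assigned
  rank-matched — the k-th largest draw to the k-th roomiest cell — so the
  cell-capacity cap almost never binds and the planted diameter sample
  tracks the lognormal. `max_extent_px` optionally caps the maximal Feret
  extent (used by the reconstruction study to guarantee extent <
  overlap).
* **nuclei** — planted per fiber; peripheral nuclei sit on an exact
  iso-depth contour with boundary gap in [0.15, 1.0] µm, central nuclei
  with gap ≥ 3.4 µm, i.e. at least 1 µm of construction margin on either
  side of the 2.2 µm rule, so raster/vector discretization (≲ 0.4 µm)
  cannot flip a planted flag. Each nucleus is central with probability
  `p_central_nucleus`.
* **artifacts** — dark blobs (dust/folds) and bright tears; fibers
  intersecting an artifact are excluded from ground truth, so planted
  truth never overlaps artifact pixels.
* **perturbations** — seeded label noise for manufacturing imperfect
  predictions: i.i.d. mask drops, boundary erode/dilate jitter (dilation
  only into background), splits, merges and spurious background blobs,
  all logged per label so tests can derive expected TP/FP/FN analytically.
* **cohorts** — the default study design is WT, three doses and KO with
  planted medians 40/38/33/30/28 µm, log-SDs 0.25…0.50 and per-nucleus
  central probabilities 0.01…0.30; section seeds derive from
  (master seed, group index, section index), so groups and sections are
  independent but reproducible.

Problem sizes in the shipped verification (2048² px reconstruction scene,
1280² px cohort sections, 2 sections/group, 20 master seeds) are the
package's own choice of a desk-scale study; they run in minutes on one
CPU.

## 8. Numerical conventions

* Label images are int32 rasters; 16-bit PNG on disk (capacity 65 535
  labels per image, enforced). Labels must be 4-connected; writers
  relabel violators with a warning.
* Mask-to-polygon conversion produces the exact pixel-corner boundary
  (union of per-row run rectangles), so polygon area equals pixel count
  and rasterization by the pixel-center rule is an exact inverse. This is
  what makes "IoU = 1.0" a meaningful, achievable target in round-trip
  and reconstruction tests.
* GeoJSON follows the QuPath dialect (`properties.classification.name`);
  MultiPolygons are split into one annotation per part; features with
  missing geometry are skipped with a warning, missing classifications
  default to "unclassified". Vertex coordinates survive round trips to
  ≤ 1e-6 px.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; cohort and per-tile seeds are derived, never global.

## 9. Limitations

* The exactly-once guarantee requires every mask extent to be smaller
  than the tile overlap; larger objects can be removed from both
  neighboring tiles. The defaults (200 px = 100 µm) are safe for muscle
  fibers but not for arbitrary structures.
* The synthetic generator is statistical, not photorealistic: real H&E
  variability (stain gradients, necrotic fibers, inflammatory infiltrate)
  is out of scope, so segmentation *models* cannot be benchmarked on it —
  only the pipeline stages around them.
* The reference nucleus detector is a deliberately simple stand-in;
  its thresholds were set against the synthetic palette and will need
  retuning for scanner imagery.
* One-way ANOVA in the cohort report is a labeled stock statistic
  (scipy), provided for orientation only; n = 2 sections/group in the
  default design is far below inferential power.
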