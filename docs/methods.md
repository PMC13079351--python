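# Methods

`fibernuc` quantifies cell-nuclei deposits on ECMO membrane-lung fibers
from DAPI fluorescence images. This note records the models and
procedures the package implements, the parameters that matter, and the
design choices made where the problem left the design open.

## Coordinate and geometry conventions

All coordinates are 0-based, half-open pixel indices, x = column,
y = row, origin top-left (the COCO convention). A pixel (x, y) occupies
the unit square [x, x+1) × [y, y+1). Instance areas are raw foreground
pixel counts — integers, directly checkable against per-pixel oracles —
not polygon areas.

COCO polygon export traces the boundary of the union of a mask's pixel
squares (vertices on pixel corners), so an axis-aligned rectangle
exports as exactly 4 corners after collinear-vertex pruning and
re-rasterization (a pixel is set iff its center lies inside the
polygon) reproduces the mask exactly. Masks with holes export the outer
contour only; nuclei are effectively simply connected, so this is a
stated, deliberate simplification. Self-intersecting or zero-area
polygons are rejected on import.

Two overlap measures are used: IoU (intersection over union) for
evaluation and NMS, and IoS (intersection over the *smaller* area) for
merging and clustering. IoS ≥ IoU always; both are symmetric and
in [0, 1].

The "radius" of an arbitrarily shaped nucleus is its area-equivalent
circle radius `r = √(area/π)`.

## Tiling

Full-scale images are sliced into `tile_size` × `tile_size` tiles
(default 400 px) with fractional overlap `overlap_fraction` (default
0.2, i.e. an 80-px shared band). Tile starts advance by
`stride = round(tile_size·(1−overlap))`; when the next tile would
overrun the image border, one final tile is emitted flush with the
border (shifted back, never padded, never partial) and the row/column
ends. This rule yields exactly 7 × 7 = 49 tiles for a 2,048² image —
and hence 8,330 tiles for 170 such images and 2,107 for 43, matching
the dataset-scale bookkeeping the pipeline must reproduce.

When slicing *annotations*, each instance is clipped into every tile it
intersects; a clip retaining less than `min_visible_fraction` of the
original instance area (default 0.1) is dropped, so meaningless slivers
at tile edges do not become training or evaluation instances. The
default is our choice — the overlap band exists precisely so each
nucleus is fully visible in at least one tile — and is exposed in the
configuration.

## Detection fusion

Raw per-tile detections pass through a fixed cascade:

1. **Score filter** — detections scored *below* `score_threshold` are
   discarded; a score exactly at the threshold is kept. The default
   operating point for trained network backends is 0.98; the toy
   detector registers its own calibrated default of 0.5 (its score
   scale tops out near 1.0 only for high-contrast components, so a 0.98
   cut would discard nearly everything it produces).
2. **NMS** (per tile, on boxes) — greedy by descending score, ties
   broken by lower instance id; a detection is suppressed when its box
   IoU with an already-kept detection exceeds `nms_iou_threshold`
   (default 0.5, class-agnostic; boxes are used because per-tile
   duplicates are cheap to compare and exact mask geometry matters less
   within one tile).
3. **Global shift** — tile-frame detections move to the image frame by
   adding the tile origin.
4. **NMM** (across tiles, on masks) — greedy by descending score; the
   current survivor absorbs every remaining detection whose mask IoS
   with it is ≥ `nmm_ios_threshold` (default 0.5). The merged mask is
   the **union** (preserving total deposit area, the headline
   quantity), the score the maximum, the box the tight box of the
   union. Merged survivors are re-tested against remaining candidates
   until stable, so chains of pairwise-overlapping fragments collapse
   into one instance; a `single_pass` flag disables the re-test for
   comparison (candidates are then tested against the original seed
   mask only).

NMM is idempotent, never increases the instance count, and conserves
the union-of-masks area exactly. The full reconstruction is
deterministic and independent of tile processing order (tiles are
sorted by index and detections re-indexed before merging).

## Clustering

Nuclei pairs (i, j) are connected when **either**

- their mask IoS exceeds `overlap_threshold` (default 0.02, i.e.
  "> 2 % overlap" measured against the smaller mask — the only
  well-defined reading given a single named overlap measure), **or**
- their centroid distance is within the adaptive threshold

      T(i, j) = α · (r_i + r_j) / (1 + β · ρ_ij)

  with `r` the area-equivalent radii, `ρ_ij` the mean of the two
  nuclei's local densities, α = 1.2 and β = 0.05 by default.

The functional form of T is ours: it must grow with nucleus size and
shrink with crowding, and the defaults are set so that two touching
average nuclei (r ≈ 10 px at 40× magnification) link (T = 24 px for two
r = 10 nuclei in an empty neighborhood) while dense fields are not
fused into one giant component. Both parameters, the overlap threshold
and the density definition are configurable.

Clusters are the connected components of size ≥ 2 of this graph,
numbered 1, 2, … by their topmost-then-leftmost member centroid (a
deterministic convention; only *sequential* numbering is semantically
required). Isolated nuclei carry cluster id 0. Per cluster the package
reports member count, union area of member masks (overlaps counted
once), the count ratio against all detected nuclei in the image, and
the area ratio against the full image.

For efficiency the pairwise rule is evaluated only on candidate pairs
from a KD-tree query within a conservative radius (the largest possible
T, or twice the largest box diagonal for mask overlap); a brute-force
transitive-closure oracle in the test suite confirms the pruning is
exact for scenes up to 50 nuclei.

## Morphometry

Per nucleus: area (pixel count), centroid (mask center of mass, in
pixel-index coordinates), perimeter, eccentricity, mean image intensity
under the mask, local density (number of other centroids within
`vicinity_radius`, default 100 px ≈ five typical nucleus diameters at
40×), and nearest-neighbor centroid distance (missing for a lone
nucleus).

- **Eccentricity** comes from the moment-fit ellipse: with λ₁ ≥ λ₂ the
  eigenvalues of the covariance of foreground pixel coordinates,
  `e = √(1 − λ₂/λ₁)`; 0 is circular, → 1 elongated. On rasterized
  ellipses with semi-axes ≥ 8 px this matches the analytic value within
  0.02 (tested).
- **Perimeter** (default) is the length of the sub-pixel
  marching-squares contour at level 0.5. On a digitized disk this is a
  staircase-smoothed polygon whose length lies between the analytic
  circumference and the axis-aligned pixel-boundary length (8r) — a
  known property of contour-based perimeter estimates, pinned by the
  tests. A pixel-edge-count perimeter is available as an option.

## Synthetic scenes

The generator renders what the microscope sees on a clinically used
fiber: bright elliptical-to-crescent nuclei on a darker background,
with wide brightness variation (low to high DNA density), a fraction of
nuclei in overlapping groups, Gaussian blur, additive Gaussian noise
and an optional halo ring.

Defaults (all per-field, 8-bit intensity scale): 2,048 × 2,048 px
scenes with 180 nuclei (the typical per-image annotation count on
clinical fibers), radii 8–20 px, intensities 80–230 over background 20,
shape mix 50 % circular / 35 % elliptical / 15 % u-shaped, 30 % of
nuclei in clusters, blur σ = 1 px, noise σ = 4. U-shapes are crescents
(an ellipse minus a shifted inner ellipse, largest connected piece
kept) — the morphology that splits naive detectors into two instances.

Isolated nuclei are rejection-sampled to be pairwise mask-disjoint
(error after bounded retries when the packing is infeasible); clustered
nuclei are chained with center gaps strictly below the radius sum so
their masks overlap, which makes cluster membership exactly recoverable
by the clustering rule (a parameter-recovery test). Ground truth is the
pre-blur support of every rendered nucleus, so GT masks are exact by
construction. Scenes are bytewise deterministic for a fixed seed.

**What the generator does not emulate:** fiber texture and warp-thread
background structure, optical PSFs and extended-depth-of-field
compositing, contact-point ambiguity between crossing fibers, staining
artifacts, and realistic nucleus chromatin texture (nuclei are rendered
with uniform intensity). Passing pipeline tests on synthetic scenes
therefore validates the *post-detection* machinery — tiling, fusion,
clustering, morphometry, evaluation — not detection performance on real
micrographs, which depends on the trained backend that is out of scope
here.

The bundled **toy detector** (Otsu threshold → connected components →
components < 30 px² dropped; score rising with contrast above
threshold) is a deliberately simple deterministic reference backend. On
noise-free scenes of well-separated bright nuclei it recovers ground
truth exactly (tested end-to-end: count recovery is exact, union-area
error < 5 %, mask AP@0.5 = 100). Its failure modes are the realistic
ones: dim nuclei sharing a tile with bright ones fall below the Otsu
threshold, and touching nuclei merge into one component. End-to-end
recovery tests therefore use noise-free, non-touching, bright scenes
(intensities 150–230); the recovery property is a statement about the
fusion/analysis chain, not about thresholding.

## Evaluation

- **Per-tile statistics**: nuclei count and relative area (union of
  masks over tile area — overlapping instances counted once, the same
  convention as everywhere else in the package) per tile, with mean and
  median summaries.
- **Mann–Whitney U**: two-sided; exact when both samples are ≤ 20
  without ties, otherwise the normal approximation with tie and
  continuity correction (scipy's implementation stands behind this
  surface; an independent full-enumeration oracle in the test suite
  checks the exact mode for n ≤ 7). Comparisons are pooled per-tile
  distributions, not tile-paired.
- **Expert deviation**: `100·|predicted − reference|/reference`,
  reported to one decimal, with the *median* of independent expert
  counts as the reference.
- **AP@0.5**: COCO-convention average precision at a single IoU
  threshold, on boxes or masks — predictions sorted by descending score
  (ties by id), greedy matching to the highest-IoU unmatched ground
  truth, 101-point interpolated precision, 0–100 scale, no area-range
  or max-detection filters. Undefined (reported missing) without ground
  truth.

## Problem sizes and numerical choices

Test and acceptance runs use scenes of 512²–1,024² px with 15–45 nuclei
and oracle comparisons on rasters ≤ 64² or sets ≤ 50 instances — sizes
at which every brute-force oracle is exact and fast while exercising
multi-tile grids (a 1,024² scene has 16 tiles, a 512² scene 4). The
acceptance script's end-to-end pass uses a 1,024² noise-free scene with
45 nuclei, scaling the full-scale 2,048²/180-nucleus default by area.

Ties in NMS, NMM and AP are broken by lower instance id; cluster
numbering and CSV row order are fixed by stated conventions — all
outputs are bytewise reproducible for a fixed configuration and seed.
16-bit images are converted to 8-bit as `v8 = round(v16/257)` (half-up,
monotone, surjective); a per-image min–max stretch is offered as an
option but is not the default because it would make mean intensities
incomparable across images.

## Known limitations

- Polygon export drops holes (outer contours only).
- The adaptive-distance formula is a modeling choice; only its inputs
  (radii, local density) are dictated by the problem.
- The toy detector does not handle dim-next-to-bright nuclei or
  touching nuclei; it is a reference backend for exercising the
  pipeline, not a segmentation method.
- Headline detection metrics of trained networks (AP ≈ 94 on real
  validation tiles) require trained weights and annotated clinical data
  and are outside what the synthetic suite can or should reproduce.
- Runtime is single-process and deterministic; tile-parallel execution
  would require care only around NMM input ordering (inputs are sorted
  by score then id, so the merge is order-independent).
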