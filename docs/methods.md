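# Methods

## Problem setting

A ground rig photographs rice plots at roughly 0.2 mm/px, giving
6000 × 4000 px images with on the order of a hundred panicles each.
Object detectors accept inputs of a few hundred to ~1000 px per side;
downscaling the full image to that size erases small panicles. The
pipeline therefore detects on overlapping tiles and reconciles the
tile-level results geometrically. Everything in this package is that
geometry plus its evaluation; the detector itself is pluggable and no
network weights are included.

## Coordinate and box conventions

Boxes are continuous, 0-based and half-open: a box `[x_min, x_max) ×
[y_min, y_max)` has area `(x_max − x_min)(y_max − y_min)`. This makes
areas compose exactly under tiling and clipping and removes the ±1 px
ambiguity of inclusive pixel conventions. Pascal-VOC XML (the LabelImg
dialect) stores 1-based inclusive integers; the reader maps
`xmin → x_min = xmin − 1`, `xmax → x_max = xmax`, and the writer inverts
this. Degenerate (zero-area) boxes are representable — detectors can
emit slivers at tile borders — but every ratio indicator raises on
inputs where it would be 0/0, since failing loudly beats silently
propagating an arbitrary value.

## Tiling

Per axis of length `L`, tiles of side `t` are placed at origins
`0, s, 2s, …` with stride `s`, `n = ceil((L − t)/s) + 1` tiles, and the
final origin clamped to `L − t`. Clamping (rather than zero-padding)
never fabricates pixels, and because it can only increase the final
overlap it preserves the key guarantee: **any object with both sides
≤ t − s lies entirely inside at least one tile.** With the defaults
`t = 1056`, `s = 756` the overlap is 300 px — chosen to exceed the
large-panicle size at rig resolution — and a 6000 × 4000 image yields
8 × 5 = 40 tiles. "Stride" here means the step between origins;
overlap = tile − stride. Tiles are ordered row-major so results are
reproducibly ordered.

## Duplicate removal

For a box pair with intersection `I`, union `U`, and the smaller/bigger
member by area:

* `IOB = I / area(smaller)` — 1 iff the smaller box is contained in the
  bigger;
* `BOU = area(bigger) / U` — 1 iff the union coincides with the bigger
  box.

A pair is a *repeated detection* when `IOB > θ_IOB` and `BOU > θ_BOU`
(strict inequalities), and the smaller box is removed. Defaults are
`θ_IOB = θ_BOU = 0.8`: high enough that two distinct panicles with a
partially shared extent (IOB typically ≪ 0.8) are never merged, low
enough to absorb a few pixels of detector jitter on a clipped fragment.
Both thresholds are configurable; no canonical published values exist
for them.

Resolution order matters in containment chains (big ⊐ medium,
medium ⊐ small, but big ⊉ small): removing the medium box first spares
the small one, removing in the other order does not. The rule is
therefore defined with a canonical order — pairs are resolved
largest-surviving-box-first, with exact area ties broken by
lexicographic corner order (the lexicographically smaller corner counts
as the "smaller" box and is removed). The fast implementation is a
single largest-area-first sweep; `brute_force_dedup` reaches the same
fixed point by exhaustive rescanning and serves as an independent
cross-check in the tests.

Suppression is applied globally to the merged set rather than only
inside inter-tile overlap bands: the rule is a no-op on pairs that
cannot co-occur, and global application is simpler and robust to
ordering. Greedy NMS with IoU, GIoU (`IoU − (A_c − U)/A_c`, `A_c` the
smallest enclosing-box area) and DIoU (`IoU − ρ²/c²`, `ρ` the center
distance and `c` the enclosing-box diagonal) is provided as the
baseline family, visiting boxes in descending score with descending
area as the no-score fallback, default threshold 0.5.

## Pipeline

`count_panicles` chains plan → crop → detect → merge → suppress. The
detector contract returns boxes in original-tile pixel coordinates;
any internal resizing to the model's input size (e.g. 416 × 416) must
be inverted inside the adapter, which keeps the geometric pipeline
independent of the backend. Merged boxes are clipped to the image
bounds (edge tiles cannot produce out-of-image boxes, but adapters
might) and zero-area boxes are dropped before suppression. A detector
score cut-off, when wanted, belongs in the adapter; the oracle detector
assigns 0.95 to whole boxes and 0.6 to fragments so score-ordered NMS
behaves sensibly.

## Evaluation

Matching of detections to ground truth is greedy and one-to-one:
predictions in descending score (area as fallback), each taking the
unmatched ground-truth box of highest IoU provided IoU ≥ 0.5 (the
threshold is configurable and logged — there is no single canonical
matching rule for counting work). TP/FP/FN follow; TN ≡ 0 because
background is not a detection class. Metrics, all on the 0–100 scale:
MAPE over per-image counts (manual counts must be positive), Precision,
Recall, F (harmonic mean), Accuracy `(TP+TN)/(TP+TN+FP+FN)` which under
TN = 0 is the critical success index `TP/(TP+FP+FN)` and is provably
≤ min(Precision, Recall), and counting accuracy `P_c = N_cor/N_real`.
R² is the squared Pearson correlation of machine vs manual counts —
the R² of the fitted regression line, not of the identity line — so a
consistent proportional bias still scores 1.0; MAPE is the metric that
penalizes bias.

## Segmentation comparator

The alternative counting route consumes a binary panicle mask from any
segmentation method. The mask is cleaned by morphological opening then
closing (that literal order) with a square 5 × 5 element — the opening
removes speckle and thin bridges between touching panicles, the closing
repairs small holes; the composite filter is idempotent. Components are
labeled with 8-connectivity (panicle branches are thin and diagonal).
With `m` the median component area — lower median for an even count, to
keep the rule integer-friendly — a component of area `A > 2m` counts as
`ceil(A/m)` panicles (an occluded cluster), every other component as 1.
Worked example: areas (100, 100, 250) → median 100, the 250 px
component splits into 3, total 5. The rule is invariant to a global
rescaling of all areas and never counts fewer than the number of
components.

## Synthetic scenes and the oracle detector

`generate_scene` renders textured elliptical blobs on a noisy
green-brown background and returns the image, the blobs' tight
half-open bounding boxes as ground truth, and the union-of-supports
mask. Sizes are bimodal — small mode 30–60 px, large mode 150–290 px at
rig-like resolution, equal weight — because the whole-box/fragment area
disparity that separates IOB/BOU from IoU-NMS only arises when object
sizes vary widely; the large mode is kept below the 300 px overlap of
the default tiling so the whole-object guarantee holds for every
generated object. A configurable fraction of objects (default 0.2) is
placed touching an earlier object to emulate occluded clusters. A
placement whose bounding box would be near-contained in an existing
object's box (IOB > 0.7 and BOU > 0.7) is rejected and retried: a
panicle that thoroughly hidden is not annotatable as a separate object
by a human rater either, so well-posed ground truth excludes it. All
stochastic choices for a scene come from one seeded generator; equal
specs give byte-identical images.

The oracle detector replays ground truth per tile: a box fully inside
the tile is emitted exactly; a box cut by a tile edge is emitted as the
clipped fragment (the central hazard the duplicate-removal stage
exists for). Optional noise — per-detection drop probability, Poisson
spurious boxes per tile, uniform corner jitter — is drawn from a stream
seeded per (seed, tile origin), so results are deterministic and
independent of tile visiting order. What passing tests on these scenes
establish is the correctness of the geometry: tiling, merging,
duplicate removal and metrics. They say nothing about a real detector's
recognition accuracy on real canopies — no illumination variation,
leaf clutter, motion blur or label noise is simulated.

## Problem sizes in tests and the acceptance script

The unit suite exercises the pipeline on 900 × 700 scenes with a
352/252 tiling — the same overlap structure as the field geometry,
shrunk ~3× — and the acceptance studies run 2000 × 1500 scenes at the
full 1056/756 geometry with 12–50 scenes per study, sizes at which
every property checked is already fully expressed. The duplicate-removal
equivalence study uses 500 random box sets of up to 20 boxes with area
scales spanning more than an order of magnitude.

## Known limitations

* The pipeline's exact-recovery property requires all objects to fit
  within the tile overlap; objects larger than `tile − stride` can be
  detected only as fragments and may be double-counted or merged.
* The IOB/BOU rule cannot distinguish a repeated detection from a
  genuinely nested pair of distinct objects; at the default thresholds
  a panicle whose box is >80% contained in another's box is treated as
  a duplicate.
* The segmentation comparator's median-split rule assumes roughly
  unimodal panicle areas within an image; strongly bimodal sizes make
  it over-split large panicles.
* R² as squared correlation is blind to calibration; report it together
  with MAPE.
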