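# Methods

This note records the models, rules and numerical choices behind `qwaseg`,
and what the synthetic test bed does and does not demonstrate about real
wood-section data.

## Data model

A *label map* is a 2-D grid of non-negative integers: 0 is background, each
positive id is the lumen-pixel set of one cell instance.  Ids are normalised
to `1..N` (ascending original order) on construction, so downstream code can
index per-id arrays densely.  Coordinates are 0-based `(row, col)` with the
origin top-left; bounding boxes store inclusive min/max pixel coordinates
(`x` = column, `y` = row).  Annotations are accepted either as drawn binary
masks — alpha channel wins when present, since masks are typically drawn on a
transparent layer; otherwise any nonzero-luminance pixel is foreground — or as
16-bit single-channel label maps, the package's lossless on-disk dialect.
Connected components default to 8-connectivity because hand-drawn strokes
produce diagonal bridges; 4-connectivity is available everywhere the
componentisation is exposed.

## Instance matching

Matching similarity is IoU.  The matcher proceeds in five steps:

1. **Border exclusion** (default on). Ground-truth cells touching the outer
   frame are excluded as *incomplete*; predictions are excluded if they touch
   the frame or if more than κ of their own area lies inside an excluded cell,
   so border clipping can never manufacture false positives.
2. **Greedy one-to-one assignment** of candidate pairs with IoU ≥ τ, sorted
   by descending IoU with (gt id, pred id) tie-breaks.  At the default
   τ = 0.5 a prediction can exceed τ against at most one ground-truth cell
   and vice versa, so the greedy result equals the exhaustive optimal
   assignment (verified against a brute-force oracle in the tests); the
   deterministic tie-breaks only matter for user-lowered thresholds.
3. **Split detection**: for an unmatched true cell G, the unmatched
   predictions with more than κ of their own mass inside G are its fragments;
   if there are ≥ 2 of them and their union reaches IoU ≥ τ with G, the
   fragments are FP `disconnected_positive` and G is FN
   `disconnected_victim`.
4. **Merge detection**, the mirror image: unmatched true cells mostly covered
   by one unmatched prediction whose union reaches IoU ≥ τ become FN
   `merged_negative`, the prediction FP `merged_prediction`.
5. Remaining true cells are FN `missed`; remaining predictions FP `spurious`.

τ and κ both default to 0.5.  τ = 0.5 is the uniqueness threshold and the
community convention for instance matching; κ = 0.5 makes "majority of its
own mass" literal.  Both are configurable (`MatchConfig`), and every category
assignment is exclusive: each non-excluded instance lands in exactly one
bucket, which the partition invariants assert on every test scene.

Note that published per-cell examples of badly segmented lumens (e.g. a
prediction covering 28 % of its cell) imply matches *below* IoU 0.5 — an
operator matching by eye or by a looser overlap rule will accept pairs the
default τ rejects.  Per-cell pixel metrics therefore accept any overlapping
pair directly, and the matcher's τ can be lowered when reproducing such
tables.

## Metrics

`precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`, `F1` their harmonic mean.
Degenerate denominators yield 0 by convention (conservative: an empty
prediction scores 0, not undefined).  All arithmetic is double precision;
2-decimal rounding exists only in display formats (CSV/JSON store full
precision).  Aggregation over images is exposed in three modes — macro
(mean of per-image statistics), micro (pooled counts), per-cell (mean over
matched cells' pixel statistics) — because "average" is ambiguous across
published tables; none is asserted as canonical.  The missed-cell size
histogram uses 10 equal-width bins over the observed ground-truth areas by
default (quantile binning available).

## Error maps

One colour per category; anchored choices are dark-green FN pixels, orange FP
pixels, blue missed cells.  Painting order (later wins): incomplete < merged
cells < missed cells < matched-cell TP/FN/FP pixels < split fragments <
spurious predictions.  Only the categories with whole-instance fills are
painted as fills; split victims and merged predictions are legible from their
counterparts.  `color_census` inverts an unblended render exactly and raises
on any off-palette colour, which is why the legend strip is an explicit
opt-in (`add_legend`) rather than always appended, and why census requires
`base=None`: blending and legend text necessarily introduce off-palette
colours.

## Tiled pipeline

Tiles default to 1000×1000 px (2000×3000 preset for ring-porous wood, whose
earlywood vessels must fit inside one tile) with 100 px overlap — roughly the
largest conifer tracheid diameter at typical magnifications, so any cell is
seen whole by at least one tile unless it is wider than the overlap.
Trailing tiles are shifted, not shrunk.  Stitching places instances in global
coordinates and accepts them in priority order (unclipped before clipped,
then by backend confidence): a candidate overlapping an accepted instance at
IoU ≥ 0.5 is a duplicate and is dropped; a tile-edge-clipped candidate
overlapping an accepted unclipped instance yields to it; two clipped views of
the same cell are merged by pixel union.  Output ids are renumbered in raster
order, so stitching is deterministic.

Backends are anything with `segment(image) -> (LabelMap, per-id confidence)`.
Backends may additionally expose `calibrate(image)`; `run_tiled` calls it
with the whole image before tiling.  This exists because global statistics do
not commute with tiling: a per-tile automatic threshold can land between
tissue and ray tones on tiles whose histograms lack some intensity mode,
promoting rays into the lumen class only in the tiled run.  Calibration fixes
such statistics once per image.

The dual-resolution scheme for ring-porous wood runs the backend at native
resolution (fine pass) and at 1/2 resolution with the same tile size — twice
the field of view — for the large vessels (coarse pass), upsamples the coarse
labels, and merges: fine instances below the size gate and coarse instances
at or above it are primary; the complementary instances are fallback, kept
only where no primary duplicate (IoU ≥ 0.5) exists, so neither object class
is silently dropped when one pass fails.  Cross-pass duplicates resolve by
confidence.  The size gate defaults to 2000 px, between the latewood and
earlywood vessel area modes at the default scales.

The bundled `ThresholdWatershedBackend` is a classical reference method:
grayscale → 3-class multi-Otsu keeping the brightest class (walls / tissue /
lumen; falls back to bimodal Otsu on simple histograms) → opening (radius 1)
→ connected components → distance-transform watershed seeded by the plateaus
where the distance reaches 0.6 of each component's maximum (one seed per
convex lumen, two for touching lumens with a neck) → area filter (min 12 px).
Confidence is the instance's distance-peak height over the image maximum.

## Synthetic scenes

The generator draws caricature sections sufficient to exercise every
evaluator and pipeline path — dark walls around bright lumens on mid-tone
tissue with additive Gaussian noise (σ = 5 grey levels) — not photorealistic
histology.  Default canvas 384×384 px (448×448 ring-porous).

* **conifer**: a lattice of rectangular tracheids; within each ring the cell
  width shrinks linearly to 0.45 of the earlywood width while walls thicken
  from 2 to 4 px, so lumen areas decrease monotonically along each ring — the
  property the size-class histogram tests rely on. Rings hold 7–10 cell
  columns; rows are 20–27 px tall.
* **diffuse**: ~60 vessels of radius 8–13 px placed without overlap over a
  fibre-speckled matrix; 15 % of vessels get thin scalariform bars drawn over
  the lumen (image only — the vessel remains one ground-truth instance, the
  classic trap where bar-split conduits must not count as two cells).
* **semidiffuse**: as diffuse with a gradual within-ring radius decline.
* **ringporous**: per ring, a band of large earlywood vessels (radius
  19–26 px) and scattered small latewood vessels (radius 4–7 px); the
  bimodal size distribution drives the dual-scale pipeline tests.

Non-targets (rays, pit chambers, resin canals, fibres, bark) are drawn in the
image but never enter the label map.  Artifact injection (dust, folded
tissue, stains, paraffin, broken walls, blur, illumination gradients)
modifies the image only and records every region with the ground-truth ids it
covers: the annotation marks true lumens regardless of image quality.

What the scenes do **not** emulate: real staining variability, cell-shape
irregularity, wall damage and debris continua, out-of-focus optics, scanner
stitching artifacts beyond the catalogued types.  A method scoring perfectly
here can still fail on slides; the synthetic bed validates the *evaluator and
pipeline machinery*, and provides a regression floor (the classical baseline
recovers ≥ 0.9 of clean conifer tracheids) rather than evidence about any
segmentation method's field performance.

## Perturbation oracle

`perturb_labelmap` plants exact error counts, constructed so the matching
rules at τ = κ = 0.5 classify them unambiguously:

* deletions → `missed`; spurious discs (radius 3–5 px) are placed ≥ 2 px from
  every true cell and off the border → `spurious`;
* splits cut a cell with a straight band through its interior, sized so every
  fragment is ≤ 0.45 of the parent (no fragment can reach IoU 0.5 alone) and
  at most 0.35 of the area is removed (the fragment union always reaches it);
* merges bridge two same-size-class cells (area ratio ≤ 2) with a background
  corridor that is widened until each partner's IoU with the union is < 0.5
  while the pair's joint IoU stays ≥ 0.5 — verified per pair, with candidate
  pairs searched by similarity and proximity;
* erosions/dilations shift matched-cell boundaries by a radius while keeping
  IoU ≥ 0.55 (so the cell stays matched and only pixel metrics move);
  dilations never invade other cells or the border.

Cells are drawn from the interior (non-border) pool with disjoint subsets per
operation; unsuitable cells are skipped and returned to the pool, and
`PlanInfeasibleError` is raised only when the scene truly cannot host the
plan.  Closure — the evaluator reproducing every planned count exactly — is
asserted over 100 seeded scenes in the test suite and recomputed by the
acceptance script.

## Problem sizes and determinism

Test and acceptance runs use 384–448 px scenes (about 40–260 cells each),
256 px tiles with 64 px overlap, 100-scene closure sweeps, 200-map matcher
comparisons and 50-scene duality sweeps: large enough that every code path
and category occurs many times per sweep, small enough for interactive runs.
All randomness flows through `numpy.random.default_rng` seeds carried in the
configs; every public operation is bit-reproducible for fixed inputs, which
the determinism tests assert.

## Known limitations

* The split/merge sub-categorisation is this package's operationalisation of
  informally described error classes; other tools may bin borderline cases
  (e.g. a fragment union at IoU 0.49) differently.
* Greedy matching is only provably optimal for τ ≥ 0.5.
* Stitching resolves conflicts by confidence; backends emitting uniform
  confidences fall back to tile order for exact duplicates (deterministic but
  arbitrary).
* µm² calibration is a single scale-factor pass-through in reports; no
  optical model is applied.
* The DCNN-side of the comparison is out of scope: `qwaseg` evaluates and
  orchestrates segmenters, it does not train them. The published training
  hyperparameters are recorded as documented constants
  (`reporting.DCNN_REFERENCE_CONFIG`) for adapter authors and are never used
  in computation.
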