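# Methods

This document describes the measurement model, the algorithms, every tuned
parameter with its rationale, and how the whole chain is validated.

## 1. Image model and geometry

A confocal frame is a 2-D array of reflectance intensities in `[0, 1]` with
a known physical field of view.  The reference geometry is 384 × 384 px over
400 × 400 µm: pixel size 400/384 ≈ 1.0417 µm, field area 0.16 mm².  All
physical quantities (lengths, densities, prune thresholds) are computed in
micrometres from the stated field size, never from pixel counts alone, so
any frame geometry works as long as pixels are square (enforced at load).

Integer images are rescaled by their dtype's full range (255, 65535);
floating-point images are accepted as-is if already within `[0, 1]`,
otherwise rescaled by their maximum.  RGB frames are converted to luminance
(ITU-R BT.601 weights) before rescaling.  A plain-text sidecar
(`<image>.size.json`) carries the physical width/height so a frame round
trips losslessly through PNG/TIFF; multi-page TIFF stacks carry an
inter-slice spacing as well.  SNP slice selection from a through-focus
stack picks the slice with the strongest ridge response (summed Sato
vesselness), which prefers the fibre-rich subbasal plane over the brighter
but texture-less epithelial layers.

## 2. Segmentation

Pipeline (all steps skipped when `mask_passthrough=True`, in which case the
input is simply thresholded at its midpoint — used to feed known masks
straight to the graph stage):

| step | operator | parameter | default | rationale |
|---|---|---|---|---|
| background flattening | white top-hat | `tophat_radius_px` | 8 | structuring disk larger than any fibre width (≤ ~6 px) but smaller than illumination gradients |
| contrast stretch | percentile rescale | fixed 1st/99th | — | robust to hot pixels; makes hysteresis thresholds comparable across frames |
| ridge enhancement | Sato vesselness | `scales_px` | (1, 2, 3) | fibre half-widths of roughly 1–3 px at the reference geometry |
| thresholding | hysteresis | `low`, `high` | 0.10, 0.25 | high threshold seeds only on confident ridge cores; low threshold grows them along dim fibre tails without admitting background |
| smoothing | binary opening | `smooth_radius_px` | 1 | removes 1-px noise protrusions that would become false spurs |
| speck removal | component filter | `min_component_px` | 30 | a real fibre fragment at minimum width (~2 px) and minimal length (~12 µm) covers well over 30 px; anything smaller is noise |
| width trim | core + backbone | `core_fraction` | 0.7 | see below |

The Sato filter is computed on a reflect-padded copy (pad =
⌈4 · max scale⌉ + 1 px, cropped afterwards) because the filter's internal
Gaussian derivatives otherwise break rotational symmetry at the frame
border; with padding, a 90° image rotation changes the response only at
machine precision.

**Width trim.**  Hysteresis segments the full bright halo of each fibre,
which is wider than the true fibre profile and biases `component_pixels`
and, through skeleton geometry, total length upward.  A fibre's cross
profile is approximately Gaussian with its half-width as σ, so the true
edge sits at exp(−½) ≈ 0.61 of the local peak; optical blur raises the
observed edge fraction to roughly 0.7.  The trim keeps mask pixels brighter
than `core_fraction` × (local maximum over a 5 px window), then unions the
skeleton of the untrimmed mask back in as a connectivity backbone so the
trim can never disconnect a fibre, and finally re-applies the small
component filter.

## 3. Skeletonisation and graph

The mask is thinned with Lee's 3-D-capable thinning (`skimage`
`skeletonize(method="lee")`), which on this data produces straighter medial
axes and cleaner bar ends than the Zhang–Suen variant (verified against the
synthetic oracle: both give exact counts, Lee gives slightly lower length
discretisation error).

The skeleton becomes a graph:

- **Pixel adjacency** is 8-connected, with redundant diagonal shortcuts
  removed (a diagonal step is dropped when the two pixels already connect
  through a shared orthogonal neighbour), so chain lengths are not double
  counted.
- **Nodes** are pixels of degree ≠ 2: degree ≤ 1 pixels are endpoints,
  degree ≥ 3 pixels form branch points (adjacent branch pixels are merged
  into one junction).  Endpoints within `BORDER_BAND_PX = 3` of the frame
  edge are classified as **border crossings** (connectivity points) rather
  than free endings.  The band is 3 px, not 1, because thinning retracts a
  fibre tip that touches the border by about one pixel orthogonally and up
  to two pixels diagonally.
- **Junction loop collapse** (`loop_um = 6`): thinning sometimes resolves a
  single anatomical junction into two nearby branch pixels joined by a tiny
  edge, or into a small triangular loop; branch–branch edges shorter than
  6 µm are contracted so each junction counts once.  6 µm is larger than
  any thinning artefact (≲ 3 px ≈ 3 µm) and smaller than any real
  inter-junction fibre in the model (minimum edge 12 µm).
- **Spur pruning** (`prune_um = 5`, settable to 0): terminal edges shorter
  than 5 µm whose free end is an interior endpoint are removed and the
  graph rebuilt; these are thinning artefacts of residual mask-width bumps
  and would otherwise inflate the single-fibre count.  Border-touching
  edges are never pruned.
- **Edge length** uses the chain code: orthogonal step = 1 pixel size,
  diagonal step = √2 pixel sizes.  Consequently total length divided by
  skeleton pixel count is always within `[pixel, √2 · pixel]` — a property
  asserted in the tests.
- **Invariant**: every skeleton pixel is assigned to exactly one node or
  chain (checked internally), so metrics cannot silently drop geometry.

## 4. Metrics

Nine parameters per frame (definitions in the README table).  Nerve fibre
density is the exact identity

```
NFD [mm/mm²] = (total_fibre_length_um / 1000) / area_mm²
```

e.g. 1578 µm in 0.16 mm² → 9.863 mm/mm² (the package's worked example).
`normalize_per_mm2` rescales the extensive counts (pixels, components,
fibres, length, connectivity points, branches) by 1/area; intensive
quantities (density, average length) are untouched, and double
normalisation is rejected.  Reported values are rounded half-away-from-zero
(3 decimals for lengths and densities, 2 for doses, integers for
percentages) via `decimal.Decimal`, not banker's rounding.

## 5. Longitudinal analysis and dosimetry

Corneal zones are `applicator` (adjacent to the plaque), `central`, and
`distal`; visits are baseline, day 3, months 1, 4 and 7.  A series'
percent-of-baseline value at visit *t* is `round(100 · x_t / x_baseline)`;
a baseline of zero or duplicate visit rows are errors.  Replicate
aggregation returns mean and population-style sample SD; quantiles use
linear interpolation.  Cochet–Bonnet aesthesiometry readings are filament
lengths in {0} ∪ [55, 60] mm (intermediate lengths are not physically
produced by the instrument's 0.5-cm steps below full extension and are
rejected); sensation percent-of-baseline uses the same rounding rule, e.g.
54/58 mm → 93 %.

Corneal surface doses derive from a prescribed scleral apex dose via fixed
isodose fractions per zone: adjacent conjunctiva 0.44 %, central cornea
0.12 %, distal cornea 0.015 %, rounded to 2 decimals in Gy.  Treatment
duration is prescribed dose / dose rate.  Bundled reference tables
(`src/snpquant/data/`) hold the study cohort's group means per metric, zone
and visit, its sensation series, and its per-patient prescribed doses with
the published per-zone values for cross-checking.

Two cells of the published per-patient table differ from the recomputed
values by one unit in the last printed digit (patients 5 and 7, adjacent
zone: 2.31 vs 2.32 and 4.70 vs 4.71) — consistent with independent rounding
in the source; the acceptance test encodes exactly these two tolerances and
requires all other cells to match exactly.

## 6. Synthetic generator

`generate_scene` grows `n_trees` (default 8) fibre trees, each entering at
a random border point and performing a smoothed random walk: step 1 µm,
per-step heading jitter σ = `tortuosity` (0.12 rad), branch probability
0.02 per step up to 4 walkers per tree, random stopping probability 0.003
per step.  Constraints that keep the truth graph unambiguous:

- fibres of *different* trees keep ≥ `min_separation_um` = 8 µm apart, and
  a walker keeps ≥ 6 µm (0.75 ×) from its *own* tree's older points,
  ignoring its most recent 15 steps (so it cannot collide with itself) —
  these guarantee distinct fibres never merge in the rendered mask;
- a freshly spawned branch ignores a window of 13 stored points around its
  spawn point for its first 25 steps (`_SPAWN_WINDOW`,
  `_SPAWN_BALL_STEPS`), letting it leave the junction without tripping on
  its parent, while still being repelled by everything else;
- after a junction both walkers run straight for 12 steps and cannot branch
  again for 15 steps, so junctions are cleanly separated (minimum edge
  12 µm, border margin 10 µm for interior endpoints).

Rendering draws each fibre as a Gaussian-profile stroke (σ = half-width,
width 2.1 µm, peak 0.6–1.0) over background 0.15, then applies Gaussian
blur (0.8 px), multiplicative speckle (σ = 0.2) and additive noise
(σ = 0.05) — chosen to resemble confocal frames: bright fibres of 2–3 px
apparent width over a speckled mid-grey background.  The truth mask marks
pixels within the fibre half-width of a centreline.  `truth_metrics`
computes all nine parameters analytically from the polylines (length as the
exact polyline sum), so every scene is a labelled test case.  Everything is
deterministic per seed (`numpy` `SeedSequence`).

Limits: the generator produces tree topologies only (no anastomoses or
crossings), constant width per scene, and uniform background — adequate for
validating the measurement chain, not a biophysical model of nerve growth.

## 7. Validation

Three layers, all in the test suite and the acceptance script:

1. **Noiseless oracle** — the truth mask is fed directly to the graph stage
   (`mask_passthrough`, `prune_um=0`).  Across 50 seeds (140 in
   development) all four count parameters match the analytic truth exactly
   and total length agrees within 5 % (observed maximum ≈ 4.2 %, the
   chain-code discretisation floor).
2. **Identities** — NFD × area = length/1000 to 1 × 10⁻¹²; length per
   skeleton pixel within `[pixel, √2 · pixel]`; skeleton ⊆ mask; pixel
   conservation in the graph.
3. **Noisy recovery** — the full pipeline on 20 default-noise renders
   recovers nerve fibre density within ±15 % of truth on every seed
   (observed mean +1.7 %, max 4.0 %).  Count-type parameters are reported
   but not toleranced on noisy input: speckle can merge nearby trees and
   split dim tails, which changes counts while barely moving total length.

## 8. Numerical and engineering choices

- Established primitives are used rather than reimplemented: `skimage`
  Sato filter, hysteresis threshold, morphology, thinning, labelling;
  `scipy` filters; `pandas` for tables.  The graph builder and chain-code
  measurement are bespoke because the pixel-accounting invariant and
  junction handling are the point of the package.
- All randomness flows through explicit seeds; repeated runs are
  byte-identical (asserted for the CLI).
- No binary fixtures: synthetic scenes are generated on demand, reference
  data ship as CSV.
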