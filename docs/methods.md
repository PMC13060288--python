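# Methods

## Problem setting

A CosMx SMI experiment is acquired as a grid of fields of view (FOVs). The
AtoMx export describes everything in FOV-local pixel coordinates: cell
boundary polygons, per-molecule transcript positions, and cell centroids. The
FOV position table gives each FOV's global top-left corner in pixels.
`smibridge` performs three operations on this export: whole-slide mosaic
reconstruction, local-to-global coordinate mapping with GeoJSON serialization,
and spatial expression visualization. Throughout, coordinates are 0-based
pixels, origin at the image top-left, y increasing downward; millimetre
position files are converted on read with an explicit pixels-per-millimetre
scale (never guessed), and an optional y-flip handles stage axes that point
up.

## Mosaic reconstruction

Placement is purely position-driven: no registration, flat-field correction
or seam blending is attempted, because the instrument's positions are already
in a common pixel frame. The canvas bounding box is the min/max over all tile
extents; each tile's integer offset is `round(position − (min x, min y))`, so
the offset table always has minimum 0 on both axes and is invariant under
translation of all positions.

Scalability comes from a memory-mapped (Big)TIFF canvas: tiles are read in
batches (optionally with joblib threads) and written in ascending FOV order,
so peak RAM is one batch of tiles regardless of FOV count. Ascending-order
writes also make the overlap rule deterministic: **the larger FOV id wins on
every contested pixel**. The instrument's nominal grid is gap- and
overlap-free, so this rule only matters for custom layouts, but determinism
is required for testing; the stitcher is verified bit-identical to a naive
dense-placement reference on all grids up to 3 × 3 and on a deliberately
overlapping pair.

The overview is a block-mean (area-average) downsample at factor 20 by
default. Block mean rather than stride subsampling was chosen because it is
alias-free and has a closed-form oracle (edge blocks are averaged over the
pixels actually present, so output dims are `ceil(dims / factor)` and a
constant image stays exactly constant). The overview is computed strip-wise
from the memmap so the full canvas is never resident.

## Coordinate mapping and GeoJSON

The transform is `global = local + integer FOV offset`. Plain float64
addition is not bit-exactly invertible for arbitrary coordinates
(`(x + 4256) − 4256 ≠ x` once the sum rounds), so all coordinates are
maintained on a fixed **1/256-px subpixel grid**: readers snap on input, and
the transforms snap their arguments. On that grid the addition is exact in
float64, the round trip is bit-exact, and every emitted GeoJSON vertex minus
its FOV offset reproduces the input vertex exactly. The 2⁻⁹-px quantization
is orders of magnitude below the platform's optical resolution.

GeoJSON follows the property dialect QuPath v0.5 imports: cells as closed
`Polygon` features with `objectType: "cell"`, the cell id under `name`,
`classification: {name, color}` only when a cell type is known (no
placeholder class), and `isLocked: true` to protect imported segmentations;
transcripts as **one `MultiPoint` per gene over the whole slide** with
`objectType: "annotation"`. Per-gene grouping keeps the feature count equal
to the number of genes rather than the number of cells; the transcript-to-cell
association is preserved losslessly as an optional `cell_ids` list aligned
with the points. Cells with fewer than 3 distinct vertices cannot form a
polygon and are dropped into a returned skip report rather than raising.
Feature order is sorted cell id, which makes output byte-identical for any
batch size. Winding order is not enforced (target viewers accept either);
coordinate order is `[x, y]` in pixels with no CRS member.

Colors come from a fixed 12-color categorical cycle assigned by sorted label,
user-overridable — determinism again.

## Visualization

Tissue detection on the overview: grayscale = channel mean, Gaussian blur
(default sigma 2 px at overview resolution — small enough not to erode
structures at 1 px ≈ 20 full-resolution px, large enough to suppress
speckle), then Otsu's threshold with tissue on the bright side, as
fluorescence foreground is bright on a dark field. The mask is recolored with
the user's tissue color over a blanked (black) background. A uniform overview
leaves Otsu undefined; the mask is then empty and a warning is issued.

All overlays share one placement transform: whole-slide coordinate divided by
the downsample factor, kept at full precision and rasterized only at draw
time. Cell-level expression uses a perceptually uniform sequential colormap
(viridis) min–max normalized per figure; a degenerate range (all counts
equal) maps to mid-scale. FOV-level expression is the arithmetic mean of the
gene's counts over the cells of each FOV; FOVs with no cells are excluded
from the summary and reported separately, and expression rows that cannot be
assigned to a FOV (cell absent from metadata) are an error, not a silent
drop. Figures are written as PNG at fixed DPI with sorted legends.

## Large transcript tables

Transcript files can reach millions of rows. `read_transcripts` scans the
CSV in record batches (pyarrow incremental reader) and applies the gene
filter per batch before concatenation, so the peak working set is
proportional to the filtered output plus one read batch, not to the file.
The streamed and in-memory paths return row-identical frames and both are
tested.

## Synthetic export generator

The generator emulates the export's *format and geometry*, not tissue
biology. Defaults are the reference fixture: a 2 × 2 grid (4 FOVs) of
4256 × 4256-px, 2-channel, 16-bit tiles at exact tile-size multiples
(gap-free, overlap-free, which makes the stitching oracles exact). Per FOV,
50 cells with radii 40–80 px are placed uniformly, rejecting overlaps
(cells may touch; 1000 failed attempts means the density is infeasible and
is an error); boundaries are regular 12-gons; types are drawn from a fixed
3-label set. Tiles carry one Gaussian blob per cell (peak 20000 above a
Poisson noise floor of 100, sigma = radius/2) — with non-overlapping cells
the blob peak is the pixel nearest the centroid, which the end-to-end test
exploits (centroid mapped through the post-stitch table lands within 1 px of
the canvas peak). Transcript counts per cell per gene are Poisson with mean
5, scattered uniformly in the polygon's inscribed circle so every molecule
is inside its cell; the expression matrix is *defined* as the per-cell
transcript row counts, making cross-file consistency exact by construction.
A `small` preset (256-px tiles, 20 cells/FOV, radii 8–16 px) keeps the test
suite fast; the full-scale preset is exercised by the acceptance checks.
Fixed seed ⇒ byte-identical directory (independent, reproducible RNG streams
per FOV and purpose).

What passing on synthetic data does **not** show: robustness to real-world
illumination gradients, segmentation errors, overlapping or irregular cells,
spatially autocorrelated expression, or vendor header drift beyond what
`ColumnMap` expresses.

## Numerical and degenerate-case choices

- Non-integer FOV positions are rounded to the nearest pixel before placement.
- Canvas background fill is 0 in the tiles' native bit depth (dark-field
  convention); bit depth is preserved end to end.
- The full-resolution output is promoted to BigTIFF above 4 GiB.
- Vertices exactly on a tile's far edge (nominal extent is half-open) are
  retained with a warning: segmentation tools commonly emit edge-touching
  vertices.
- A requested gene absent from the transcript table is a warning and an
  empty result, not an error — a typo should not kill a long pipeline run,
  and the warning names the gene.
- Tile shape is configurable (default 4256 × 4256) rather than hardcoded.

## Problem sizes

The test suite and the acceptance script use the small preset (256-px tiles)
for everything except fixture fidelity, which generates and stitches the
full-scale 2 × 2 × 4256-px fixture; stitching-oracle comparisons use 64-px
tiles on grids up to 3 × 3, the round-trip check uses 10⁴ random points, and
the streamed-filter check uses a 2 × 10⁵-row table.

## Known limitations

- Tailored to AtoMx-style directory layouts; other platforms' exports need
  at least a `ColumnMap` and possibly new readers.
- Visualization is performed at overview resolution; fine subcellular detail
  is not rendered.
- GeoJSON is write-only: reading annotations back into tables, polygon
  simplification and topology repair beyond ring closure are out of scope,
  as are registration, flat-fielding and seam blending in the stitcher.
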