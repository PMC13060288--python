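# smibridge

Bridge CosMx SMI / AtoMx spatial-transcriptomics exports to digital-pathology
workflows: reconstruct whole-slide images from field-of-view (FOV) tiles,
convert cell segmentation polygons and subcellular transcript coordinates into
the global slide frame, serialize them as QuPath-compatible GeoJSON, and render
spatial gene-expression overlays.

## Who this is for

Imaging-based spatial transcriptomics platforms such as the CosMx Spatial
Molecular Imager profile hundreds to thousands of RNA targets at subcellular
resolution, tiling the tissue section into a grid of FOVs. The vendor's AtoMx
platform exports, per experiment: multi-channel image tiles (4256 × 4256 px per
FOV), an FOV position table, cell-boundary polygon vertices and transcript
coordinates in **FOV-local** pixels, cell metadata with centroids, and a
cell × gene count matrix. None of these plug directly into histopathology tools.
`smibridge` is for translational researchers and pathologists who want to
inspect segmentation and expression in QuPath or similar viewers, on the
reconstructed slide.

## What it computes

- **Stitching.** The FOV position table gives each tile's global top-left
  corner (x_f, y_f). The mosaic canvas spans the bounding box
  [min x_f, max x_f + W) × [min y_f, max y_f + H), and each tile is copied
  verbatim to its integer offset (x_f − min x, y_f − min y) on a memory-mapped
  array, so peak RAM is bounded by one batch of tiles regardless of FOV count.
  Outputs: full-resolution TIFF, a block-mean overview downsampled by factor
  20, and the **post-stitch position table** — the key that converts any
  FOV-local coordinate to whole-slide space.
- **Coordinate transform.** (x_global, y_global) = (x_local, y_local) +
  (x_offset_f, y_offset_f). Offsets are integers and coordinates live on a
  1/256-px subpixel grid, so the transform round-trips bit-exactly.
- **GeoJSON bridge.** One closed `Polygon` feature per cell
  (`objectType: "cell"`, optional `classification {name, color}`, `isLocked:
  true`) and one `MultiPoint` feature per gene of interest
  (`objectType: "annotation"`), in the dialect QuPath v0.5 imports.
- **Visualization.** The overview becomes a background canvas via Gaussian
  blur + Otsu thresholding (tissue recolored, background blanked); cell types,
  transcript locations (single-gene mode `s` or multi-gene overlay `m`),
  cell-level expression on a continuous color scale, and per-FOV mean
  expression (mean over cells in each FOV) as color-coded tiles.
- **Synthetic export generator.** A seeded generator reproducing the full
  export layout — by default 4 FOVs on a 2 × 2 grid with simulated fluorescent
  cell signals — so the entire pipeline is testable without instrument data.

## Worked example

```bash
smibridge simulate --preset small --seed 11 --out demo/export
smibridge run --export demo/export --out demo/out
```

prints

```
wrote 4 FOVs to demo/export
INFO:smibridge:stage stitch   done in 0.02s
INFO:smibridge:stage geojson  done in 0.05s
INFO:smibridge:stage viz      done in 0.15s
{"cell_features": 80, "cells": 80, "fovs": 4, "transcript_features": 3, "transcripts": 1193}
```

i.e. 4 FOVs were stitched, all 80 generated cells became polygon features, and
each of the 3 genes became one MultiPoint feature (1193 transcripts in total). `demo/out/` now holds `stitched/stitched.tif`,
`stitched/overview.tif`, the post-stitch position table, `cells.geojson`,
`transcripts.geojson`, and the PNG overlays. The first lines of the position
table and the first cell feature:

```
fov,x_offset_px,y_offset_px
1,0,0
2,256,0
```

```json
{"objectType": "cell", "name": "c_1_0000", "isLocked": true,
 "classification": {"name": "epithelial", "color": [31, 119, 180]}}
```

Every feature vertex minus its FOV offset reproduces the input local vertex
exactly. The same steps run on a real AtoMx export directory; if the export
uses different CSV headers or millimetre units, describe them once in a
`ColumnMap` YAML and pass `--config`.

Library use mirrors the CLI:

```python
import smibridge as sb

positions = sb.read_fov_positions("export/fov_positions.csv")
result = sb.stitch_tiles(sb.TileDirectorySource("export"), positions, "out")
polygons = sb.read_polygon_table("export/cell_polygons.csv")
fc, skipped = sb.polygons_to_features(polygons, result.positions)
sb.write_geojson(fc, "out/cells.geojson")
```

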