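import numpy as np
import pandas as pd
import pytest

import smibridge as sb


@pytest.fixture(scope="session")
def small_export(tmp_path_factory):
    """Synthetic 2x2-grid export with 256-px tiles (session-wide, read-only)."""
    cfg = sb.small_preset(seed=7)
    out = tmp_path_factory.mktemp("export")
    paths = sb.generate_export(cfg, out)
    return cfg, paths


@pytest.fixture(scope="session")
def stitched_small(small_export, tmp_path_factory):
    cfg, paths = small_export
    positions = sb.read_fov_positions(paths.positions)
    source = sb.TileDirectorySource(paths.directory)
    result = sb.stitch_tiles(
        source, positions, tmp_path_factory.mktemp("stitch"), factor=20
    )
    return cfg, paths, result


@pytest.fixture
def offsets_2x2():
    """Post-stitch offsets of a gap-free 2x2 grid of 4256-px tiles."""
    return pd.DataFrame(
        {
            "fov": [1, 2, 3, 4],
            "x_offset": [0, 4256, 0, 4256],
            "y_offset": [0, 0, 4256, 4256],
        }
    )


def naive_dense_stitch(tiles: dict, positions: dict, tile_w, tile_h, background=0):
    """Independent reference: place every tile on a dense array.

    Pure-Python bookkeeping, ascending FOV order (larger id overwrites on
    overlap), kept free of any package stitching code.
    """
    xs = [p[0] for p in positions.values()]
    ys = [p[1] for p in positions.values()]
    x_min, y_min = min(xs), min(ys)
    first = next(iter(tiles.values()))
    canvas_w = max(int(round(x - x_min)) for x in xs) + tile_w
    canvas_h = max(int(round(y - y_min)) for y in ys) + tile_h
    multi = first.ndim == 3
    shape = (first.shape[0], canvas_h, canvas_w) if multi else (canvas_h, canvas_w)
    canvas = np.full(shape, background, dtype=first.dtype)
    for fov in sorted(tiles):
        x0 = int(round(positions[fov][0] - x_min))
        y0 = int(round(positions[fov][1] - y_min))
        if multi:
            canvas[:, y0 : y0 + tile_h, x0 : x0 + tile_w] = tiles[fov]
        else:
            canvas[y0 : y0 + tile_h, x0 : x0 + tile_w] = tiles[fov]
    return canvas
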