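"""Whole-slide mosaic assembly from FOV tiles.

Tiles are placed purely by position (no registration, flat-fielding or seam
blending): the FOV position table gives each tile's global top-left corner,
the global bounding box is the min/max over all tile extents, and each tile
is copied verbatim to ``position - (x_min, y_min)`` on a memory-mapped
canvas.  Peak working memory is bounded by one batch of tiles regardless of
FOV count.  Outputs are the full-resolution stitched TIFF, a block-mean
overview downsampled by ``factor`` (default 20), and the post-stitch FOV
position CSV that converts any FOV-local coordinate to whole-slide space.

Overlapping tiles (not produced by the instrument's nominal grid, but
possible in custom layouts) are resolved deterministically: the tile with
the larger FOV id wins on every contested pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from joblib import Parallel, delayed

from .errors import ValidationError
from .io import write_post_stitch_positions

DEFAULT_TILE = (4256, 4256)  # instrument native FOV size, px
DEFAULT_FACTOR = 20


@dataclass(frozen=True)
class TileShape:
    """Shape of one FOV tile: width x height px, channel count, dtype."""

    width: int = DEFAULT_TILE[0]
    height: int = DEFAULT_TILE[1]
    channels: int = 1
    dtype: str = "uint16"

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0 or self.channels <= 0:
            raise ValidationError("tile width, height, channels must be positive")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "TileShape":
        if arr.ndim == 2:
            h, w = arr.shape
            c = 1
        elif arr.ndim == 3:
            c, h, w = arr.shape
        else:
            raise ValidationError(f"tile must be 2-D or (C, H, W), got {arr.shape}")
        return cls(width=w, height=h, channels=c, dtype=str(arr.dtype))


@dataclass(frozen=True)
class GlobalBounds:
    """Half-open global extent covering every tile: [x_min, x_max) x [y_min, y_max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass
class StitchResult:
    full_image: Path
    overview: Path
    factor: int
    positions: pd.DataFrame  # post-stitch offsets: fov, x_offset, y_offset
    positions_csv: Path
    bounds: GlobalBounds
    tile_shape: TileShape


class TileDirectorySource:
    """Resolve per-FOV TIFF tiles in a directory by filename pattern.

    The pattern is a format string containing ``{fov...}``; the default
    ``*F{fov:03d}*.tif`` matches AtoMx-style names such as
    ``SlideA_F001.tif``.  Calling the source with a FOV id reads and returns
    the tile array.
    """

    def __init__(self, directory, pattern: str = "*F{fov:03d}*.tif"):
        self.directory = Path(directory)
        self.pattern = pattern
        if not self.directory.is_dir():
            raise FileNotFoundError(f"tile directory not found: {self.directory}")

    def path_for(self, fov_id: int) -> Path:
        glob_pat = self.pattern.format(fov=int(fov_id))
        matches = sorted(self.directory.glob(glob_pat))
        if not matches:
            raise FileNotFoundError(
                f"no tile matching {glob_pat!r} for FOV {fov_id} in {self.directory}"
            )
        if len(matches) > 1:
            raise ValidationError(
                f"multiple tiles match {glob_pat!r} for FOV {fov_id}: "
                f"{[m.name for m in matches]}"
            )
        return matches[0]

    def __call__(self, fov_id: int) -> np.ndarray:
        return tifffile.imread(self.path_for(fov_id))


def compute_global_bounds(positions: pd.DataFrame, tile: TileShape) -> GlobalBounds:
    """Bounding box tightly containing every tile extent."""
    if len(positions) == 0:
        raise ValidationError("FOV position table is empty")
    x = positions["x"].to_numpy(dtype=float)
    y = positions["y"].to_numpy(dtype=float)
    return GlobalBounds(
        x_min=float(x.min()),
        y_min=float(y.min()),
        x_max=float(x.max()) + tile.width,
        y_max=float(y.max()) + tile.height,
    )


def assign_tile_offsets(positions: pd.DataFrame, bounds: GlobalBounds) -> pd.DataFrame:
    """Integer top-left offsets on the stitched canvas (min 0 on each axis).

    ``offset = round(position - (x_min, y_min))``; translation of all
    positions by any constant leaves the table unchanged.
    """
    out = pd.DataFrame(
        {
            "fov": positions["fov"].to_numpy(dtype=np.int64),
            "x_offset": np.rint(positions["x"].to_numpy(float) - bounds.x_min).astype(
                np.int64
            ),
            "y_offset": np.rint(positions["y"].to_numpy(float) - bounds.y_min).astype(
                np.int64
            ),
        }
    )
    return out.sort_values("fov", ignore_index=True)


def downsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Area-average (block-mean) downsampling.

    Output dims are ``ceil(dims / factor)``; edge blocks are averaged over
    the pixels actually present, so a constant image stays exactly constant.
    Channels (leading axes) are preserved.  Returns float64.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValidationError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    a = np.asarray(image, dtype=np.float64)
    h, w = a.shape[-2], a.shape[-1]
    ri = np.arange(0, h, factor)
    ci = np.arange(0, w, factor)
    s = np.add.reduceat(np.add.reduceat(a, ri, axis=-2), ci, axis=-1)
    nr = np.diff(np.append(ri, h)).astype(np.float64)
    nc = np.diff(np.append(ci, w)).astype(np.float64)
    return s / (nr[:, None] * nc[None, :])


def _to_chw(arr: np.ndarray, tile: TileShape, fov_id) -> np.ndarray:
    got = TileShape.from_array(arr)
    if (got.width, got.height, got.channels) != (tile.width, tile.height, tile.channels):
        raise ValidationError(
            f"tile shape mismatch for FOV {fov_id}: expected "
            f"{tile.channels}x{tile.height}x{tile.width}, got "
            f"{got.channels}x{got.height}x{got.width}"
        )
    return arr[None] if arr.ndim == 2 else arr


def stitch_tiles(
    tile_source,
    positions: pd.DataFrame,
    out_dir,
    factor: int = DEFAULT_FACTOR,
    batch_size: int = 4,
    tile_shape: TileShape | None = None,
    n_jobs: int = 1,
    background=0,
) -> StitchResult:
    """Assemble FOV tiles onto a memory-mapped whole-slide canvas.

    Parameters
    ----------
    tile_source
        Callable ``fov_id -> ndarray`` (e.g. a :class:`TileDirectorySource`).
    positions
        FOV position table (columns ``fov, x, y``, global pixels).
    out_dir
        Directory receiving ``stitched.tif``, ``overview.tif`` and
        ``fov_positions_post_stitch.csv``.
    factor
        Overview downsampling factor (default 20).
    batch_size
        Tiles held in memory at once; output is independent of this value.
    n_jobs
        joblib workers used to read each batch of tiles.
    background
        Canvas fill value for pixels not covered by any tile.

    The canvas is written as a (Big)TIFF memmap, so the full mosaic is never
    resident in RAM.  Tiles are placed in ascending FOV order; on overlap
    the larger FOV id wins.
    """
    if len(positions) == 0:
        raise ValidationError("FOV position table is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fovs = sorted(positions["fov"].tolist())
    first = np.asarray(tile_source(fovs[0]))
    if tile_shape is None:
        tile_shape = TileShape.from_array(first)
    _to_chw(first, tile_shape, fovs[0])  # validates the first tile too

    bounds = compute_global_bounds(positions, tile_shape)
    offsets = assign_tile_offsets(positions, bounds)
    off = offsets.set_index("fov")
    canvas_w = int(off["x_offset"].max()) + tile_shape.width
    canvas_h = int(off["y_offset"].max()) + tile_shape.height

    c = tile_shape.channels
    dtype = np.dtype(tile_shape.dtype)
    shape = (c, canvas_h, canvas_w) if c > 1 else (canvas_h, canvas_w)
    nbytes = int(np.prod(shape)) * dtype.itemsize
    full_path = out_dir / "stitched.tif"
    canvas = tifffile.memmap(
        str(full_path), shape=shape, dtype=dtype,
        bigtiff=nbytes > 2**32 - 2**25, photometric="minisblack",
    )
    if background != 0:
        canvas[:] = background

    # ascending-FOV placement in bounded batches: larger fov id wins overlaps
    for start in range(0, len(fovs), max(1, int(batch_size))):
        batch = fovs[start : start + max(1, int(batch_size))]
        tiles = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(tile_source)(f) for f in batch
        )
        for fov_id, arr in zip(batch, tiles):
            arr = _to_chw(np.asarray(arr), tile_shape, fov_id)
            x0 = int(off.at[fov_id, "x_offset"])
            y0 = int(off.at[fov_id, "y_offset"])
            if c > 1:
                canvas[:, y0 : y0 + tile_shape.height, x0 : x0 + tile_shape.width] = arr
            else:
                canvas[y0 : y0 + tile_shape.height, x0 : x0 + tile_shape.width] = arr[0]
    canvas.flush()

    overview_path = out_dir / "overview.tif"
    _write_overview(canvas, overview_path, factor, dtype)
    del canvas

    positions_csv = write_post_stitch_positions(
        offsets, out_dir / "fov_positions_post_stitch.csv"
    )
    return StitchResult(
        full_image=full_path,
        overview=overview_path,
        factor=int(factor),
        positions=offsets,
        positions_csv=positions_csv,
        bounds=bounds,
        tile_shape=tile_shape,
    )


def _write_overview(canvas: np.ndarray, path: Path, factor: int, dtype) -> None:
    """Strip-wise block-mean overview so the canvas is never fully loaded."""
    if not float(factor).is_integer() or factor < 1:
        raise ValidationError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    h, w = canvas.shape[-2], canvas.shape[-1]
    oh, ow = math.ceil(h / factor), math.ceil(w / factor)
    multi = canvas.ndim == 3
    out_shape = (canvas.shape[0], oh, ow) if multi else (oh, ow)
    out = np.empty(out_shape, dtype=np.float64)
    strip = 64 * factor  # rows of input per pass
    for y0 in range(0, h, strip):
        block = np.asarray(canvas[..., y0 : y0 + strip, :])
        out[..., y0 // factor : y0 // factor + math.ceil(block.shape[-2] / factor), :] = (
            downsample_image(block, factor)
        )
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    tifffile.imwrite(str(path), out.astype(dtype), photometric="minisblack")
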