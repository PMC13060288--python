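"""Seeded synthetic AtoMx-style export generator.

Produces a complete export directory — multi-channel FOV tiles, FOV
position file, cell polygon table, transcript table, cell metadata, and a
cell x gene expression matrix — that every reader in :mod:`smibridge.io`
accepts, so the whole pipeline is testable without instrument data.

Generative model (an explicit stand-in, not a reconstruction of real
tissue): FOVs sit on a gap-free grid at exact tile-size multiples; each
FOV holds randomly placed round cells whose boundaries are regular
12-gons; tiles carry a Gaussian intensity blob per cell (sigma = radius/2)
over a Poisson noise floor; per-cell per-gene transcript counts are
Poisson with a common mean, with molecules scattered uniformly inside the
cell's inscribed circle; and the expression matrix equals the per-cell
transcript row counts exactly.  A fixed seed reproduces the directory
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .stitching import TileShape

CELL_TYPES = ("epithelial", "immune", "stromal")
N_POLY_VERTICES = 12
BLOB_AMPLITUDE = 20000  # peak intensity above the noise floor, 16-bit units


@dataclass
class SimConfig:
    """Study conditions for the synthetic export.

    Defaults reproduce the reference fixture: 4 FOVs on a 2x2 grid of
    4256 x 4256 px tiles with simulated fluorescent cell signals.  The
    ``small`` preset shrinks tiles to 256 px for fast tests.
    """

    grid: tuple = (2, 2)  # (rows, cols) of FOVs
    tile: TileShape = field(
        default_factory=lambda: TileShape(4256, 4256, channels=2, dtype="uint16")
    )
    cells_per_fov: int = 50
    cell_radius_range: tuple = (40.0, 80.0)  # px
    genes: tuple = ("GENE_A", "GENE_B", "GENE_C")
    transcripts_per_cell_mean: float = 5.0  # Poisson mean, per cell per gene
    noise_floor: float = 100.0  # background Poisson intensity
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.grid
        if rows < 1 or cols < 1:
            raise ValidationError("grid must be at least 1x1")
        rmin, rmax = self.cell_radius_range
        if not (0 < rmin <= rmax):
            raise ValidationError("cell radius range must satisfy 0 < min <= max")
        if rmax >= min(self.tile.width, self.tile.height) / 2:
            raise ValidationError("cell radius must be < half the tile dims")

    @property
    def n_fovs(self) -> int:
        return self.grid[0] * self.grid[1]


def paper_preset(seed: int = 0) -> SimConfig:
    """Full-scale fixture: 2x2 grid of native 4256 px tiles."""
    return SimConfig(seed=seed)


def small_preset(seed: int = 0) -> SimConfig:
    """Fast fixture: 2x2 grid of 256 px tiles, 20 cells/FOV, 3 genes."""
    return SimConfig(
        tile=TileShape(256, 256, channels=2, dtype="uint16"),
        cells_per_fov=20,
        cell_radius_range=(8.0, 16.0),
        seed=seed,
    )


@dataclass
class CellSpec:
    cell_id: str
    fov: int
    cx: float
    cy: float
    radius: float
    vertices: np.ndarray  # (N_POLY_VERTICES, 2) local px
    cell_type: str


def _fov_rng(config: SimConfig, fov_id: int, stream: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, fov, purpose)
    return np.random.default_rng([int(config.seed), int(fov_id), int(stream)])


def generate_cells(config: SimConfig, fov_id: int) -> list[CellSpec]:
    """Place cells in one FOV: centroid, radius, 12-gon boundary, type.

    Centroids stay at least one radius from the tile edges so every vertex
    lies inside the tile.  Placement retries until a candidate does not
    overlap an accepted cell; cells may still touch.  If a candidate cannot
    be placed within 1000 attempts the density is infeasible.
    """
    rng = _fov_rng(config, fov_id, 0)
    w, h = config.tile.width, config.tile.height
    rmin, rmax = config.cell_radius_range
    angles = 2 * np.pi * np.arange(N_POLY_VERTICES) / N_POLY_VERTICES
    specs: list[CellSpec] = []
    for i in range(config.cells_per_fov):
        for attempt in range(1000):
            r = float(rng.uniform(rmin, rmax))
            cx = float(rng.uniform(r, w - 1 - r))
            cy = float(rng.uniform(r, h - 1 - r))
            if all(
                np.hypot(cx - s.cx, cy - s.cy) > (r + s.radius) for s in specs
            ):
                break
        else:
            raise ValidationError(
                f"could not place cell {i} in FOV {fov_id} within 1000 attempts; "
                "reduce cells_per_fov or the radius range"
            )
        verts = np.column_stack(
            (cx + r * np.cos(angles), cy + r * np.sin(angles))
        )
        specs.append(
            CellSpec(
                cell_id=f"c_{fov_id}_{i:04d}",
                fov=int(fov_id),
                cx=cx,
                cy=cy,
                radius=r,
                vertices=verts,
                cell_type=str(rng.choice(CELL_TYPES)),
            )
        )
    return specs


def generate_fov_tile(
    specs: list[CellSpec], tile: TileShape, noise_floor: float, rng
) -> np.ndarray:
    """Render one multi-channel 16-bit tile.

    Channel 0 carries a Gaussian-profile blob per cell (peak at the
    centroid, sigma = radius/2) over a Poisson noise floor; further
    channels repeat the blob signal with independent noise draws.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h, w = tile.height, tile.width
    signal = np.zeros((h, w), dtype=np.float64)
    for s in specs:
        sigma = s.radius / 2.0
        ext = int(np.ceil(3 * s.radius))
        x0, x1 = max(0, int(s.cx) - ext), min(w, int(s.cx) + ext + 1)
        y0, y1 = max(0, int(s.cy) - ext), min(h, int(s.cy) + ext + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - s.cx) ** 2 + (yy - s.cy) ** 2
        signal[y0:y1, x0:x1] += BLOB_AMPLITUDE * np.exp(-d2 / (2 * sigma**2))
    channels = []
    for _ in range(tile.channels):
        noise = rng.poisson(noise_floor, size=(h, w)).astype(np.float64)
        channels.append(np.clip(signal + noise, 0, 2**16 - 1).astype(np.uint16))
    arr = np.stack(channels)
    return arr[0] if tile.channels == 1 else arr


def _grid_positions(config: SimConfig) -> pd.DataFrame:
    """FOV ids 1..N in row-major order at exact tile-size multiples."""
    rows, cols = config.grid
    recs = []
    fov = 1
    for r in range(rows):
        for c in range(cols):
            recs.append((fov, c * config.tile.width, r * config.tile.height))
            fov += 1
    return pd.DataFrame(recs, columns=["fov", "x_global_px", "y_global_px"])


@dataclass
class ExportPaths:
    directory: Path
    tiles: dict  # fov -> path
    positions: Path
    polygons: Path
    transcripts: Path
    metadata: Path
    expression: Path
    cells: list  # all CellSpec, every FOV


def generate_export(config: SimConfig, out_dir) -> ExportPaths:
    """Write a complete synthetic export directory.

    Files: ``Slide1_F{fov:03d}.tif`` per FOV, ``fov_positions.csv``,
    ``cell_polygons.csv``, ``transcripts.csv``, ``cell_metadata.csv``,
    ``expression.csv`` — all under the canonical headers so the default
    :class:`~smibridge.config.ColumnMap` reads them.  The (cell, gene)
    expression entry equals that cell's transcript row count exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    positions = _grid_positions(config)

    tiles: dict = {}
    poly_rows, tx_rows, meta_rows = [], [], []
    all_cells: list[CellSpec] = []
    genes = [str(g) for g in config.genes]

    for fov in positions["fov"]:
        specs = generate_cells(config, int(fov))
        all_cells.extend(specs)
        tile_img = generate_fov_tile(
            specs, config.tile, config.noise_floor, _fov_rng(config, int(fov), 1)
        )
        tile_path = out_dir / f"Slide1_F{int(fov):03d}.tif"
        tifffile.imwrite(str(tile_path), tile_img, photometric="minisblack")
        tiles[int(fov)] = tile_path

        tx_rng = _fov_rng(config, int(fov), 2)
        incircle = np.cos(np.pi / N_POLY_VERTICES)  # 12-gon inscribed-circle ratio
        for s in specs:
            for vi, (vx, vy) in enumerate(s.vertices):
                poly_rows.append((s.cell_id, s.fov, vi, vx, vy))
            meta_rows.append((s.cell_id, s.fov, s.cx, s.cy, s.cell_type))
            for gene in genes:
                n = int(tx_rng.poisson(config.transcripts_per_cell_mean))
                if n == 0:
                    continue
                # uniform in the polygon's inscribed circle -> always inside
                rad = s.radius * incircle * np.sqrt(tx_rng.uniform(size=n))
                ang = tx_rng.uniform(0, 2 * np.pi, size=n)
                for x, y in zip(s.cx + rad * np.cos(ang), s.cy + rad * np.sin(ang)):
                    tx_rows.append((gene, s.fov, x, y, s.cell_id))

    positions_path = out_dir / "fov_positions.csv"
    positions.to_csv(positions_path, index=False)

    poly = pd.DataFrame(
        poly_rows,
        columns=["cell_ID", "fov", "vertex_index", "x_local_px", "y_local_px"],
    )
    poly_path = out_dir / "cell_polygons.csv"
    poly.to_csv(poly_path, index=False)

    tx = pd.DataFrame(
        tx_rows, columns=["target", "fov", "x_local_px", "y_local_px", "cell_ID"]
    )
    tx_path = out_dir / "transcripts.csv"
    tx.to_csv(tx_path, index=False)

    meta = pd.DataFrame(
        meta_rows, columns=["cell_ID", "fov", "CenterX", "CenterY", "cell_type"]
    )
    meta_path = out_dir / "cell_metadata.csv"
    meta.to_csv(meta_path, index=False)

    # expression = exact per-cell transcript row counts, zero-filled
    counts = (
        tx.groupby(["cell_ID", "target"]).size().unstack(fill_value=0)
        if len(tx)
        else pd.DataFrame()
    )
    expr = counts.reindex(
        index=sorted(meta["cell_ID"]), columns=genes, fill_value=0
    ).astype(int)
    expr.index.name = "cell_ID"
    expr_path = out_dir / "expression.csv"
    expr.to_csv(expr_path)

    return ExportPaths(
        directory=out_dir,
        tiles=tiles,
        positions=positions_path,
        polygons=poly_path,
        transcripts=tx_path,
        metadata=meta_path,
        expression=expr_path,
        cells=all_cells,
    )
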