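"""End-to-end pipeline: stitch -> GeoJSON -> visualization.

A :class:`RunConfig` names the export directory, output directory, and the
options of each stage; :func:`run_pipeline` executes the stages in order
and returns a JSON-serializable run report listing every artifact path and
the FOV / cell / transcript / feature counts.  Reruns with identical
config and inputs reproduce identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import tifffile
import yaml

from . import geojson as gj
from . import io, viz
from .config import ColumnMap
from .errors import StageError
from .stitching import TileDirectorySource, stitch_tiles

logger = logging.getLogger("smibridge")


@dataclass
class RunConfig:
    """Validated, file-serializable configuration for one pipeline run."""

    export_dir: str
    out_dir: str
    colmap: ColumnMap = field(default_factory=ColumnMap)
    tile_pattern: str = "*F{fov:03d}*.tif"
    factor: int = 20
    batch_size: int = 4
    genes: tuple | None = None  # None -> all genes in the expression matrix
    sigma: float = 2.0
    tissue_color: tuple = viz.DEFAULT_TISSUE_COLOR
    mode: str = "m"
    seed: int = 0
    verbosity: str = "INFO"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["colmap"] = self.colmap.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "colmap" in d:
            d["colmap"] = ColumnMap.from_dict(d["colmap"])
        for key in ("genes", "tissue_color"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            logger.info("stage %-8s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run stitch -> geojson -> viz on an export directory.

    Returns the run report (also written to ``<out_dir>/run_report.json``).
    Any stage failure aborts with a stage-labeled :class:`StageError`.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    export_dir = Path(config.export_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "artifacts": {}, "counts": {}, "skipped": {}}

    positions_csv = export_dir / "fov_positions.csv"
    if not positions_csv.exists():
        raise StageError("validate", f"FOV position file not found: {positions_csv}")

    @_stage("stitch")
    def do_stitch():
        positions = io.read_fov_positions(positions_csv, config.colmap)
        source = TileDirectorySource(export_dir, config.tile_pattern)
        return stitch_tiles(
            source, positions, out_dir / "stitched",
            factor=config.factor, batch_size=config.batch_size,
        ), positions

    result, positions = do_stitch()
    report["counts"]["fovs"] = len(positions)
    report["artifacts"]["stitched"] = str(result.full_image)
    report["artifacts"]["overview"] = str(result.overview)
    report["artifacts"]["post_stitch_positions"] = str(result.positions_csv)

    @_stage("geojson")
    def do_geojson():
        tile = result.tile_shape
        polygons = io.read_polygon_table(
            export_dir / "cell_polygons.csv", config.colmap, tile
        )
        metadata = io.read_cell_metadata(
            export_dir / "cell_metadata.csv", config.colmap, tile
        )
        types = (
            dict(zip(metadata["cell_id"], metadata["cell_type"]))
            if "cell_type" in metadata.columns
            else None
        )
        fc_cells, skipped = gj.polygons_to_features(
            polygons, result.positions, cell_types=types,
            batch_size=config.batch_size,
        )
        cells_path = gj.write_geojson(fc_cells, out_dir / "cells.geojson")

        expr = io.read_expression(export_dir / "expression.csv")
        genes = list(config.genes) if config.genes else list(expr.columns)
        transcripts = io.read_transcripts(
            export_dir / "transcripts.csv", config.colmap, genes=genes
        )
        fc_tx = gj.transcripts_to_features(transcripts, genes, result.positions)
        tx_path = gj.write_geojson(fc_tx, out_dir / "transcripts.geojson")
        return cells_path, tx_path, fc_cells, fc_tx, skipped, polygons, metadata, expr, transcripts, genes

    (cells_path, tx_path, fc_cells, fc_tx, skipped, polygons, metadata, expr,
     transcripts, genes) = do_geojson()
    report["artifacts"]["cells_geojson"] = str(cells_path)
    report["artifacts"]["transcripts_geojson"] = str(tx_path)
    report["counts"]["cells"] = polygons["cell_id"].nunique()
    report["counts"]["transcripts"] = len(transcripts)
    report["counts"]["cell_features"] = len(fc_cells["features"])
    report["counts"]["transcript_features"] = len(fc_tx["features"])
    report["skipped"]["degenerate_cells"] = list(skipped)

    @_stage("viz")
    def do_viz():
        overview = tifffile.imread(str(result.overview))
        canvas = viz.make_background(
            overview, sigma=config.sigma, tissue_color=config.tissue_color,
            factor=config.factor,
        )
        figs = {}
        figs["cell_types"] = str(
            viz.plot_cell_types(
                canvas, metadata, result.positions, out_dir / "cell_types.png"
            )
        )
        for p in viz.plot_transcripts(
            canvas, transcripts, genes, result.positions, config.mode, out_dir
        ):
            figs[p.stem] = str(p)
        gene0 = genes[0]
        figs["cell_expression"] = str(
            viz.plot_cell_expression(
                canvas, metadata, expr, gene0, result.positions,
                out_dir / f"cell_expression_{gene0}.png",
            )
        )
        summary = viz.fov_mean_expression(
            expr, metadata, gene0, fovs=positions["fov"]
        )
        summary.to_csv(out_dir / f"fov_mean_expression_{gene0}.csv")
        figs["fov_expression"] = str(
            viz.plot_fov_expression(
                canvas, summary, result.positions, result.tile_shape,
                out_dir / f"fov_expression_{gene0}.png",
            )
        )
        return figs, summary

    figs, summary = do_viz()
    report["artifacts"].update(figs)
    report["skipped"]["empty_fovs"] = list(summary.empty_fovs)

    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    report["artifacts"]["run_report"] = str(report_path)
    return report
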