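"""FOV-local -> whole-slide coordinate transforms and GeoJSON serialization.

Cell segmentation polygons and per-molecule transcript coordinates are
exported in FOV-local pixels.  Joining with the post-stitch position table
(one top-left offset per FOV on the stitched canvas) converts them to
whole-slide pixels.  They are then serialized as an RFC 7946-style
FeatureCollection in image pixel space (no CRS member), using the property
dialect that QuPath (v0.5) imports:

* cells: ``Polygon`` features, ``properties.objectType = "cell"``, the
  cell id under ``name``, optional ``classification = {name, color}`` for
  the cell type, and ``isLocked = true`` so imported segmentations are not
  edited by accident;
* transcripts: one ``MultiPoint`` feature per gene over the whole slide,
  ``properties.objectType = "annotation"``, classified by gene.

Coordinate order is ``[x, y]``; exterior rings are closed by repeating the
first vertex; winding order is not enforced (target viewers accept either).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from shapely.geometry import shape as shapely_shape

from ._grid import snap
from .errors import FovLookupError, ValidationError
from .palette import assign_colors


def _offset_lookup(offsets: pd.DataFrame):
    return {
        int(f): (int(x), int(y))
        for f, x, y in zip(offsets["fov"], offsets["x_offset"], offsets["y_offset"])
    }


def local_to_global(x_local, y_local, fov_id, offsets: pd.DataFrame):
    """FOV-local pixels -> whole-slide pixels: ``local + fov offset``.

    Accepts scalars or equal-length arrays.  Coordinates are snapped to
    the package-wide 1/256-px grid, which makes the transform bit-exactly
    invertible (offsets are integers).  Unknown FOV ids raise
    :class:`~smibridge.errors.FovLookupError`.
    """
    lut = _offset_lookup(offsets)
    fov = np.atleast_1d(np.asarray(fov_id))
    missing = set(fov.tolist()) - set(lut)
    if missing:
        raise FovLookupError(sorted(missing)[0])
    dx = np.array([lut[int(f)][0] for f in fov], dtype=np.float64)
    dy = np.array([lut[int(f)][1] for f in fov], dtype=np.float64)
    xg = snap(np.atleast_1d(np.asarray(x_local, dtype=np.float64))) + dx
    yg = snap(np.atleast_1d(np.asarray(y_local, dtype=np.float64))) + dy
    if np.isscalar(fov_id) or np.ndim(fov_id) == 0:
        return float(xg[0]), float(yg[0])
    return xg, yg


def global_to_local(x_global, y_global, fov_id, offsets: pd.DataFrame):
    """Inverse of :func:`local_to_global` for the same FOV."""
    lut = _offset_lookup(offsets)
    fov = np.atleast_1d(np.asarray(fov_id))
    missing = set(fov.tolist()) - set(lut)
    if missing:
        raise FovLookupError(sorted(missing)[0])
    dx = np.array([lut[int(f)][0] for f in fov], dtype=np.float64)
    dy = np.array([lut[int(f)][1] for f in fov], dtype=np.float64)
    xl = snap(np.atleast_1d(np.asarray(x_global, dtype=np.float64))) - dx
    yl = snap(np.atleast_1d(np.asarray(y_global, dtype=np.float64))) - dy
    if np.isscalar(fov_id) or np.ndim(fov_id) == 0:
        return float(xl[0]), float(yl[0])
    return xl, yl


def _cell_feature(cell_id, ring, cell_type, color):
    props = {"objectType": "cell", "name": str(cell_id), "isLocked": True}
    if cell_type is not None:
        props["classification"] = {"name": str(cell_type), "color": list(color)}
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": props,
    }


def _build_cell(cell_id, xs, ys, dx, dy, cell_type, color):
    """Translate one cell's vertices and close the ring; None if degenerate."""
    pts = [[float(x + dx), float(y + dy)] for x, y in zip(xs, ys)]
    distinct = {(p[0], p[1]) for p in pts}
    if len(distinct) < 3:
        return None
    if pts[0] != pts[-1]:
        pts.append(list(pts[0]))
    return _cell_feature(cell_id, pts, cell_type, color)


def polygons_to_features(
    polygons: pd.DataFrame,
    offsets: pd.DataFrame,
    cell_types: dict | None = None,
    palette: dict | None = None,
    batch_size: int | None = None,
    n_jobs: int = 1,
):
    """Build one closed Polygon feature per cell in whole-slide pixels.

    Cells with fewer than 3 distinct vertices cannot form a polygon; they
    are dropped and listed in the returned skip report.  Feature order is
    sorted cell id and the output is identical for any *batch_size*.

    Returns
    -------
    (feature_collection, skipped) : (dict, list of cell_id)
    """
    lut = _offset_lookup(offsets)
    cell_types = cell_types or {}
    if palette is None:
        palette = assign_colors(cell_types.values())
    fovs = set(polygons["fov"].unique().tolist()) if len(polygons) else set()
    missing = fovs - set(lut)
    if missing:
        raise FovLookupError(sorted(missing)[0])

    cells = []  # (cell_id, xs, ys, dx, dy, type, color) sorted by cell_id
    for cell_id, g in polygons.sort_values(["cell_id", "vertex_index"]).groupby(
        "cell_id", sort=True
    ):
        fov = int(g["fov"].iloc[0])
        dx, dy = lut[fov]
        ctype = cell_types.get(cell_id)
        color = palette.get(str(ctype)) if ctype is not None else None
        cells.append(
            (cell_id, g["x_local"].to_numpy(), g["y_local"].to_numpy(), dx, dy, ctype, color)
        )

    if batch_size is None or batch_size <= 0:
        batch_size = max(1, len(cells))
    batches = [cells[i : i + batch_size] for i in range(0, len(cells), batch_size)]
    results = Parallel(n_jobs=n_jobs, prefer="threads")(
        delayed(lambda b: [_build_cell(*spec) for spec in b])(b) for b in batches
    )
    features, skipped = [], []
    for batch, feats in zip(batches, results):
        for spec, feat in zip(batch, feats):
            if feat is None:
                skipped.append(spec[0])
            else:
                features.append(feat)
    return {"type": "FeatureCollection", "features": features}, skipped


def transcripts_to_features(
    transcripts: pd.DataFrame,
    genes,
    offsets: pd.DataFrame,
    palette: dict | None = None,
    include_cell_ids: bool = False,
) -> dict:
    """One MultiPoint feature per requested gene, in whole-slide pixels.

    Genes with zero transcripts are omitted with a warning.  With
    *include_cell_ids*, each feature carries a ``cell_ids`` list aligned
    with its points (empty string for extracellular molecules), preserving
    the transcript-to-cell association without per-cell fragmentation.
    """
    genes = sorted({str(g) for g in genes})
    if not genes:
        raise ValidationError("genes must be a non-empty set")
    if palette is None:
        palette = assign_colors(genes)
    sub = transcripts[transcripts["gene"].astype(str).isin(genes)]
    if len(sub):
        xg, yg = local_to_global(
            sub["x_local"].to_numpy(), sub["y_local"].to_numpy(),
            sub["fov"].to_numpy(), offsets,
        )
        sub = sub.assign(_xg=xg, _yg=yg)
    features = []
    for gene in genes:
        rows = sub[sub["gene"].astype(str) == gene]
        if len(rows) == 0:
            warnings.warn(f"gene {gene!r} has no transcripts; omitted", stacklevel=2)
            continue
        props = {
            "objectType": "annotation",
            "name": gene,
            "classification": {"name": gene, "color": list(palette[gene])},
        }
        if include_cell_ids and "cell_id" in rows.columns:
            props["cell_ids"] = [
                "" if pd.isna(c) else str(c) for c in rows["cell_id"]
            ]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "MultiPoint",
                    "coordinates": [
                        [float(x), float(y)] for x, y in zip(rows["_xg"], rows["_yg"])
                    ],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def validate_geojson(fc: dict) -> None:
    """Structural GeoJSON validation; raises ValidationError on any defect.

    Checks the FeatureCollection framing, per-feature type/geometry/
    properties members, polygon ring closure and minimum length, and parses
    every geometry with shapely.
    """
    if not isinstance(fc, dict) or fc.get("type") != "FeatureCollection":
        raise ValidationError("not a FeatureCollection")
    feats = fc.get("features")
    if not isinstance(feats, list):
        raise ValidationError("'features' must be a list")
    for i, f in enumerate(feats):
        if not isinstance(f, dict) or f.get("type") != "Feature":
            raise ValidationError(f"feature {i} lacks type 'Feature'")
        geom = f.get("geometry")
        if not isinstance(geom, dict) or "type" not in geom or "coordinates" not in geom:
            raise ValidationError(f"feature {i} has no valid geometry")
        if geom["type"] == "Polygon":
            for ring in geom["coordinates"]:
                if len(ring) < 4 or ring[0] != ring[-1]:
                    raise ValidationError(
                        f"feature {i}: polygon ring not closed or too short"
                    )
        try:
            shapely_shape(geom)
        except Exception as exc:  # malformed coordinates
            raise ValidationError(f"feature {i}: unparseable geometry: {exc}") from exc
        if "properties" not in f:
            raise ValidationError(f"feature {i} has no properties member")


def write_geojson(fc: dict, path) -> Path:
    """Serialize a FeatureCollection as UTF-8 GeoJSON text."""
    validate_geojson(fc)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fc, fh, ensure_ascii=False, separators=(",", ":"))
    return path


def read_geojson(path) -> dict:
    """Parse a GeoJSON file back into a FeatureCollection dict."""
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    validate_geojson(fc)
    return fc
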