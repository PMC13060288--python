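"""Readers and writers for AtoMx-style export tables.

All tables are returned as :class:`pandas.DataFrame` with canonical column
names (see :mod:`smibridge.config`); the expression matrix is a DataFrame
indexed by ``cell_id`` with one column per gene.  Every reader validates the
structural invariants of its table and raises :class:`~smibridge.errors.SchemaError`
/ :class:`~smibridge.errors.ValidationError` on violation.

The transcript reader supports very large files: with ``streaming=True``
(the default) the CSV is scanned batch-by-batch with pyarrow and the gene
filter is applied per batch, so the peak working set is proportional to the
filtered output plus one read batch, not to the file size.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.csv as pacsv
import scipy.io
import scipy.sparse

from ._grid import snap
from .config import ColumnMap, OPTIONAL_COLUMNS
from .errors import SchemaError, ValidationError

#: canonical headers of the post-stitch position file
POST_STITCH_COLUMNS = ("fov", "x_offset_px", "y_offset_px")


def _tile_wh(tile_shape):
    """Accept a TileShape, (width, height) tuple, or None."""
    if tile_shape is None:
        return None
    if hasattr(tile_shape, "width"):
        return float(tile_shape.width), float(tile_shape.height)
    w, h = tile_shape
    return float(w), float(h)


def _read_mapped(path, colmap: ColumnMap | None, table: str) -> pd.DataFrame:
    """Read a CSV and rename mapped headers to canonical names."""
    colmap = colmap or ColumnMap()
    mapping = colmap.resolve(table)
    optional = OPTIONAL_COLUMNS.get(table, set())
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} file not found: {path}")
    df = pd.read_csv(path)
    missing = [
        hdr
        for canon, hdr in mapping.items()
        if hdr not in df.columns and canon not in optional
    ]
    if missing:
        raise SchemaError(
            f"{table} file {path} is missing required column(s) {missing}; "
            f"adapt the ColumnMap if this export uses different headers"
        )
    present = {hdr: canon for canon, hdr in mapping.items() if hdr in df.columns}
    out = df[list(present)].rename(columns=present)
    return out


def read_fov_positions(path, colmap: ColumnMap | None = None) -> pd.DataFrame:
    """Read the FOV position file: global top-left pixel coordinate per FOV.

    Millimetre units (``colmap.units == "mm"``) are converted to pixels with
    ``colmap.mm_to_px``; ``colmap.y_flip`` negates y.  Returns columns
    ``fov, x, y`` sorted by ``fov``.
    """
    colmap = colmap or ColumnMap()
    df = _read_mapped(path, colmap, "fov_positions")
    if len(df) == 0:
        raise ValidationError(f"FOV position file {path} contains no rows")
    if df["fov"].duplicated().any():
        dups = sorted(df.loc[df["fov"].duplicated(), "fov"].unique().tolist())
        raise ValidationError(f"duplicate FOV id(s) in position file: {dups}")
    df = df.astype({"fov": np.int64, "x": np.float64, "y": np.float64})
    if colmap.units == "mm":
        df["x"] *= colmap.mm_to_px
        df["y"] *= colmap.mm_to_px
    if colmap.y_flip:
        df["y"] = -df["y"]
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValidationError("non-finite FOV coordinates in position file")
    return df.sort_values("fov", ignore_index=True)


def read_polygon_table(
    path, colmap: ColumnMap | None = None, tile_shape=None
) -> pd.DataFrame:
    """Read per-cell boundary vertices in FOV-local pixel coordinates.

    Vertices are sorted by ``(cell_id, vertex_index)``.  Each cell's
    ``vertex_index`` must run 0..n-1 without gaps.  If *tile_shape* is given,
    vertices outside the half-open tile extent ``[0, width) x [0, height)``
    are retained but reported in a warning (segmentation tools commonly emit
    edge-touching vertices).
    """
    df = _read_mapped(path, colmap, "polygons")
    df = df.astype(
        {
            "cell_id": str,
            "fov": np.int64,
            "vertex_index": np.int64,
            "x_local": np.float64,
            "y_local": np.float64,
        }
    )
    df["x_local"] = snap(df["x_local"])
    df["y_local"] = snap(df["y_local"])
    df = df.sort_values(["cell_id", "vertex_index"], ignore_index=True)
    # vertex_index must be 0..n-1 per cell
    grp = df.groupby("cell_id")["vertex_index"]
    n = grp.size()
    bad = (grp.min() != 0) | (grp.max() != n - 1) | (grp.nunique() != n)
    if bad.any():
        raise ValidationError(
            "vertex_index is not contiguous 0..n-1 for cell(s): "
            f"{sorted(bad.index[bad].tolist())}"
        )
    wh = _tile_wh(tile_shape)
    if wh is not None:
        w, h = wh
        out = (
            (df["x_local"] < 0)
            | (df["x_local"] >= w)
            | (df["y_local"] < 0)
            | (df["y_local"] >= h)
        )
        if out.any():
            cells = sorted(df.loc[out, "cell_id"].unique().tolist())
            warnings.warn(
                f"{int(out.sum())} polygon vertex(es) at or beyond the tile "
                f"extent [0, {w}) x [0, {h}) in cell(s) {cells}; retained",
                stacklevel=2,
            )
    return df


def read_transcripts(
    path,
    colmap: ColumnMap | None = None,
    genes=None,
    streaming: bool = True,
    batch_rows: int = 65536,
) -> pd.DataFrame:
    """Read the per-molecule transcript table, optionally filtered to *genes*.

    With ``streaming=True`` the file is scanned in pyarrow record batches and
    the gene filter applied per batch before concatenation, so memory scales
    with the filtered output.  Both code paths return row-identical frames.

    A requested gene absent from the file yields an empty (or reduced)
    result with a warning, not an error.
    """
    colmap = colmap or ColumnMap()
    mapping = colmap.resolve("transcripts")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"transcript file not found: {path}")
    gene_set = None if genes is None else {str(g) for g in genes}

    if streaming:
        df = _scan_transcripts(path, mapping, gene_set, batch_rows)
    else:
        df = pd.read_csv(path)
        missing = [
            hdr
            for canon, hdr in mapping.items()
            if hdr not in df.columns and canon not in OPTIONAL_COLUMNS["transcripts"]
        ]
        if missing:
            raise SchemaError(
                f"transcript file {path} is missing required column(s) {missing}"
            )
        present = {hdr: canon for canon, hdr in mapping.items() if hdr in df.columns}
        df = df[list(present)].rename(columns=present)
        df["gene"] = df["gene"].astype(str)
        if gene_set is not None:
            df = df[df["gene"].isin(gene_set)].reset_index(drop=True)

    df = df.astype(
        {"gene": str, "fov": np.int64, "x_local": np.float64, "y_local": np.float64}
    )
    df["x_local"] = snap(df["x_local"])
    df["y_local"] = snap(df["y_local"])
    if "cell_id" in df.columns:
        # extracellular molecules have no cell: empty string, never NaN
        df["cell_id"] = df["cell_id"].fillna("").astype(str)
    if (df["gene"] == "").any():
        raise ValidationError("empty gene name in transcript table")
    if gene_set is not None:
        found = set(df["gene"].unique())
        absent = gene_set - found
        if absent:
            warnings.warn(
                f"requested gene(s) not present in transcript table: "
                f"{sorted(absent)}",
                stacklevel=2,
            )
    return df.reset_index(drop=True)


def _scan_transcripts(path, mapping, gene_set, batch_rows) -> pd.DataFrame:
    """Batchwise pyarrow CSV scan with per-batch gene filtering."""
    read_opts = pacsv.ReadOptions(block_size=max(batch_rows * 64, 1 << 16))
    reader = pacsv.open_csv(path, read_options=read_opts)
    schema_names = reader.schema.names
    missing = [
        hdr
        for canon, hdr in mapping.items()
        if hdr not in schema_names and canon not in OPTIONAL_COLUMNS["transcripts"]
    ]
    if missing:
        raise SchemaError(
            f"transcript file {path} is missing required column(s) {missing}"
        )
    present = {hdr: canon for canon, hdr in mapping.items() if hdr in schema_names}
    gene_hdr = mapping["gene"]
    chunks = []
    for batch in reader:
        tbl = pa.Table.from_batches([batch])
        if gene_set is not None:
            mask = pa.compute.is_in(
                pa.compute.cast(tbl[gene_hdr], pa.string()),
                value_set=pa.array(sorted(gene_set), pa.string()),
            )
            tbl = tbl.filter(mask)
        if tbl.num_rows:
            chunks.append(
                tbl.select(list(present)).rename_columns(list(present.values()))
            )
    if not chunks:
        cols = list(present.values())
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    return pa.concat_tables(chunks).to_pandas()


def read_cell_metadata(
    path, colmap: ColumnMap | None = None, tile_shape=None
) -> pd.DataFrame:
    """Read cell metadata: centroid (FOV-local pixels), FOV, optional type.

    Returns columns ``cell_id, fov, cx, cy[, cell_type]``; ``cell_type`` is
    present only when the file carries it.
    """
    df = _read_mapped(path, colmap, "metadata")
    if df["cell_id"].duplicated().any():
        dups = sorted(df.loc[df["cell_id"].duplicated(), "cell_id"].unique().tolist())
        raise ValidationError(f"duplicate cell_id(s) in metadata: {dups}")
    df = df.astype(
        {"cell_id": str, "fov": np.int64, "cx": np.float64, "cy": np.float64}
    )
    df["cx"] = snap(df["cx"])
    df["cy"] = snap(df["cy"])
    wh = _tile_wh(tile_shape)
    if wh is not None:
        w, h = wh
        out = (df["cx"] < 0) | (df["cx"] >= w) | (df["cy"] < 0) | (df["cy"] >= h)
        if out.any():
            warnings.warn(
                f"{int(out.sum())} cell centroid(s) outside the tile extent; retained",
                stacklevel=2,
            )
    return df.sort_values("cell_id", ignore_index=True)


def read_expression(path, cells_path=None, genes_path=None) -> pd.DataFrame:
    """Read a cells x genes count matrix as a DataFrame (index ``cell_id``).

    Accepts a dense CSV (first column = cell id, one column per gene) or a
    MatrixMarket ``.mtx`` triplet with row/column name sidecars.  Sidecar
    paths default to ``<stem>_cells.txt`` / ``<stem>_genes.txt`` next to the
    matrix, one name per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if path.suffix == ".mtx":
        cells_path = Path(cells_path or path.with_name(path.stem + "_cells.txt"))
        genes_path = Path(genes_path or path.with_name(path.stem + "_genes.txt"))
        mat = scipy.io.mmread(path)
        cells = cells_path.read_text().split()
        genes = genes_path.read_text().split()
        df = pd.DataFrame(
            np.asarray(scipy.sparse.coo_matrix(mat).todense()),
            index=pd.Index(cells, name="cell_id"),
            columns=genes,
        )
    else:
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.index.name = "cell_id"
    if df.index.duplicated().any():
        raise ValidationError("duplicate cell_id rows in expression matrix")
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative counts in expression matrix")
    return df


def write_expression_mtx(expr: pd.DataFrame, path) -> None:
    """Write a cells x genes DataFrame as MTX + name sidecars (see reader)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(expr.to_numpy()))
    path.with_name(path.stem + "_cells.txt").write_text(
        "\n".join(map(str, expr.index)) + "\n"
    )
    path.with_name(path.stem + "_genes.txt").write_text(
        "\n".join(map(str, expr.columns)) + "\n"
    )


def write_post_stitch_positions(table: pd.DataFrame, path) -> Path:
    """Write the post-stitch offset table as CSV with canonical headers.

    *table* must have columns ``fov, x_offset, y_offset`` (or already the
    canonical file headers) with min offset 0 on each axis.
    """
    df = table.rename(
        columns={"x_offset": "x_offset_px", "y_offset": "y_offset_px"}
    )[list(POST_STITCH_COLUMNS)]
    if len(df) == 0:
        raise ValidationError("post-stitch position table is empty")
    if df["x_offset_px"].min() != 0 or df["y_offset_px"].min() != 0:
        raise ValidationError("post-stitch offsets must have minimum 0 on each axis")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_post_stitch_positions(path) -> pd.DataFrame:
    """Read the post-stitch offset table (columns ``fov, x_offset, y_offset``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"post-stitch position file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in POST_STITCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"post-stitch file {path} missing column(s) {missing}")
    df = df.rename(columns={"x_offset_px": "x_offset", "y_offset_px": "y_offset"})
    df = df.astype({"fov": np.int64, "x_offset": np.int64, "y_offset": np.int64})
    if df["fov"].duplicated().any():
        raise ValidationError("duplicate FOV id(s) in post-stitch file")
    return df.sort_values("fov", ignore_index=True)
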