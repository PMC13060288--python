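"""Spatial visualization on the downsampled whole-slide overview.

The overview (stitched mosaic downsampled by ``factor``, default 20) is
turned into a background canvas: Gaussian blur of the channel-mean
grayscale, Otsu thresholding to separate bright tissue from dark field,
and recoloring of the tissue mask with a user-chosen color over a blanked
(black) background.  Cell types, transcript locations, and cell- or
FOV-level expression are then overlaid.

Every overlay uses the same placement transform: whole-slide pixel
coordinate divided by the downsample factor (see :func:`canvas_coords`).
Coordinates are kept at full precision and only rasterized at draw time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
import matplotlib.cm
import matplotlib.colors
import matplotlib.patches
from skimage.filters import gaussian, threshold_otsu

from .errors import ValidationError
from .geojson import local_to_global
from .palette import assign_colors

DPI = 100
DEFAULT_TISSUE_COLOR = (70, 110, 90)
DEFAULT_CMAP = "viridis"  # perceptually uniform sequential


@dataclass
class BackgroundCanvas:
    """RGB plotting canvas at overview resolution plus its tissue mask."""

    image: np.ndarray  # (H, W, 3) uint8
    factor: int
    tissue_mask: np.ndarray  # (H, W) bool

    def __post_init__(self):
        if self.factor <= 0:
            raise ValidationError("canvas factor must be positive")
        if self.tissue_mask.shape != self.image.shape[:2]:
            raise ValidationError("tissue mask dims must equal image dims")


@dataclass
class FovExpressionSummary:
    """Per-FOV mean expression of one gene; empty FOVs listed separately."""

    table: pd.DataFrame  # columns: fov, gene, mean_expression
    empty_fovs: list = field(default_factory=list)

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)
        return path


def canvas_coords(x_global, y_global, factor):
    """Whole-slide pixels -> overview-canvas coordinates (shared by all plots)."""
    return np.asarray(x_global, dtype=np.float64) / factor, np.asarray(
        y_global, dtype=np.float64
    ) / factor


def make_background(
    overview: np.ndarray,
    sigma: float = 2.0,
    tissue_color=DEFAULT_TISSUE_COLOR,
    factor: int = 20,
) -> BackgroundCanvas:
    """Detect tissue on the overview and recolor it onto a dark canvas.

    Grayscale is the mean over channels; after a Gaussian blur of *sigma*
    px, Otsu's threshold splits bright (tissue) from dark (background).
    A uniform image leaves Otsu undefined: the mask is empty and a warning
    is issued.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    arr = np.asarray(overview, dtype=np.float64)
    if arr.size == 0:
        raise ValidationError("overview image is empty")
    gray = arr.mean(axis=0) if arr.ndim == 3 else arr
    blurred = gaussian(gray, sigma=sigma, preserve_range=True) if sigma > 0 else gray
    if np.ptp(blurred) == 0:
        warnings.warn(
            "overview is uniform; Otsu threshold undefined, mask left empty",
            stacklevel=2,
        )
        mask = np.zeros(gray.shape, dtype=bool)
    else:
        mask = blurred > threshold_otsu(blurred)
    image = np.zeros((*gray.shape, 3), dtype=np.uint8)
    image[mask] = np.asarray(tissue_color, dtype=np.uint8)
    return BackgroundCanvas(image=image, factor=int(factor), tissue_mask=mask)


def _new_figure(canvas: BackgroundCanvas):
    h, w = canvas.image.shape[:2]
    fig = Figure(figsize=(max(w, 1) / DPI, max(h, 1) / DPI), dpi=DPI)
    FigureCanvasAgg(fig)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.imshow(canvas.image, interpolation="nearest")
    ax.set_xlim(-0.5, w - 0.5)
    ax.set_ylim(h - 0.5, -0.5)
    ax.set_axis_off()
    return fig, ax


def _save(fig: Figure, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=DPI)
    return path


def plot_cell_types(
    canvas: BackgroundCanvas,
    metadata: pd.DataFrame,
    offsets: pd.DataFrame,
    out_path,
    palette: dict | None = None,
    point_size: float = 4.0,
) -> Path:
    """Scatter cell centroids on the canvas, colored by cell type."""
    fig, ax = _new_figure(canvas)
    if len(metadata):
        xg, yg = local_to_global(
            metadata["cx"].to_numpy(), metadata["cy"].to_numpy(),
            metadata["fov"].to_numpy(), offsets,
        )
        cx, cy = canvas_coords(xg, yg, canvas.factor)
        types = (
            metadata["cell_type"].fillna("unassigned").astype(str)
            if "cell_type" in metadata.columns
            else pd.Series(["cell"] * len(metadata))
        )
        if palette is None:
            palette = assign_colors(types.unique())
        for label in sorted(types.unique()):
            sel = (types == label).to_numpy()
            rgb = np.asarray(palette[label]) / 255.0
            ax.scatter(cx[sel], cy[sel], s=point_size, color=rgb, label=label,
                       linewidths=0)
        ax.legend(loc="upper right", fontsize=6, markerscale=2)
    return _save(fig, out_path)


def plot_transcripts(
    canvas: BackgroundCanvas,
    transcripts: pd.DataFrame,
    genes,
    offsets: pd.DataFrame,
    mode: str,
    out_dir,
    palette: dict | None = None,
    point_size: float = 2.0,
) -> list[Path]:
    """Overlay transcript locations for *genes*.

    ``mode="s"``: one figure per gene (``transcripts_<gene>.png``);
    ``mode="m"``: a single figure with all genes overlaid in distinct
    colors (``transcripts_multi.png``).
    """
    if mode not in ("s", "m"):
        raise ValidationError(f"mode must be 's' or 'm', got {mode!r}")
    genes = sorted({str(g) for g in genes})
    if not genes:
        raise ValidationError("genes must be non-empty")
    if palette is None:
        palette = assign_colors(genes)
    out_dir = Path(out_dir)

    sub = transcripts[transcripts["gene"].astype(str).isin(genes)]
    if len(sub):
        xg, yg = local_to_global(
            sub["x_local"].to_numpy(), sub["y_local"].to_numpy(),
            sub["fov"].to_numpy(), offsets,
        )
        cx, cy = canvas_coords(xg, yg, canvas.factor)
    else:
        cx = cy = np.array([])
    gene_col = sub["gene"].astype(str).to_numpy() if len(sub) else np.array([])

    paths = []
    if mode == "s":
        for gene in genes:
            fig, ax = _new_figure(canvas)
            sel = gene_col == gene
            rgb = np.asarray(palette[gene]) / 255.0
            ax.scatter(cx[sel], cy[sel], s=point_size, color=rgb, label=gene,
                       linewidths=0)
            ax.legend(loc="upper right", fontsize=6, markerscale=3)
            paths.append(_save(fig, out_dir / f"transcripts_{gene}.png"))
    else:
        fig, ax = _new_figure(canvas)
        for gene in genes:
            sel = gene_col == gene
            rgb = np.asarray(palette[gene]) / 255.0
            ax.scatter(cx[sel], cy[sel], s=point_size, color=rgb, label=gene,
                       linewidths=0)
        ax.legend(loc="upper right", fontsize=6, markerscale=3)
        paths.append(_save(fig, out_dir / "transcripts_multi.png"))
    return paths


def normalize_counts(values: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a degenerate range maps to mid-scale."""
    v = np.asarray(values, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full(v.shape, 0.5)
    return (v - lo) / (hi - lo)


def plot_cell_expression(
    canvas: BackgroundCanvas,
    metadata: pd.DataFrame,
    expression: pd.DataFrame,
    gene: str,
    offsets: pd.DataFrame,
    out_path,
    cmap: str = DEFAULT_CMAP,
    point_size: float = 4.0,
) -> Path:
    """Color each cell centroid by its count for *gene* on a continuous scale.

    The scale is min-max normalized over the plotted cells; equal counts
    everywhere collapse to mid-scale.  A colorbar shows the count range.
    """
    if gene not in expression.columns:
        raise ValidationError(f"gene {gene!r} not present in expression matrix")
    meta = metadata[metadata["cell_id"].isin(expression.index)]
    counts = expression.loc[meta["cell_id"], gene].to_numpy(dtype=np.float64)
    xg, yg = local_to_global(
        meta["cx"].to_numpy(), meta["cy"].to_numpy(), meta["fov"].to_numpy(), offsets
    )
    cx, cy = canvas_coords(xg, yg, canvas.factor)
    fig, ax = _new_figure(canvas)
    cm = matplotlib.colormaps[cmap]
    sc = ax.scatter(
        cx, cy, s=point_size, c=cm(normalize_counts(counts)), linewidths=0
    )
    lo, hi = (counts.min(), counts.max()) if len(counts) else (0, 1)
    norm = matplotlib.colors.Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1)
    fig.colorbar(
        matplotlib.cm.ScalarMappable(norm=norm, cmap=cm),
        ax=ax, fraction=0.04, label=gene,
    )
    del sc
    return _save(fig, out_path)


def fov_mean_expression(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    gene: str,
    fovs=None,
) -> FovExpressionSummary:
    """Average counts of *gene* per cell within each FOV.

    *fovs* optionally gives the full FOV universe (e.g. from the position
    table); FOVs with no cells are excluded from the table and listed in
    ``empty_fovs``.  Cells present in the expression matrix but absent from
    the metadata cannot be assigned a FOV and raise an error.
    """
    if gene not in expression.columns:
        raise ValidationError(f"gene {gene!r} not present in expression matrix")
    meta_ids = set(metadata["cell_id"])
    orphans = [c for c in expression.index if c not in meta_ids]
    if orphans:
        raise ValidationError(
            f"cell(s) in expression matrix missing from metadata: {sorted(orphans)}"
        )
    joined = metadata[["cell_id", "fov"]].merge(
        expression[[gene]], left_on="cell_id", right_index=True, how="inner"
    )
    means = joined.groupby("fov")[gene].mean()
    universe = (
        sorted({int(f) for f in fovs}) if fovs is not None else sorted(means.index)
    )
    empty = [f for f in universe if f not in means.index]
    table = pd.DataFrame(
        {
            "fov": [f for f in universe if f in means.index],
            "gene": gene,
            "mean_expression": [means[f] for f in universe if f in means.index],
        }
    )
    return FovExpressionSummary(table=table, empty_fovs=empty)


def plot_fov_expression(
    canvas: BackgroundCanvas,
    summary: FovExpressionSummary,
    offsets: pd.DataFrame,
    tile,
    out_path,
    cmap: str = DEFAULT_CMAP,
) -> Path:
    """Fill each FOV's rectangle with the color of its mean expression."""
    if len(summary.table) == 0:
        raise ValidationError("FOV expression summary is empty")
    off = offsets.set_index("fov")
    cm = matplotlib.colormaps[cmap]
    means = summary.table["mean_expression"].to_numpy(dtype=np.float64)
    colors = cm(normalize_counts(means))
    fig, ax = _new_figure(canvas)
    f = canvas.factor
    for (_, row), color in zip(summary.table.iterrows(), colors):
        x0, y0 = canvas_coords(
            off.at[int(row["fov"]), "x_offset"], off.at[int(row["fov"]), "y_offset"], f
        )
        rect = matplotlib.patches.Rectangle(
            (x0 - 0.5, y0 - 0.5), tile.width / f, tile.height / f,
            facecolor=color, edgecolor="none", alpha=0.85,
        )
        ax.add_patch(rect)
    lo, hi = means.min(), means.max()
    norm = matplotlib.colors.Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1)
    gene = summary.table["gene"].iloc[0]
    fig.colorbar(
        matplotlib.cm.ScalarMappable(norm=norm, cmap=cm),
        ax=ax, fraction=0.04, label=f"mean {gene} per cell",
    )
    return _save(fig, out_path)
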