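"""Column-mapping and run configuration.

AtoMx exports from different software versions use different CSV headers.
All readers in :mod:`smibridge.io` therefore go through a :class:`ColumnMap`
that maps the canonical schema (the names the package uses internally) onto
the actual file headers, and records the coordinate units of the position
file.

Canonical column names
----------------------
======================  ==========================================
table                   canonical columns (internal -> default header)
======================  ==========================================
FOV positions           fov -> ``fov``, x -> ``x_global_px``, y -> ``y_global_px``
cell polygons           cell_id -> ``cell_ID``, fov -> ``fov``,
                        vertex_index -> ``vertex_index``,
                        x_local -> ``x_local_px``, y_local -> ``y_local_px``
transcripts             gene -> ``target``, fov -> ``fov``,
                        x_local -> ``x_local_px``, y_local -> ``y_local_px``,
                        cell_id -> ``cell_ID`` (optional)
cell metadata           cell_id -> ``cell_ID``, fov -> ``fov``,
                        cx -> ``CenterX``, cy -> ``CenterY``,
                        cell_type -> ``cell_type`` (optional)
======================  ==========================================

Coordinates are 0-based pixels with origin at the image top-left and y
increasing downward.  Position files in millimetres require an explicit
``mm_to_px`` scale; an optional ``y_flip`` negates global y for exports
whose stage axis points up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ValidationError

_DEFAULTS = {
    "fov_positions": {"fov": "fov", "x": "x_global_px", "y": "y_global_px"},
    "polygons": {
        "cell_id": "cell_ID",
        "fov": "fov",
        "vertex_index": "vertex_index",
        "x_local": "x_local_px",
        "y_local": "y_local_px",
    },
    "transcripts": {
        "gene": "target",
        "fov": "fov",
        "x_local": "x_local_px",
        "y_local": "y_local_px",
        "cell_id": "cell_ID",
    },
    "metadata": {
        "cell_id": "cell_ID",
        "fov": "fov",
        "cx": "CenterX",
        "cy": "CenterY",
        "cell_type": "cell_type",
    },
}

#: canonical columns that may be absent from a file without error
OPTIONAL_COLUMNS = {
    "transcripts": {"cell_id"},
    "metadata": {"cell_type"},
}


@dataclass
class ColumnMap:
    """Maps canonical table schemas onto actual export headers.

    Parameters
    ----------
    fov_positions, polygons, transcripts, metadata
        Partial ``{canonical: header}`` overrides; unspecified entries keep
        the canonical defaults above.
    units
        ``"px"`` (default) or ``"mm"``.  Millimetre positions are converted
        on read using ``mm_to_px``.
    mm_to_px
        Pixels per millimetre; required (and > 0) when ``units == "mm"``.
    y_flip
        Negate the global y coordinate of FOV positions on read.
    """

    fov_positions: dict = field(default_factory=dict)
    polygons: dict = field(default_factory=dict)
    transcripts: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    units: str = "px"
    mm_to_px: float | None = None
    y_flip: bool = False

    def __post_init__(self):
        if self.units not in ("px", "mm"):
            raise ValidationError(f"units must be 'px' or 'mm', got {self.units!r}")
        if self.units == "mm":
            if self.mm_to_px is None or not self.mm_to_px > 0:
                raise ValidationError(
                    "units='mm' requires a positive mm_to_px scale factor"
                )
        for table in _DEFAULTS:
            merged = {**_DEFAULTS[table], **getattr(self, table)}
            unknown = set(getattr(self, table)) - set(_DEFAULTS[table])
            if unknown:
                raise ValidationError(
                    f"unknown canonical column(s) {sorted(unknown)} for table {table!r}"
                )
            headers = list(merged.values())
            if len(headers) != len(set(headers)):
                raise ValidationError(
                    f"column map for {table!r} maps two canonical columns "
                    f"to the same header: {merged}"
                )
            setattr(self, table, merged)

    def resolve(self, table: str) -> dict:
        """Return the full ``{canonical: header}`` mapping for *table*."""
        return dict(getattr(self, table))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnMap":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ColumnMap":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
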