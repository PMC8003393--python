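"""Categorical land-cover rasters: ESRI ASCII I/O, legend reclassification, buffer clipping.

The analysis operates on small categorical rasters clipped to a riparian
buffer.  Cells are squares (default 10 m side), the origin is the top-left
corner, and cells outside the buffer carry the nodata code.  No CRS handling
is done here: the pipeline consumes rasters that have already been projected
and clipped upstream, or synthetic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "URBAN",
    "AGRICULTURE",
    "FOREST",
    "OTHER",
    "CATEGORY_NAMES",
    "LandCoverGrid",
    "Legend",
    "DEFAULT_LEGEND",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_legend",
    "reclassify",
    "clip_to_mask",
]

# Analysis categories after reclassification.
URBAN = 1
AGRICULTURE = 2
FOREST = 3
OTHER = 4

CATEGORY_NAMES = {URBAN: "URBAN", AGRICULTURE: "AGRICULTURE", FOREST: "FOREST", OTHER: "OTHER"}
_NAME_TO_CATEGORY = {v: k for k, v in CATEGORY_NAMES.items()}


class GridFormatError(ValueError):
    """Raised when an ESRI ASCII grid file is malformed."""


@dataclass
class LandCoverGrid:
    """A categorical raster with square cells and an integer nodata code.

    ``values`` is a 2-D integer array, row 0 at the top.  ``cell_size`` is
    the cell side length in meters.
    """

    values: np.ndarray
    cell_size: float = 10.0
    nodata: int = -9999
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got shape {self.values.shape}")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError(f"grid values must be integer, got dtype {self.values.dtype}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells inside the buffer (not nodata)."""
        return self.values != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def cell_area_m2(self) -> float:
        return float(self.cell_size) ** 2

    @property
    def landscape_area_m2(self) -> float:
        """Total valid (non-nodata) area in m² — the metric denominator."""
        return self.n_valid * self.cell_area_m2

    def codes(self) -> np.ndarray:
        """Sorted unique non-nodata codes present in the grid."""
        vals = self.values[self.valid_mask]
        return np.unique(vals)


@dataclass(frozen=True)
class Legend:
    """Total mapping from raw land-cover codes to analysis categories.

    Every raw code in a raster must be covered; each raw code maps to
    exactly one of URBAN, AGRICULTURE, FOREST, OTHER.
    """

    mapping: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in CATEGORY_NAMES}
        if bad:
            raise ValueError(f"legend maps to unknown categories: {sorted(bad)}")


# The Korean MOE land-cover map has 7 major categories; the analysis merges
# forested and grassy areas into one vegetated category and pools wetland,
# barren soil and water as OTHER.
DEFAULT_LEGEND = Legend(
    mapping={
        1: URBAN,        # residential / industrial / commercial / roads
        2: AGRICULTURE,  # paddy fields, farms, orchards
        3: FOREST,       # forest
        4: FOREST,       # grassy areas (merged with forest)
        5: OTHER,        # wetlands
        6: OTHER,        # barren soil
        7: OTHER,        # water
    }
)

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path) -> LandCoverGrid:
    """Read an ESRI ASCII grid (.asc) with integer cell values.

    The header must provide ncols, nrows, xllcorner, yllcorner and cellsize;
    NODATA_value is optional (default -9999).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"{path}: bad header line {i + 1}: {line!r}") from exc
        else:
            break
    else:
        i += 1  # file was all header

    missing = [k for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize") if k not in header]
    if missing:
        raise GridFormatError(f"{path}: header missing {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = int(header.get("nodata_value", -9999))

    rows = []
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        try:
            row = [int(float(tok)) for tok in line.split()]
        except ValueError as exc:
            raise GridFormatError(f"{path}: bad data line {lineno}: {line!r}") from exc
        if len(row) != ncols:
            raise GridFormatError(
                f"{path}: line {lineno} has {len(row)} values, expected ncols={ncols}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridFormatError(f"{path}: found {len(rows)} data rows, expected nrows={nrows}")

    values = np.array(rows, dtype=np.int64)
    return LandCoverGrid(
        values=values,
        cell_size=header["cellsize"],
        nodata=nodata,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
    )


def write_ascii_grid(grid: LandCoverGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid; integer cell values are preserved exactly."""
    path = Path(path)

    def _num(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    with path.open("w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {_num(grid.xllcorner)}\n")
        fh.write(f"yllcorner {_num(grid.yllcorner)}\n")
        fh.write(f"cellsize {_num(grid.cell_size)}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        for row in grid.values:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_legend(path: str | Path) -> Legend:
    """Read a two-column delimited mapping file: raw_code <sep> category name or code."""
    mapping: dict[int, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").replace("\t", " ").split()
        if len(parts) != 2:
            raise ValueError(f"legend line {lineno}: expected 2 columns, got {line!r}")
        raw = int(parts[0])
        cat_tok = parts[1].upper()
        if cat_tok in _NAME_TO_CATEGORY:
            mapping[raw] = _NAME_TO_CATEGORY[cat_tok]
        else:
            mapping[raw] = int(cat_tok)
    return Legend(mapping=mapping)


def reclassify(grid: LandCoverGrid, legend: Legend = DEFAULT_LEGEND) -> LandCoverGrid:
    """Map raw land-cover codes to the analysis categories.

    Nodata cells are preserved; shape and cell size are unchanged.  Raises if
    the grid has no valid cells or contains a code the legend does not map.
    """
    valid = grid.valid_mask
    if not valid.any():
        raise ValueError("grid has no valid (non-nodata) cells")
    present = np.unique(grid.values[valid])
    unmapped = [int(c) for c in present if int(c) not in legend.mapping]
    if unmapped:
        counts = {c: int((grid.values == c).sum()) for c in unmapped}
        raise ValueError(f"legend does not map codes (code: cell count): {counts}")

    out = np.full(grid.shape, grid.nodata, dtype=np.int64)
    for raw, cat in legend.mapping.items():
        out[grid.values == raw] = cat
    out[~valid] = grid.nodata
    return replace(grid, values=out)


def clip_to_mask(grid: LandCoverGrid, mask: np.ndarray) -> LandCoverGrid:
    """Set cells outside ``mask`` (boolean, same shape) to nodata."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    out = grid.values.copy()
    out[~mask] = grid.nodata
    return replace(grid, values=out)
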