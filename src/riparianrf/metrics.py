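"""Class-level landscape pattern metrics: LPI, PLAND, PD, ED.

Patches are maximal connected components of same-class cells (8-neighbor
rule by default, the FRAGSTATS convention; configurable to 4).  All four
metrics are normalized by the total valid landscape area — the area of the
riparian buffer — and reported in FRAGSTATS units:

* LPI, PLAND — percent of landscape area,
* PD — patches per 100 ha,
* ED — meters of class edge per hectare.

Edges are cell sides shared by a class cell and a cell of any other class.
By default the landscape/nodata boundary (the buffer outline) is excluded,
so clipping does not inflate ED; set ``include_boundary=True`` to count it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import AGRICULTURE, FOREST, URBAN, LandCoverGrid

__all__ = [
    "PatchLabeling",
    "label_patches",
    "lpi",
    "pland",
    "pd_metric",
    "ed_metric",
    "compute_class_metrics",
    "METRIC_COLUMNS",
    "PROPORTION_COLUMNS",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)

# Table-style column names: class prefix × metric suffix.
_CLASS_PREFIX = {URBAN: "Urban", AGRICULTURE: "Agricultural", FOREST: "Forest"}
PROPORTION_COLUMNS = ["urban_pct", "agri_pct", "forest_pct"]
METRIC_COLUMNS = [
    f"{prefix}_{suffix}"
    for prefix in ("Urban", "Agricultural", "Forest")
    for suffix in ("LPI", "PLAND", "PD", "ED")
]


@dataclass
class PatchLabeling:
    """Connected-component labeling of one class within a landscape.

    ``labels`` uses 0 for cells not of this class and 1..n_patches for the
    patches, numbered in row-major order of each patch's first cell.  Edge
    lengths are provided both excluding and including the landscape/nodata
    boundary so the ED flag can be resolved later.
    """

    labels: np.ndarray
    n_patches: int
    patch_areas: np.ndarray           # m², index p-1 for patch p
    patch_edge_lengths: np.ndarray    # m, boundary excluded
    patch_edge_lengths_with_boundary: np.ndarray  # m, boundary included


def _relabel_row_major(labels: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """Renumber components so patch 1 is the one whose first cell comes first in row-major scan."""
    if n == 0:
        return labels, 0
    flat = labels.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reverse scan so the earliest index wins
    for i in nz[::-1]:
        first_idx[flat[i]] = i
    order = np.argsort(first_idx[1:], kind="stable")  # old label-1 → rank
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[order + 1] = np.arange(1, n + 1)
    return remap[labels], n


def label_patches(grid: LandCoverGrid, category: int, connectivity: int = 8) -> PatchLabeling:
    """Label the patches of ``category`` in a reclassified grid.

    Labels are deterministic: patches are numbered by the row-major position
    of their first cell.  An absent class yields ``n_patches == 0``.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    struct = _STRUCT4 if connectivity == 4 else _STRUCT8
    class_mask = (grid.values == category) & grid.valid_mask
    raw_labels, n = ndimage.label(class_mask, structure=struct)
    labels, n = _relabel_row_major(raw_labels.astype(np.int64), int(n))

    cell_area = grid.cell_area_m2
    if n:
        areas = np.bincount(labels.ravel(), minlength=n + 1)[1:] * cell_area
    else:
        areas = np.zeros(0)

    # Edge length per patch: count cell sides adjoining a different class.
    # Pad with nodata so the grid exterior behaves like the buffer boundary.
    padded_vals = np.pad(grid.values, 1, constant_values=grid.nodata)
    edge_excl = np.zeros(n + 1, dtype=np.int64)
    edge_incl = np.zeros(n + 1, dtype=np.int64)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded_vals[1 + dr : padded_vals.shape[0] - 1 + dr,
                         1 + dc : padded_vals.shape[1] - 1 + dc]
        here = class_mask
        diff = here & (nb != category)
        nodata_nb = here & (nb == grid.nodata)
        edge_incl += np.bincount(labels[diff], minlength=n + 1)
        edge_excl += np.bincount(labels[diff & ~nodata_nb], minlength=n + 1)
    side = grid.cell_size
    return PatchLabeling(
        labels=labels,
        n_patches=n,
        patch_areas=areas,
        patch_edge_lengths=edge_excl[1:] * side,
        patch_edge_lengths_with_boundary=edge_incl[1:] * side,
    )


def lpi(labeling: PatchLabeling, landscape_area_m2: float) -> float:
    """Largest patch index: largest patch area as % of landscape area."""
    if landscape_area_m2 <= 0:
        raise ValueError("landscape area must be positive")
    if labeling.n_patches == 0:
        return 0.0
    return 100.0 * float(labeling.patch_areas.max()) / landscape_area_m2


def pland(labeling: PatchLabeling, landscape_area_m2: float) -> float:
    """Percentage of landscape: total class area as % of landscape area."""
    if landscape_area_m2 <= 0:
        raise ValueError("landscape area must be positive")
    return 100.0 * float(labeling.patch_areas.sum()) / landscape_area_m2


def pd_metric(labeling: PatchLabeling, landscape_area_m2: float) -> float:
    """Patch density: patches per 100 ha (= per 10^6 m²)."""
    if landscape_area_m2 <= 0:
        raise ValueError("landscape area must be positive")
    return labeling.n_patches / landscape_area_m2 * 1e6


def ed_metric(
    labeling: PatchLabeling, landscape_area_m2: float, include_boundary: bool = False
) -> float:
    """Edge density: class edge length (m) per hectare of landscape."""
    if landscape_area_m2 <= 0:
        raise ValueError("landscape area must be positive")
    lengths = (
        labeling.patch_edge_lengths_with_boundary
        if include_boundary
        else labeling.patch_edge_lengths
    )
    return float(lengths.sum()) / (landscape_area_m2 / 1e4)


def compute_class_metrics(
    grid: LandCoverGrid, connectivity: int = 8, include_boundary: bool = False
) -> pd.Series:
    """Compute the 3 land-cover proportions and the 12 class-level metrics.

    Returns a Series with ``urban_pct, agri_pct, forest_pct`` followed by
    ``{Urban,Agricultural,Forest}_{LPI,PLAND,PD,ED}``.  Proportions use the
    same denominator as the metrics: all valid cells in the buffer.
    """
    if grid.n_valid == 0:
        raise ValueError("grid has no valid (non-nodata) cells")
    area = grid.landscape_area_m2
    out: dict[str, float] = {}
    valid_vals = grid.values[grid.valid_mask]
    for cat, pct_name in zip((URBAN, AGRICULTURE, FOREST), PROPORTION_COLUMNS):
        out[pct_name] = 100.0 * float((valid_vals == cat).sum()) / grid.n_valid
    for cat in (URBAN, AGRICULTURE, FOREST):
        prefix = _CLASS_PREFIX[cat]
        lab = label_patches(grid, cat, connectivity=connectivity)
        out[f"{prefix}_LPI"] = lpi(lab, area)
        out[f"{prefix}_PLAND"] = pland(lab, area)
        out[f"{prefix}_PD"] = pd_metric(lab, area)
        out[f"{prefix}_ED"] = ed_metric(lab, area, include_boundary=include_boundary)
    return pd.Series(out)
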