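"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from riparianrf.grids import AGRICULTURE, FOREST, OTHER, URBAN, LandCoverGrid

NODATA = -9999


def make_grid(values, cell_size=10.0, nodata=NODATA) -> LandCoverGrid:
    return LandCoverGrid(values=np.asarray(values, dtype=np.int64), cell_size=cell_size, nodata=nodata)


def flood_fill_labels(values: np.ndarray, category: int, connectivity: int, nodata=NODATA):
    """Independent patch-labeling oracle: stack-based flood fill, row-major seeds."""
    nrows, ncols = values.shape
    labels = np.zeros((nrows, ncols), dtype=int)
    if connectivity == 4:
        offsets = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    nxt = 0
    for r0 in range(nrows):
        for c0 in range(ncols):
            if values[r0, c0] == category and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < nrows
                            and 0 <= cc < ncols
                            and values[rr, cc] == category
                            and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels, nxt


def brute_force_edge_length(
    values: np.ndarray, category: int, cell_size: float, include_boundary: bool, nodata=NODATA
) -> float:
    """Count unlike cell-side adjacencies of a class one side at a time."""
    nrows, ncols = values.shape
    total = 0
    for r in range(nrows):
        for c in range(ncols):
            if values[r, c] != category:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    nb = values[rr, cc]
                else:
                    nb = nodata
                if nb == category:
                    continue
                if nb == nodata and not include_boundary:
                    continue
                total += 1
    return total * cell_size


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_category_grids(rng):
    """Random 12x12 categorical grids (with some nodata) for oracle comparisons."""
    grids = []
    for _ in range(50):
        vals = rng.integers(1, 5, size=(12, 12)).astype(np.int64)
        holes = rng.random((12, 12)) < 0.1
        vals[holes] = NODATA
        grids.append(make_grid(vals))
    return grids


ALL_CATEGORIES = (URBAN, AGRICULTURE, FOREST, OTHER)
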