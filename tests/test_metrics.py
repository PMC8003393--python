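"""Patch labeling and the four class-level pattern metrics."""

import numpy as np
import pytest

from riparianrf.grids import AGRICULTURE, FOREST, OTHER, URBAN
from riparianrf.metrics import (
    METRIC_COLUMNS,
    compute_class_metrics,
    ed_metric,
    label_patches,
    lpi,
    pd_metric,
    pland,
)

from conftest import (
    ALL_CATEGORIES,
    NODATA,
    brute_force_edge_length,
    flood_fill_labels,
    make_grid,
)


def same_partition(labels_a, labels_b, n_a, n_b) -> bool:
    """Two labelings describe the same patches up to renumbering."""
    if n_a != n_b:
        return False
    mapping = {}
    for la, lb in zip(labels_a.ravel(), labels_b.ravel()):
        if (la == 0) != (lb == 0):
            return False
        if la:
            if mapping.setdefault(la, lb) != lb:
                return False
    return len(set(mapping.values())) == len(mapping)


class TestLabeling:
    def test_diagonal_cells_split_by_connectivity(self):
        grid = make_grid([[1, 4], [4, 1]])
        assert label_patches(grid, URBAN, connectivity=8).n_patches == 1
        assert label_patches(grid, URBAN, connectivity=4).n_patches == 2

    def test_uniform_grid_is_one_patch(self):
        grid = make_grid(np.full((5, 5), FOREST))
        lab = label_patches(grid, FOREST)
        assert lab.n_patches == 1
        assert lab.patch_areas.sum() == 25 * 100

    def test_labels_are_row_major_deterministic(self):
        grid = make_grid([[4, 1, 4], [1, 4, 4], [4, 4, 1]])
        lab = label_patches(grid, URBAN, connectivity=4)
        # first patch is the one containing the earliest row-major cell
        first_cells = [np.argwhere(lab.labels == p)[0] for p in range(1, lab.n_patches + 1)]
        flat = [int(r * 3 + c) for r, c in first_cells]
        assert flat == sorted(flat)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, random_category_grids, connectivity):
        for grid in random_category_grids:
            for cat in ALL_CATEGORIES:
                lab = label_patches(grid, cat, connectivity=connectivity)
                oracle_labels, oracle_n = flood_fill_labels(grid.values, cat, connectivity)
                assert same_partition(lab.labels, oracle_labels, lab.n_patches, oracle_n)
                # area accounting
                n_cells = int(((grid.values == cat)).sum())
                assert lab.patch_areas.sum() == pytest.approx(n_cells * grid.cell_area_m2)


class TestHandComputedMetrics:
    def test_lpi_three_cells_of_sixteen(self):
        vals = np.full((4, 4), OTHER)
        vals[0, :3] = URBAN
        grid = make_grid(vals)
        lab = label_patches(grid, URBAN)
        assert lpi(lab, grid.landscape_area_m2) == pytest.approx(18.75)

    def test_pland_two_patches(self):
        vals = np.full((4, 4), OTHER)
        vals[0, :3] = URBAN  # 3-cell patch
        vals[3, 3] = URBAN   # isolated cell
        grid = make_grid(vals)
        lab = label_patches(grid, URBAN)
        assert lab.n_patches == 2
        assert pland(lab, grid.landscape_area_m2) == pytest.approx(25.0)

    def test_pd_single_patch(self):
        vals = np.full((4, 4), OTHER)
        vals[1:3, 1:3] = FOREST
        grid = make_grid(vals)
        lab = label_patches(grid, FOREST)
        assert pd_metric(lab, grid.landscape_area_m2) == pytest.approx(625.0)

    def test_ed_interior_square(self):
        vals = np.full((4, 4), OTHER)
        vals[1:3, 1:3] = FOREST
        grid = make_grid(vals)
        lab = label_patches(grid, FOREST)
        # 2x2 patch of 10 m cells: perimeter 80 m over 0.16 ha
        assert ed_metric(lab, grid.landscape_area_m2) == pytest.approx(500.0)

    def test_empty_class_is_all_zero(self):
        grid = make_grid(np.full((4, 4), OTHER))
        lab = label_patches(grid, URBAN)
        area = grid.landscape_area_m2
        assert lab.n_patches == 0
        assert lpi(lab, area) == pland(lab, area) == pd_metric(lab, area) == 0
        assert ed_metric(lab, area) == 0


class TestMetricProperties:
    def test_lpi_le_pland_with_equality_iff_single_patch(self, random_category_grids):
        for grid in random_category_grids:
            area = grid.landscape_area_m2
            for cat in ALL_CATEGORIES:
                lab = label_patches(grid, cat)
                l, p = lpi(lab, area), pland(lab, area)
                assert l <= p + 1e-12
                if lab.n_patches <= 1:
                    assert l == pytest.approx(p)
                else:
                    assert l < p

    def test_edge_length_matches_brute_force(self, random_category_grids):
        for grid in random_category_grids[:15]:
            for cat in ALL_CATEGORIES:
                lab = label_patches(grid, cat)
                for include in (False, True):
                    expect = brute_force_edge_length(grid.values, cat, grid.cell_size, include)
                    got = (
                        lab.patch_edge_lengths_with_boundary if include else lab.patch_edge_lengths
                    ).sum()
                    assert got == pytest.approx(expect)

    def test_pland_sums_to_100_over_all_categories(self, random_category_grids):
        for grid in random_category_grids[:10]:
            if grid.n_valid == 0:
                continue
            area = grid.landscape_area_m2
            total = sum(pland(label_patches(grid, c), area) for c in ALL_CATEGORIES)
            assert total == pytest.approx(100.0)

    def test_merging_adjacent_patches_decrements_count(self):
        vals = np.full((3, 5), OTHER)
        vals[1, 0:2] = URBAN
        vals[1, 3:5] = URBAN
        grid = make_grid(vals)
        assert label_patches(grid, URBAN).n_patches == 2
        vals2 = vals.copy()
        vals2[1, 2] = URBAN  # fill the gap
        assert label_patches(make_grid(vals2), URBAN).n_patches == 1

    def test_cell_size_scaling(self, rng):
        vals = rng.integers(1, 5, size=(10, 10))
        g10 = make_grid(vals, cell_size=10.0)
        g20 = make_grid(vals, cell_size=20.0)
        for cat in ALL_CATEGORIES:
            lab10 = label_patches(g10, cat)
            lab20 = label_patches(g20, cat)
            np.testing.assert_allclose(lab20.patch_areas, 4 * lab10.patch_areas)
            np.testing.assert_allclose(lab20.patch_edge_lengths, 2 * lab10.patch_edge_lengths)
            a10, a20 = g10.landscape_area_m2, g20.landscape_area_m2
            assert pd_metric(lab20, a20) == pytest.approx(pd_metric(lab10, a10) / 4)
            assert ed_metric(lab20, a20) == pytest.approx(ed_metric(lab10, a10) / 2)
            # dimensionless percentages are invariant
            assert pland(lab20, a20) == pytest.approx(pland(lab10, a10))


class TestClassMetricsTable:
    def test_all_forest_grid(self):
        grid = make_grid(np.full((6, 6), FOREST))
        rec = compute_class_metrics(grid)
        assert rec["Forest_LPI"] == rec["Forest_PLAND"] == 100.0
        assert rec["Forest_PD"] == pytest.approx(1e6 / grid.landscape_area_m2)
        assert rec["Forest_ED"] == 0.0  # boundary excluded by default
        for prefix in ("Urban", "Agricultural"):
            for suffix in ("LPI", "PLAND", "PD", "ED"):
                assert rec[f"{prefix}_{suffix}"] == 0.0
        assert rec["forest_pct"] == 100.0

    def test_twelve_pattern_metric_columns(self, rng):
        grid = make_grid(rng.integers(1, 5, size=(8, 8)))
        rec = compute_class_metrics(grid)
        assert [c for c in rec.index if c in METRIC_COLUMNS] == METRIC_COLUMNS
        assert len(METRIC_COLUMNS) == 12

    def test_symmetry_under_transpose_and_rotation(self, rng):
        vals = rng.integers(1, 5, size=(9, 6))
        base = compute_class_metrics(make_grid(vals))
        for variant in (vals.T, np.rot90(vals), np.rot90(vals, 2)):
            rec = compute_class_metrics(make_grid(np.ascontiguousarray(variant)))
            np.testing.assert_allclose(rec.to_numpy(), base.to_numpy())

    def test_empty_grid_rejected(self):
        grid = make_grid(np.full((4, 4), NODATA))
        with pytest.raises(ValueError, match="no valid"):
            compute_class_metrics(grid)
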