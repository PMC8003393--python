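"""Synthetic landscapes, the piecewise-linear response, and the site table."""

import numpy as np
import pandas as pd
import pytest

from riparianrf.grids import FOREST, OTHER, URBAN
from riparianrf.indices import bmi, tdi
from riparianrf.metrics import METRIC_COLUMNS, compute_class_metrics, label_patches, pd_metric
from riparianrf.synth import (
    INDEX_COLUMNS,
    ResponseConfig,
    feature_columns,
    generate_assemblages,
    generate_landscape,
    generate_sites,
    response,
)


class TestResponse:
    def test_baseline_at_origin(self):
        assert response(0, 0, 0) == pytest.approx(55.0)

    def test_forest_plateau(self):
        cfg = ResponseConfig()
        at_knot = response(cfg.tau_forest, 0, 0, cfg)
        assert at_knot == pytest.approx(85.0)
        assert response(100, 0, 0, cfg) == pytest.approx(at_knot)

    def test_urban_saturation(self):
        cfg = ResponseConfig()
        assert response(0, cfg.tau_urban, 0, cfg) == response(0, 100, 0, cfg) == pytest.approx(40.0)

    def test_agri_ramp(self):
        cfg = ResponseConfig()
        assert response(0, 0, 19.99, cfg) == pytest.approx(55.0, abs=0.01)
        assert response(0, 0, 30, cfg) == pytest.approx(55.0 - 7.5)
        assert response(0, 0, 60, cfg) == pytest.approx(40.0)

    def test_piecewise_slopes_by_finite_differences(self):
        cfg = ResponseConfig()
        h = 1e-6

        def slope(f, u, a, df=0.0, du=0.0, da=0.0):
            return float(
                (response(f + df * h, u + du * h, a + da * h, cfg) - response(f, u, a, cfg)) / h
            )

        assert slope(30, 0, 0, df=1) == pytest.approx(cfg.w_forest / cfg.tau_forest, abs=1e-4)
        assert slope(80, 0, 0, df=1) == pytest.approx(0.0, abs=1e-4)
        assert slope(0, 10, 0, du=1) == pytest.approx(-cfg.w_urban / cfg.tau_urban, abs=1e-4)
        assert slope(0, 60, 0, du=1) == pytest.approx(0.0, abs=1e-4)
        assert slope(0, 0, 30, da=1) == pytest.approx(-cfg.w_agri / 20.0, abs=1e-4)
        assert slope(0, 0, 10, da=1) == pytest.approx(0.0, abs=1e-4)

    def test_clipped_to_index_scale(self):
        cfg = ResponseConfig(baseline=5.0, w_urban=40.0, w_agri=40.0)
        assert response(0, 100, 100, cfg) == 0.0


class TestLandscape:
    def test_pure_forest_single_patch(self):
        grid = generate_landscape((0, 0, 100), n_seeds_per_class=1, seed=3)
        assert np.all(grid.values == FOREST)
        rec = compute_class_metrics(grid)
        assert rec["Forest_LPI"] == 100.0

    def test_quotas_met_within_rounding(self):
        for seed in range(5):
            grid = generate_landscape((17, 28, 41), shape=(20, 20), seed=seed)
            n = grid.n_valid
            for cat, pct in ((URBAN, 17), (2, 28), (FOREST, 41)):
                achieved = (grid.values == cat).sum() / n * 100
                assert achieved == pytest.approx(pct, abs=100 / n)  # ±1 cell

    def test_reproducible_per_seed(self):
        a = generate_landscape((20, 30, 40), seed=11)
        b = generate_landscape((20, 30, 40), seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_more_seeds_increase_fragmentation(self):
        # Monte-Carlo: patch density non-decreasing in seeds-per-class
        def mean_pd(n_seeds):
            vals = []
            for seed in range(20):
                grid = generate_landscape((0, 0, 40), n_seeds_per_class=n_seeds,
                                          shape=(24, 24), seed=seed)
                lab = label_patches(grid, FOREST)
                vals.append(pd_metric(lab, grid.landscape_area_m2))
            return np.mean(vals)

        assert mean_pd(6) > mean_pd(1)

    def test_respects_mask(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 3:9] = True
        grid = generate_landscape((10, 20, 30), shape=(12, 12), mask=mask, seed=1)
        assert grid.n_valid == 36
        assert np.all(grid.values[~mask] == grid.nodata)

    def test_infeasible_quota_rejected(self):
        with pytest.raises(ValueError, match="sum <= 100"):
            generate_landscape((60, 60, 10), seed=0)


class TestSiteTable:
    def test_schema(self):
        table = generate_sites(ResponseConfig(n_sites=25, seed=1))
        assert len(table) == 25
        assert list(table.columns[:4]) == ["site_id", "urban_pct", "agri_pct", "forest_pct"]
        assert [c for c in table.columns if c in METRIC_COLUMNS] == METRIC_COLUMNS
        assert all(c in table.columns for c in INDEX_COLUMNS + ["true_response"])
        assert len(feature_columns("15")) == 15 and len(feature_columns("12")) == 12

    def test_noiseless_observation_equals_truth(self):
        table = generate_sites(ResponseConfig(n_sites=30, sigma=0.0, seed=2))
        for name in INDEX_COLUMNS:
            np.testing.assert_allclose(table[name], table["true_response"])

    def test_same_seed_is_byte_identical(self):
        cfg = ResponseConfig(n_sites=40, seed=9)
        a = generate_sites(cfg).to_csv(index=False)
        b = generate_sites(ResponseConfig(n_sites=40, seed=9)).to_csv(index=False)
        assert a == b

    def test_proportions_on_simplex_and_indices_in_range(self):
        table = generate_sites(ResponseConfig(n_sites=200, seed=3))
        sums = table[["urban_pct", "agri_pct", "forest_pct"]].sum(axis=1)
        assert (sums <= 100 + 1e-9).all()
        for name in INDEX_COLUMNS:
            assert table[name].between(0, 100).all()

    def test_forest_mean_matches_survey(self):
        means = [
            generate_sites(ResponseConfig(seed=s))["forest_pct"].mean() for s in (101, 102, 103)
        ]
        assert np.mean(means) == pytest.approx(50.0, abs=3.0)

    def test_raster_mode_measures_real_landscapes(self):
        table = generate_sites(ResponseConfig(n_sites=12, seed=4), mode="raster", shape=(16, 16))
        assert len(table) == 12
        # in raster mode PLAND and the proportion share one denominator exactly
        np.testing.assert_allclose(table["Forest_PLAND"], table["forest_pct"], atol=1e-9)
        np.testing.assert_allclose(table["Urban_PLAND"], table["urban_pct"], atol=1e-9)
        assert (table["Forest_LPI"] <= table["Forest_PLAND"] + 1e-9).all()

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            generate_sites(ResponseConfig(n_sites=10, seed=0), mode="vector")


class TestAssemblages:
    @pytest.mark.parametrize("target", [0, 25, 50, 75, 100])
    def test_round_trip_within_two_points(self, target):
        d = generate_assemblages(target, "diatom", seed=target + 1)
        m = generate_assemblages(target, "macroinvertebrate", seed=target + 1)
        assert abs(tdi(d) - target) <= 2.0
        assert abs(bmi(m) - target) <= 2.0

    def test_perfect_target_forces_uniform_sensitivity(self):
        sample = generate_assemblages(100, "diatom", seed=7)
        np.testing.assert_allclose(sample.sensitivity, 1.0)
        assert tdi(sample) == pytest.approx(100.0)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            generate_assemblages(120, "diatom")

    def test_unknown_organism_rejected(self):
        with pytest.raises(ValueError, match="organism"):
            generate_assemblages(50, "fish")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau_forest": 0}, {"tau_urban": 100}, {"agri_decline": (40, 20)},
            {"sigma": -1}, {"n_sites": 5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ResponseConfig(**kwargs)
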