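# riparianrf

Riparian land-cover pattern metrics, stream biotic-integrity indices,
and random-forest threshold analysis.

How much of a stream's biological condition is explained by what covers
the land in its riparian buffer — and at what point does adding forest
stop helping, or adding urban and agricultural cover start to bite?
`riparianrf` is a reusable pipeline for answering those questions the
way freshwater bioassessment studies do: score sites with multimetric
biotic indices, characterize the buffer with class-level landscape
metrics, fit random forests, and read ecological thresholds off partial
dependence curves with an explicit, reproducible rule instead of by eye.
It is written for stream ecologists and landscape modellers who want the
full chain — from a categorical raster or an assemblage table to a
threshold estimate — as tested, scriptable components.

## What it computes

**Biotic indices** (0–100, higher = better condition):

- Trophic Diatom Index: TDI = 100 − (25·WMS − 25), with weighted mean
  sensitivity WMS = Σ AⱼSⱼVⱼ / Σ AⱼVⱼ over taxa with abundance A,
  pollution sensitivity S ∈ [1,5] and indicator value V ∈ [1,3];
- Benthic Macroinvertebrate Index: BMI = (4 − Σ SⱼHⱼGⱼ / Σ HⱼGⱼ) × 25
  from saprobic values S ∈ [0,4], frequencies H and weights G;
- Fish Assessment Index: the sum of 8 scored assemblage metrics under a
  configurable rubric (the shipped default is a documented synthetic
  stand-in for the unpublished agency breakpoints).

**Landscape pattern metrics** at the class level for urban, agricultural
and forest cover, in FRAGSTATS conventions: largest patch index (LPI, %),
percentage of landscape (PLAND, %), patch density (PD, patches/100 ha)
and edge density (ED, m/ha), from connected-component patches of a
reclassified, buffer-clipped ESRI ASCII raster.

**Modelling**: one `RiparianForestRegressor` per index (scikit-learn
compatible; 500 trees, mtry = ⌊p/3⌋, seeded 70/30 split, held-out RMSE
and MAE) with %IncMSE permutation importance, exact Friedman partial
dependence, and change-point detectors for plateau onsets and
steep-decline intervals.

**Synthetic survey generator**: with no inputs at all, the package
simulates a ~770-site monitoring table (or per-site rasters) whose
indices respond to land cover through a piecewise-linear truth with
change points at 60% forest, 25% urban and 20–40% agriculture — so the
whole pipeline can be validated against a known answer.

## Worked example

```python
from riparianrf import (DiatomSample, tdi, wms,
                        ResponseConfig, generate_sites,
                        fit_rf, RFConfig, partial_dependence, detect_plateau)

# a diatom sample: two taxa, abundances 60/40, sensitivities 2/4, indicator values 1/3
sample = DiatomSample([60, 40], [2, 4], [1, 3])
print(wms(sample), tdi(sample))
# 3.3333333333333335 41.66666666666666

# synthetic survey -> random forest -> importance -> threshold
table = generate_sites(ResponseConfig(seed=1))          # 770 sites
est = fit_rf(table, "TDI", config=RFConfig(seed=1))
print(est.rmse_, est.mae_)                              # 8.83 7.10 (index points)
print(est.importances_.head(3))
#       feature  pct_inc_mse  rank
#    forest_pct        69.67     1
#  Forest_PLAND        36.12     2
#      agri_pct        16.54     3

X = table.iloc[est.train_indices_][list(est.feature_names_in_)]
curve = partial_dependence(est, X, "forest_pct")
print(detect_plateau(curve, alpha=0.1, window=5).location)
# 59.0
```

Reading the output: the WMS of 10/3 maps to a TDI of 41.7 — a degraded
site.  On the synthetic survey the forest predicts held-out TDI to
within ~9 index points of the σ = 8 observation noise; the forest
proportion dominates the importance ranking (%IncMSE 69.7), and the
detected plateau onset of 59.0% recovers the 60% change point built
into the generator.

## Command line

Every stage is also a subcommand of the `riparianrf` CLI, exchanging
CSV/JSON artifacts so stages can run independently:

```bash
riparianrf simulate --seed 1 --out run1
riparianrf fit --sites run1/sites.csv --target all --seed 1 --out run1
riparianrf thresholds --sites run1/sites.csv --seed 1 --out run1
riparianrf run-all --seed 1 --out run1          # everything at once
riparianrf metrics buffer.asc                   # pattern metrics for a raster
riparianrf indices --diatoms diatoms.csv        # TDI from an assemblage table
```

`run-all` writes the site table, per-index importance tables and error
metrics, PD curves, `thresholds.json` and a run manifest; identical
seeds give byte-identical outputs.

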