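"""Synthetic monitoring data with the structure of a riparian bioassessment survey.

The generator emulates a national stream-monitoring site table: per site,
the proportions of urban, agricultural and forested land cover in a 1 km
riparian buffer, twelve class-level pattern metrics, and three biotic
indices (TDI, BMI, FAI) on a 0–100 scale.  The true index response to the
land-cover proportions is piecewise linear with ecologically motivated
change points — an improvement plateauing once riparian forest reaches
τ_F (default 60%), degradation saturating once urban cover reaches τ_U
(default 25%), and an abrupt decline while agricultural cover ramps
through [a_lo, a_hi] (default 20–40%) — so that threshold-recovery by the
downstream model is a well-posed test with a known answer.

Two modes are available: ``tabular`` draws land-cover compositions from a
Dirichlet distribution calibrated to the survey's reported means and
generates pattern metrics as proportion-linked noisy transforms;
``raster`` actually builds a categorical landscape per site by seeded
region growing and measures the metrics with the patch-metrics engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import AGRICULTURE, FOREST, OTHER, URBAN, LandCoverGrid
from .indices import DiatomSample, MacroinvertebrateSample, bmi, tdi
from .metrics import METRIC_COLUMNS, PROPORTION_COLUMNS, compute_class_metrics

__all__ = [
    "ResponseConfig",
    "response",
    "generate_landscape",
    "generate_sites",
    "generate_assemblages",
    "feature_columns",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ["TDI", "BMI", "FAI"]

# Dirichlet over (urban, agriculture, forest, other): means match the
# survey's reported riparian composition (11.7, 19.3, 50.0)% and the total
# concentration 2.75 reproduces the forest marginal SD (~26 points).
_DIRICHLET_MEANS = np.array([0.117, 0.193, 0.500, 0.190])
_DIRICHLET_CONCENTRATION = 2.75

# Per-class scales for the fragmentation metrics in tabular mode: urban
# cover is the most fragmented (highest patch/edge density at a given
# proportion), forest the least.
_PD_SCALE = {"Urban": 126.0, "Agricultural": 37.0, "Forest": 19.0}
_ED_SCALE = {"Urban": 305.0, "Agricultural": 180.0, "Forest": 87.0}


@dataclass
class ResponseConfig:
    """Parameters of the true index response and of the site generator.

    Change points are in percent land cover; amplitudes and the baseline
    are in index points (0–100 scale); ``sigma`` is the SD of the additive
    Gaussian observation noise on each index.
    """

    tau_forest: float = 60.0
    tau_urban: float = 25.0
    agri_decline: tuple[float, float] = (20.0, 40.0)
    w_forest: float = 30.0
    w_urban: float = 15.0
    w_agri: float = 15.0
    baseline: float = 55.0
    sigma: float = 8.0
    n_sites: int = 770
    seed: int = 0

    def __post_init__(self) -> None:
        for name, tau in (("tau_forest", self.tau_forest), ("tau_urban", self.tau_urban)):
            if not 0 < tau < 100:
                raise ValueError(f"{name} must lie in (0, 100), got {tau}")
        lo, hi = self.agri_decline
        if not lo < hi:
            raise ValueError(f"agri_decline must be an increasing interval, got {self.agri_decline}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_sites < 10:
            raise ValueError(f"n_sites must be >= 10, got {self.n_sites}")


def response(f_pct, u_pct, a_pct, config: ResponseConfig | None = None) -> np.ndarray:
    """Noiseless biotic-index response to the land-cover proportions.

    Additive piecewise-linear effects: a forest benefit rising to +w_F at
    τ_F then flat; an urban penalty reaching −w_U at τ_U then flat; an
    agricultural penalty ramping from 0 at a_lo to −w_A at a_hi.  The sum
    plus the baseline is clipped to [0, 100].
    """
    cfg = config or ResponseConfig()
    f = np.asarray(f_pct, dtype=float)
    u = np.asarray(u_pct, dtype=float)
    a = np.asarray(a_pct, dtype=float)
    lo, hi = cfg.agri_decline
    ramp = np.clip((a - lo) / (hi - lo), 0.0, 1.0)
    val = (
        cfg.baseline
        + cfg.w_forest * np.minimum(f, cfg.tau_forest) / cfg.tau_forest
        - cfg.w_urban * np.minimum(u, cfg.tau_urban) / cfg.tau_urban
        - cfg.w_agri * ramp
    )
    return np.clip(val, 0.0, 100.0)


_GROW_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def generate_landscape(
    proportions: tuple[float, float, float],
    n_seeds_per_class: int = 3,
    shape: tuple[int, int] = (40, 40),
    cell_size: float = 10.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> LandCoverGrid:
    """Build a categorical landscape by seeded region growing.

    ``proportions`` are the (urban, agriculture, forest) percentages of the
    valid area; remaining cells become OTHER.  Class cell quotas use
    largest-remainder rounding.  Each class starts from up to
    ``n_seeds_per_class`` random seed cells and grows along 4-neighbor
    frontiers in random order until its quota is met; a class whose
    frontier dies out is reseeded.  Fully reproducible per seed.
    """
    if len(proportions) != 3:
        raise ValueError("proportions must be (urban, agriculture, forest)")
    props = np.asarray(proportions, dtype=float)
    if np.any(props < 0) or props.sum() > 100.0 + 1e-9:
        raise ValueError(f"proportions must be >= 0 and sum <= 100, got {tuple(props)}")
    nrows, ncols = shape
    if nrows < 8 or ncols < 8:
        raise ValueError(f"shape must be at least 8x8, got {shape}")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (nrows, ncols):
        raise ValueError(f"mask shape {mask.shape} != {shape}")
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError("mask has no valid cells")

    # largest-remainder quotas
    exact = props / 100.0 * n_valid
    quotas = np.floor(exact).astype(int)
    remainder = exact - quotas
    short = int(round(exact.sum())) - quotas.sum()
    for idx in np.argsort(-remainder)[:short]:
        quotas[idx] += 1
    if quotas.sum() > n_valid:
        raise ValueError(f"class quotas {quotas.tolist()} exceed valid cells ({n_valid})")

    rng = np.random.default_rng(seed)
    nodata = -9999
    values = np.full(shape, nodata, dtype=np.int64)
    values[mask] = 0  # 0 = unassigned, becomes OTHER at the end
    classes = (URBAN, AGRICULTURE, FOREST)
    remaining = {c: int(q) for c, q in zip(classes, quotas)}
    frontier: dict[int, list[tuple[int, int]]] = {c: [] for c in classes}

    def plant_seed(cat: int) -> bool:
        free = np.argwhere(values == 0)
        if free.size == 0:
            return False
        r, c = free[rng.integers(len(free))]
        assign(cat, int(r), int(c))
        return True

    def assign(cat: int, r: int, c: int) -> None:
        values[r, c] = cat
        remaining[cat] -= 1
        for dr, dc in _GROW_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and values[rr, cc] == 0:
                frontier[cat].append((rr, cc))

    for cat in classes:
        for _ in range(min(n_seeds_per_class, remaining[cat])):
            if remaining[cat] > 0:
                plant_seed(cat)

    active = [c for c in classes if remaining[c] > 0]
    while active:
        cat = active[rng.integers(len(active))]
        placed = False
        front = frontier[cat]
        while front:
            i = rng.integers(len(front))
            front[i], front[-1] = front[-1], front[i]
            r, c = front.pop()
            if values[r, c] == 0:
                assign(cat, r, c)
                placed = True
                break
        if not placed and remaining[cat] > 0:
            if not plant_seed(cat):
                raise ValueError("ran out of free cells while growing classes")
        active = [c for c in classes if remaining[c] > 0]

    values[values == 0] = OTHER
    return LandCoverGrid(values=values, cell_size=cell_size, nodata=nodata)


def _pattern_metrics_tabular(rng: np.random.Generator, props_pct: np.ndarray) -> pd.DataFrame:
    """Proportion-linked pattern metrics: PLAND tracks the proportion,
    LPI a random fraction of PLAND, PD/ED follow the unimodal
    area-fragmentation relation with class-specific scales."""
    n = props_pct.shape[0]
    out: dict[str, np.ndarray] = {}
    for k, prefix in enumerate(("Urban", "Agricultural", "Forest")):
        p = props_pct[:, k]
        pland_k = np.clip(p + rng.normal(0.0, 3.0, n), 0.0, 100.0)
        lpi_k = pland_k * rng.beta(2.0, 2.0, n)
        hump = 4.0 * (p / 100.0) * (1.0 - p / 100.0)
        pd_k = _PD_SCALE[prefix] * hump * rng.lognormal(0.0, 0.30, n)
        ed_k = _ED_SCALE[prefix] * hump * rng.lognormal(0.0, 0.25, n)
        out[f"{prefix}_LPI"] = lpi_k
        out[f"{prefix}_PLAND"] = pland_k
        out[f"{prefix}_PD"] = pd_k
        out[f"{prefix}_ED"] = ed_k
    return pd.DataFrame(out)[METRIC_COLUMNS]


def generate_sites(
    config: ResponseConfig | None = None,
    mode: str = "tabular",
    shape: tuple[int, int] = (32, 32),
    n_seeds_per_class: int = 3,
    connectivity: int = 8,
    include_boundary: bool = False,
) -> pd.DataFrame:
    """Generate the synthetic site table.

    Columns: ``site_id``, the 3 proportions, the 12 pattern metrics, the
    noiseless ``true_response`` and the observed TDI/BMI/FAI (response +
    independent Gaussian noise per index, clipped to [0, 100]).  In
    ``raster`` mode every site's metrics are measured from an actual
    generated landscape; ``tabular`` mode draws them directly.
    """
    cfg = config or ResponseConfig()
    if mode not in ("tabular", "raster"):
        raise ValueError(f"mode must be 'tabular' or 'raster', got {mode!r}")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    alphas = _DIRICHLET_CONCENTRATION * _DIRICHLET_MEANS
    comp = rng.dirichlet(alphas, size=n) * 100.0  # columns: urban, agri, forest, other

    if mode == "tabular":
        props = comp[:, :3]
        features = _pattern_metrics_tabular(rng, props)
        u, a, f = props[:, 0], props[:, 1], props[:, 2]
    else:
        records = []
        landscape_seeds = rng.integers(0, 2**31 - 1, size=n)
        for i in range(n):
            grid = generate_landscape(
                (comp[i, 0], comp[i, 1], comp[i, 2]),
                n_seeds_per_class=n_seeds_per_class,
                shape=shape,
                seed=int(landscape_seeds[i]),
            )
            records.append(compute_class_metrics(grid, connectivity, include_boundary))
        measured = pd.DataFrame(records).reset_index(drop=True)
        u = measured["urban_pct"].to_numpy()
        a = measured["agri_pct"].to_numpy()
        f = measured["forest_pct"].to_numpy()
        features = measured[METRIC_COLUMNS]

    true = response(f, u, a, cfg)
    table = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:04d}" for i in range(n)],
            "urban_pct": u,
            "agri_pct": a,
            "forest_pct": f,
        }
    )
    table = pd.concat([table, features.set_index(table.index)], axis=1)
    table["true_response"] = true
    for name in INDEX_COLUMNS:
        noise = rng.normal(0.0, cfg.sigma, size=n) if cfg.sigma > 0 else 0.0
        table[name] = np.clip(true + noise, 0.0, 100.0)
    return table


def feature_columns(mode: str = "15") -> list[str]:
    """Explanatory-variable sets: the full 15 (3 proportions + 12 pattern
    metrics) or a reduced 12 that drops the three PLANDs (near-duplicates
    of the proportions)."""
    full = PROPORTION_COLUMNS + METRIC_COLUMNS
    if mode == "15":
        return full
    if mode == "12":
        return [c for c in full if not c.endswith("_PLAND")]
    raise ValueError(f"feature mode must be '15' or '12', got {mode!r}")


def generate_assemblages(
    index_target: float, organism: str, seed: int = 0, n_taxa: int = 12
):
    """Draw an assemblage whose recomputed index lands within ±2 of a target.

    ``organism`` is "diatom" (TDI) or "macroinvertebrate" (BMI).  Taxon
    weights are random; the sensitivity/saprobity values are shifted
    iteratively until the abundance-weighted mean matches the mean implied
    by the target index (both index formulas are affine in that mean).
    """
    if not 0 <= index_target <= 100:
        raise ValueError(f"index target must lie in [0, 100], got {index_target}")
    rng = np.random.default_rng(seed)
    if organism == "diatom":
        lo, hi = 1.0, 5.0
        target_mean = (125.0 - index_target) / 25.0
    elif organism == "macroinvertebrate":
        lo, hi = 0.0, 4.0
        target_mean = 4.0 - index_target / 25.0
    else:
        raise ValueError(f"organism must be 'diatom' or 'macroinvertebrate', got {organism!r}")

    s = np.clip(rng.normal(target_mean, 0.8, n_taxa), lo, hi)
    if organism == "diatom":
        abundance = rng.uniform(1.0, 100.0, n_taxa)
        indicator = rng.integers(1, 4, n_taxa).astype(float)
        weights = abundance * indicator
    else:
        frequency = rng.integers(1, 11, n_taxa).astype(float)
        weight = rng.integers(1, 6, n_taxa).astype(float)
        weights = frequency * weight

    if target_mean <= lo:  # extreme targets force a uniform assemblage
        s = np.full(n_taxa, lo)
    elif target_mean >= hi:
        s = np.full(n_taxa, hi)
    else:
        tol_mean = 2.0 / 25.0  # ±2 index points
        for _ in range(200):
            cur = float(np.sum(s * weights) / np.sum(weights))
            if abs(cur - target_mean) <= tol_mean:
                break
            s = np.clip(s + (target_mean - cur), lo, hi)

    if organism == "diatom":
        sample = DiatomSample(abundance=abundance, sensitivity=s, indicator_value=indicator)
        achieved = tdi(sample)
    else:
        sample = MacroinvertebrateSample(saprobity=s, frequency=frequency, weight=weight)
        achieved = bmi(sample)
    if abs(achieved - index_target) > 2.0:
        raise RuntimeError(
            f"assemblage generation failed to reach target {index_target} (got {achieved:.2f})"
        )
    return sample
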