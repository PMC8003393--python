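"""Stream biotic-integrity indices: TDI, BMI and FAI.

All three indicators score a site on a 0–100 scale, 0 = very poor and
100 = very good biological condition.

* TDI (Trophic Diatom Index): ``TDI = 100 − (25·WMS − 25)`` where WMS is
  the weighted mean pollution sensitivity of the diatom assemblage,
  ``WMS = Σ A_j S_j V_j / Σ A_j V_j`` with abundance A, sensitivity
  S ∈ [1, 5] and indicator value V ∈ [1, 3].  WMS ∈ [1, 5] maps the index
  onto [0, 100] with no clipping needed.
* BMI (Benthic Macroinvertebrate Index): ``BMI = (4 − Σ S_j H_j G_j /
  Σ H_j G_j) × 25`` from unit saprobic values S ∈ [0, 4], frequencies H
  and indicator weights G.
* FAI (Fish Assessment Index): the sum of 8 scored fish-assemblage
  metrics.  The official MOE scoring breakpoints are not public; this
  module ships a synthetic default rubric (tri-level 12.5 / 6.25 / 0 per
  metric, so the index spans [0, 100]) and accepts a user rubric.

The weighted means are scale-invariant in the abundance/frequency weights,
so abundances may be supplied as percentages or raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DiatomSample",
    "MacroinvertebrateSample",
    "FishMetricsRecord",
    "MetricRule",
    "ScoringRubric",
    "DEFAULT_FAI_RUBRIC",
    "wms",
    "tdi",
    "bmi",
    "fai",
    "read_diatom_table",
    "read_macroinvertebrate_table",
    "read_fish_table",
]


def _col(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class DiatomSample:
    """Per-taxon diatom records: abundance A, pollution sensitivity S, indicator value V."""

    abundance: np.ndarray
    sensitivity: np.ndarray
    indicator_value: np.ndarray

    def __post_init__(self) -> None:
        self.abundance = _col(self.abundance, "abundance")
        self.sensitivity = _col(self.sensitivity, "sensitivity")
        self.indicator_value = _col(self.indicator_value, "indicator_value")
        n = self.abundance.size
        if self.sensitivity.size != n or self.indicator_value.size != n:
            raise ValueError("abundance, sensitivity and indicator_value must be equal length")
        if np.any(self.abundance < 0) or not np.any(self.abundance > 0):
            raise ValueError("abundances must be >= 0 with at least one positive")
        if np.any((self.sensitivity < 1) | (self.sensitivity > 5)):
            raise ValueError("pollution sensitivity must lie in [1, 5]")
        if np.any((self.indicator_value < 1) | (self.indicator_value > 3)):
            raise ValueError("indicator value must lie in [1, 3]")


@dataclass
class MacroinvertebrateSample:
    """Per-species macroinvertebrate records: saprobic value S, frequency H, weight G."""

    saprobity: np.ndarray
    frequency: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.saprobity = _col(self.saprobity, "saprobity")
        self.frequency = _col(self.frequency, "frequency")
        self.weight = _col(self.weight, "weight")
        n = self.saprobity.size
        if self.frequency.size != n or self.weight.size != n:
            raise ValueError("saprobity, frequency and weight must be equal length")
        if np.any((self.saprobity < 0) | (self.saprobity > 4)):
            raise ValueError("unit saprobic value must lie in [0, 4]")
        if np.any(self.frequency <= 0) or np.any(self.weight <= 0):
            raise ValueError("frequencies and weights must be positive")


_FISH_METRICS = ("M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8")
_COUNT_METRICS = {"M1", "M2", "M3", "M7"}
_PERCENT_METRICS = {"M4", "M5", "M6", "M8"}


@dataclass
class FishMetricsRecord:
    """Raw values of the 8 fish-assemblage metrics.

    M1 native species count; M2 riffle-benthic species count; M3 sensitive
    species count; M4 % tolerant individuals; M5 % omnivores; M6 %
    insectivores; M7 native-individual abundance; M8 % anomalies.
    """

    M1: float
    M2: float
    M3: float
    M4: float
    M5: float
    M6: float
    M7: float
    M8: float

    def __post_init__(self) -> None:
        for name in _COUNT_METRICS:
            v = getattr(self, name)
            if v < 0 or float(v) != int(v):
                raise ValueError(f"{name} must be a non-negative integer count, got {v}")
        for name in _PERCENT_METRICS:
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {m: float(getattr(self, m)) for m in _FISH_METRICS}


@dataclass(frozen=True)
class MetricRule:
    """Tri-level scoring rule for one fish metric.

    ``direction`` is "higher" (larger raw value is better) or "lower".
    A raw value at or past ``best`` scores 12.5, at or past ``mid`` scores
    6.25, otherwise 0.
    """

    direction: str
    best: float
    mid: float

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"direction must be 'higher' or 'lower', got {self.direction!r}")
        if self.direction == "higher" and not self.best > self.mid:
            raise ValueError("higher-better rule needs best > mid")
        if self.direction == "lower" and not self.best < self.mid:
            raise ValueError("lower-better rule needs best < mid")

    def score(self, raw: float) -> float:
        if self.direction == "higher":
            if raw >= self.best:
                return 12.5
            if raw >= self.mid:
                return 6.25
            return 0.0
        if raw <= self.best:
            return 12.5
        if raw <= self.mid:
            return 6.25
        return 0.0


@dataclass(frozen=True)
class ScoringRubric:
    """Per-metric scoring rules for the FAI; scores sum to at most 100."""

    rules: dict[str, MetricRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in _FISH_METRICS if m not in self.rules]
        if missing:
            raise ValueError(f"rubric missing rules for metrics: {missing}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScoringRubric":
        rules = {
            m: MetricRule(direction=r["direction"], best=float(r["best"]), mid=float(r["mid"]))
            for m, r in cfg.items()
        }
        return cls(rules=rules)


# Synthetic default rubric: the official MOE breakpoints are not published,
# so these tri-level breakpoints follow index-of-biotic-integrity practice
# (richness counts higher-better, tolerance/omnivory/anomaly percentages
# lower-better) and make FAI span the full 0-100 scale.
DEFAULT_FAI_RUBRIC = ScoringRubric(
    rules={
        "M1": MetricRule("higher", best=10, mid=5),
        "M2": MetricRule("higher", best=4, mid=2),
        "M3": MetricRule("higher", best=3, mid=1),
        "M4": MetricRule("lower", best=20, mid=45),
        "M5": MetricRule("lower", best=30, mid=50),
        "M6": MetricRule("higher", best=45, mid=20),
        "M7": MetricRule("higher", best=200, mid=75),
        "M8": MetricRule("lower", best=1, mid=5),
    }
)


def wms(sample: DiatomSample) -> float:
    """Weighted mean sensitivity of a diatom sample, in [1, 5]."""
    denom = float(np.sum(sample.abundance * sample.indicator_value))
    if denom <= 0:
        raise ValueError("empty or zero-abundance sample: sum(A*V) must be positive")
    num = float(np.sum(sample.abundance * sample.sensitivity * sample.indicator_value))
    return num / denom


def tdi(sample: DiatomSample) -> float:
    """Trophic Diatom Index: 100 − (25·WMS − 25)."""
    return 100.0 - (25.0 * wms(sample) - 25.0)


def bmi(sample: MacroinvertebrateSample) -> float:
    """Benthic Macroinvertebrate Index: (4 − weighted mean saprobity) × 25."""
    denom = float(np.sum(sample.frequency * sample.weight))
    if denom <= 0:
        raise ValueError("empty sample: sum(H*G) must be positive")
    mean_saprobity = float(np.sum(sample.saprobity * sample.frequency * sample.weight)) / denom
    return (4.0 - mean_saprobity) * 25.0


def fai(record: FishMetricsRecord, rubric: ScoringRubric = DEFAULT_FAI_RUBRIC) -> float:
    """Fish Assessment Index: sum of the 8 scored metrics, in [0, 100]."""
    return float(sum(rubric.rules[m].score(v) for m, v in record.as_dict().items()))


def read_diatom_table(path: str | Path) -> DiatomSample:
    """Read a delimited diatom table with columns taxon, A, S, V."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    return DiatomSample(
        abundance=df[cols["a"]].to_numpy(),
        sensitivity=df[cols["s"]].to_numpy(),
        indicator_value=df[cols["v"]].to_numpy(),
    )


def read_macroinvertebrate_table(path: str | Path) -> MacroinvertebrateSample:
    """Read a delimited macroinvertebrate table with columns species, S, H, G."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    return MacroinvertebrateSample(
        saprobity=df[cols["s"]].to_numpy(),
        frequency=df[cols["h"]].to_numpy(),
        weight=df[cols["g"]].to_numpy(),
    )


def read_fish_table(path: str | Path) -> list[FishMetricsRecord]:
    """Read a delimited fish table with columns M1..M8 (one row per sample)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.upper(): c for c in df.columns}
    return [
        FishMetricsRecord(**{m: row[cols[m]] for m in _FISH_METRICS})
        for _, row in df.iterrows()
    ]
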