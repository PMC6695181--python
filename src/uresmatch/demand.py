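"""Demand-side indicators: air-quality standards and GHG reduction targets.

Air-quality demand is encoded as environmental quality standards (EQS) —
authority x pollutant limit values with an averaging window (annual mean,
1-h, 8-h or maximum daily 8-h mean).  Climate-regulation demand is a city
share of national greenhouse-gas emissions, downscaled per capita, times a
national reduction target (4% unconditional / 12% conditional by 2030 for
Iran).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MOLAR_MASS",
    "MOLAR_VOLUME_L",
    "EQSStandard",
    "EQSRegistry",
    "GHGTarget",
    "CityEmissions",
    "WindowMetric",
    "load_standards",
    "to_ug_m3",
    "exceedance",
    "window_metric",
    "downscale_emissions",
    "ghg_demand",
]

#: g/mol, for ppm and mg/m3 conversions at 25 C / 1 atm
MOLAR_MASS = {"CO": 28.01, "O3": 48.00, "NO2": 46.01, "SO2": 64.07}
MOLAR_VOLUME_L = 24.45  # L/mol at 25 C, 1 atm

AUTHORITIES = ("WHO", "EU", "EPA", "IRAN")
WINDOWS = ("annual", "1h", "8h", "daily_8h_max")

#: sentinel for (authority, pollutant) pairs without a standard
NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class EQSStandard:
    authority: str
    pollutant: str
    limit: float
    units: str        # ug/m3 | mg/m3 | ppm
    window: str       # annual | 1h | 8h | daily_8h_max

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError("limit must be > 0")
        if self.units not in ("ug/m3", "mg/m3", "ppm"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.window not in WINDOWS:
            raise ValueError(f"unknown averaging window {self.window!r}")

    @property
    def limit_ug_m3(self) -> float:
        return to_ug_m3(self.limit, self.units, self.pollutant)


def to_ug_m3(value: float, units: str, pollutant: str) -> float:
    """Convert a limit to ug/m3 (ppm at 25 C, 1 atm via molar volume)."""
    if units == "ug/m3":
        return value
    if units == "mg/m3":
        return value * 1000.0
    if units == "ppm":
        if pollutant not in MOLAR_MASS:
            raise ValueError(f"no molar mass for {pollutant!r}")
        return value * MOLAR_MASS[pollutant] / MOLAR_VOLUME_L * 1000.0
    raise ValueError(f"unknown units {units!r}")


def from_ug_m3(value: float, units: str, pollutant: str) -> float:
    """Inverse of :func:`to_ug_m3`."""
    if units == "ug/m3":
        return value
    if units == "mg/m3":
        return value / 1000.0
    if units == "ppm":
        return value * MOLAR_VOLUME_L / (MOLAR_MASS[pollutant] * 1000.0)
    raise ValueError(f"unknown units {units!r}")


class EQSRegistry:
    """Authority x pollutant registry of standards.

    A pair may carry several entries (different windows, e.g. a 1-h and an
    8-h CO limit) or none at all ("no standard", a distinct outcome from a
    match).
    """

    def __init__(self, standards: list[EQSStandard]) -> None:
        self._by_pair: dict[tuple[str, str], list[EQSStandard]] = {}
        for s in standards:
            key = (s.authority, s.pollutant)
            entries = self._by_pair.setdefault(key, [])
            if any(e.window == s.window for e in entries):
                raise ValueError(
                    f"duplicate standard for {key} window {s.window!r}")
            entries.append(s)

    def get(self, authority: str, pollutant: str) -> list[EQSStandard]:
        """All entries for the pair; empty list means no standard."""
        return list(self._by_pair.get((authority, pollutant), []))

    def __iter__(self) -> Iterator[EQSStandard]:
        for entries in self._by_pair.values():
            yield from entries

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_pair.values())

    def override(self, standard: EQSStandard) -> None:
        """Replace (or add) the entry for (authority, pollutant, window)."""
        key = (standard.authority, standard.pollutant)
        entries = [e for e in self._by_pair.get(key, [])
                   if e.window != standard.window]
        entries.append(standard)
        self._by_pair[key] = entries

    def to_records(self) -> list[dict]:
        return [
            {"authority": s.authority, "pollutant": s.pollutant,
             "limit": s.limit, "units": s.units, "window": s.window}
            for s in self
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "EQSRegistry":
        return cls([EQSStandard(**r) for r in records])


def load_standards(config: str | Path | None = None) -> EQSRegistry:
    """Load the EQS registry.

    With no argument, returns the bundled default registry (WHO, EU, EPA and
    Iranian limit values for PM2.5, O3, NO2, SO2 and CO as adopted in the
    Tabriz assessment, including deliberate absences such as WHO-CO).  A user
    YAML/JSON file with the same record schema overrides or extends entries.
    """
    default_path = Path(__file__).parent / "data" / "standards.yaml"
    with open(default_path) as fh:
        raw = yaml.safe_load(fh)
    registry = EQSRegistry.from_records(raw["standards"])
    if config is not None:
        with open(config) as fh:
            user = yaml.safe_load(fh)
        if not isinstance(user, dict) or "standards" not in user:
            raise ValueError("standards config must contain a 'standards' list")
        for rec in user["standards"]:
            try:
                registry.override(EQSStandard(**rec))
            except TypeError as exc:
                raise ValueError(f"malformed standards record {rec!r}: {exc}") from None
    return registry


def exceedance(metric_ug_m3: float, standard: EQSStandard) -> float:
    """Positive part of metric minus limit, in ug/m3 (0 when compliant)."""
    return max(0.0, metric_ug_m3 - standard.limit_ug_m3)


@dataclass(frozen=True)
class WindowMetric:
    """An averaging-window statistic, flagged when the annual mean stood in
    as a proxy for a short-term window."""

    value: float   # ug/m3
    window: str
    proxy: bool = False


def window_metric(series, window: str, pollutant: str, *,
                  annual_proxy: float | None = None) -> WindowMetric:
    """Averaging-window statistic of an hourly series for one pollutant.

    annual -> annual mean; 1h -> maximum hourly value; 8h / daily_8h_max ->
    maximum complete 8-h rolling mean.  When ``series`` is None (no hourly
    data), ``annual_proxy`` substitutes for every window and the result is
    flagged ``proxy`` unless the window is annual.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown averaging window {window!r}")
    if series is None:
        if annual_proxy is None:
            raise ValueError("no hourly data and no annual proxy value")
        return WindowMetric(float(annual_proxy), window, proxy=(window != "annual"))
    values = series.data[pollutant].astype(float)
    if window == "annual":
        return WindowMetric(float(values.mean()), window)
    if window == "1h":
        return WindowMetric(float(values.max()), window)
    rolling = values.rolling(8, min_periods=8).mean()
    return WindowMetric(float(rolling.max()), window)


@dataclass(frozen=True)
class GHGTarget:
    """National GHG reduction pledge applied at city scale."""

    name: str                  # unconditional | conditional
    reduction_fraction: float  # e.g. 0.04 or 0.12
    horizon: int = 2030

    def __post_init__(self) -> None:
        if not 0.0 < self.reduction_fraction < 1.0:
            raise ValueError("reduction fraction must lie in (0, 1)")


#: Iranian national mitigation pledge: 4% unconditional, 12% conditional by 2030
DEFAULT_TARGETS = (
    GHGTarget("unconditional", 0.04, 2030),
    GHGTarget("conditional", 0.12, 2030),
)


@dataclass(frozen=True)
class CityEmissions:
    """City GHG emissions downscaled per capita from a national total."""

    national_total: float  # t CO2-eq/yr
    national_pop: float
    city_pop: float
    city_area_ha: float

    def __post_init__(self) -> None:
        for name in ("national_total", "national_pop", "city_pop", "city_area_ha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def city_total(self) -> float:
        return self.national_total * self.city_pop / self.national_pop

    @property
    def per_ha(self) -> float:
        return self.city_total / self.city_area_ha


def downscale_emissions(national_total: float, national_pop: float,
                        city_pop: float, city_area_ha: float) -> CityEmissions:
    """Per-capita linear downscaling of national emissions to the city."""
    return CityEmissions(national_total, national_pop, city_pop, city_area_ha)


def ghg_demand(city: CityEmissions, target: GHGTarget) -> float:
    """Required city-scale reduction (t CO2-eq/yr) under the target."""
    return city.city_total * target.reduction_fraction
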