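"""Seeded synthetic city generators with known ground truth.

The generators emulate the two data sources of a city-scale assessment: a
stratified random-plot tree survey (Poisson plot counts at a known stratum
density, log-normal DBH) and one calendar year of hourly pollutant
concentrations and weather (seasonal + diurnal sinusoids with AR(1) noise,
clipped at zero).  Every quantity a downstream estimator should recover is
returned alongside the data, so estimator bias and end-to-end pipelines can
be tested without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deposition import POLLUTANTS, HourlySeries
from .inventory import Plot, Stratum, TreeInventory, TreeRecord

__all__ = [
    "StratumSpec",
    "PollutantSpec",
    "CityScenario",
    "generate_inventory",
    "generate_hourly_year",
]


@dataclass(frozen=True)
class StratumSpec:
    """Ground truth for one land-use stratum."""

    name: str
    area_ha: float
    density_per_ha: float            # true tree density
    n_plots: int = 10
    plot_area_m2: float = 1000.0
    species_mix: dict[str, float] = field(
        default_factory=lambda: {"Robinia pseudoacacia": 0.5,
                                 "Pinus nigra": 0.5})

    def __post_init__(self) -> None:
        if self.density_per_ha < 0:
            raise ValueError("density must be >= 0")
        total = sum(self.species_mix.values())
        if self.species_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"species mix must sum to 1, got {total}")


@dataclass(frozen=True)
class PollutantSpec:
    """Ground truth for one pollutant's hourly year."""

    annual_mean: float               # ug/m3
    seasonal_amplitude: float = 0.0  # ug/m3, annual sinusoid
    diurnal_amplitude: float = 0.0   # ug/m3, 24-h sinusoid
    noise_sd: float = 0.0            # ug/m3, AR(1) innovations
    ar1: float = 0.7


#: species assumed coniferous by the generator
_CONIFERS = {"Pinus nigra", "Pinus eldarica", "Cupressus arizonica"}


@dataclass(frozen=True)
class CityScenario:
    """Complete specification of a synthetic city and monitoring year."""

    seed: int
    strata: tuple[StratumSpec, ...]
    pollution: dict[str, PollutantSpec] = field(
        default_factory=lambda: {"NO2": PollutantSpec(60.0, 15.0, 10.0, 5.0)})
    year: int = 2015
    dbh_log_mean: float = 2.8        # log cm: median ~16 cm
    dbh_log_sd: float = 0.5
    mean_wind_ms: float = 3.0
    wind_amplitude_ms: float = 2.0
    rain_probability: float = 0.05
    rain_mm_per_h: float = 1.0
    true_vd: dict[str, float] | None = None
    tree_cover_pct: float = 9.4

    @property
    def true_totals(self) -> dict[str, float]:
        """Expected tree count per stratum (area x density)."""
        return {s.name: s.area_ha * s.density_per_ha for s in self.strata}


def _draw_tree(rng: np.random.Generator, scenario: CityScenario,
               species: str, tree_id: str, plot_id: str) -> TreeRecord:
    dbh = float(rng.lognormal(scenario.dbh_log_mean, scenario.dbh_log_sd))
    # height loosely allometric in dbh with scatter, floored at 2 m
    height = max(2.0, 1.3 + 0.45 * dbh * float(rng.uniform(0.8, 1.2)))
    group = "conifer" if species in _CONIFERS else "hardwood"
    return TreeRecord(
        tree_id=tree_id,
        species=species,
        dbh=dbh,
        height=height,
        condition=float(rng.uniform(0.6, 1.0)),
        group=group,
        phenology="evergreen" if group == "conifer" else "deciduous",
        open_grown=bool(rng.random() < 0.7),
        plot_id=plot_id,
    )


def generate_inventory(
    scenario: CityScenario,
    seed: int | None = None,
) -> tuple[TreeInventory, dict[str, float]]:
    """Simulate the stratified plot survey.

    Returns the inventory and the true per-stratum population totals.  Plot
    tree counts are Poisson(density x plot area); the same seed always
    produces the identical inventory.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    strata: dict[str, Stratum] = {}
    plots: dict[str, Plot] = {}
    trees: list[TreeRecord] = []
    for s in scenario.strata:
        strata[s.name] = Stratum(s.name, s.area_ha)
        for j in range(s.n_plots):
            plot_id = f"{s.name}-p{j:03d}"
            plots[plot_id] = Plot(plot_id, s.name, s.plot_area_m2)
            n = int(rng.poisson(s.density_per_ha * s.plot_area_m2 / 1e4))
            if not s.species_mix:
                continue
            names = list(s.species_mix)
            probs = np.array([s.species_mix[k] for k in names])
            draws = rng.choice(len(names), size=n, p=probs)
            for k, idx in enumerate(draws):
                trees.append(_draw_tree(
                    rng, scenario, names[idx], f"{plot_id}-t{k:04d}", plot_id))
    return TreeInventory(trees=trees, plots=plots, strata=strata), scenario.true_totals


def generate_hourly_year(
    scenario: CityScenario,
    seed: int | None = None,
) -> HourlySeries:
    """Simulate one calendar year of hourly concentrations and weather.

    Concentration = annual mean + seasonal sinusoid + diurnal sinusoid +
    AR(1) noise, clipped at 0.  Wind is a diurnal sinusoid with noise (so the
    PM2.5 resuspension regime switches on and off); rain falls in independent
    hourly events.
    """
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 1)
    index = pd.date_range(f"{scenario.year}-01-01", periods=0, freq="h")
    start = pd.Timestamp(f"{scenario.year}-01-01")
    end = pd.Timestamp(f"{scenario.year + 1}-01-01")
    index = pd.date_range(start, end, freq="h", inclusive="left")
    n = len(index)
    hours = np.arange(n)

    data: dict[str, np.ndarray] = {}
    for name, spec in scenario.pollution.items():
        seasonal = spec.seasonal_amplitude * np.sin(2 * np.pi * hours / (365.25 * 24))
        diurnal = spec.diurnal_amplitude * np.sin(2 * np.pi * hours / 24)
        noise = np.zeros(n)
        if spec.noise_sd > 0:
            innov_sd = spec.noise_sd * np.sqrt(1 - spec.ar1 ** 2)
            eps = rng.normal(0.0, innov_sd, size=n)
            noise[0] = rng.normal(0.0, spec.noise_sd)
            for t in range(1, n):
                noise[t] = spec.ar1 * noise[t - 1] + eps[t]
        data[name] = np.clip(spec.annual_mean + seasonal + diurnal + noise, 0.0, None)

    wind = np.clip(
        scenario.mean_wind_ms
        + scenario.wind_amplitude_ms * np.sin(2 * np.pi * hours / 24)
        + rng.normal(0.0, 0.5, size=n),
        0.0, None)
    rain = np.where(rng.random(n) < scenario.rain_probability,
                    scenario.rain_mm_per_h / 1000.0, 0.0)

    df = pd.DataFrame(data, index=index)
    df["wind_speed_ms"] = wind
    df["precip_m"] = rain
    return HourlySeries(df)
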