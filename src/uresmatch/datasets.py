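"""Bundled case-study data for Tabriz, Iran (2015 assessment year).

These small tables carry the published city-scale summaries — the
species-level structure/service table, the annual air-quality summary and
the emissions profile — and let the whole demand/mismatch chain run in
annual-proxy mode without any hourly download.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .demand import CityEmissions
from .deposition import AirQualityReport

__all__ = [
    "TABRIZ_CITY_AREA_HA",
    "TABRIZ_TREE_COVER_PCT",
    "load_tabriz_species_services",
    "load_tabriz_air_quality",
    "load_tabriz_emissions",
]

_DATA = Path(__file__).parent / "data" / "tabriz"

TABRIZ_CITY_AREA_HA = 24_480.0   # 244.8 km2
TABRIZ_TREE_COVER_PCT = 9.4


def load_tabriz_species_services() -> pd.DataFrame:
    """Species-level counts and annual services (tonnes), one row per
    species plus an aggregate remainder row for the unlisted species."""
    return pd.read_csv(_DATA / "species_services.csv")


def tabriz_top_species_summary() -> pd.DataFrame:
    """Structure/service summary with a ``Top`` row summing the individually
    listed species (the published top-species view) and a grand ``Total``."""
    from .inventory import species_summary

    df = load_tabriz_species_services()
    listed = [s for s in df["species"] if not s.startswith("Other species")]
    table = species_summary(df)
    top = table.loc[listed].sum()
    table.loc["Top"] = top
    return table


def load_tabriz_air_quality() -> tuple[AirQualityReport, dict]:
    """Annual air-quality summary as an :class:`AirQualityReport` plus the
    raw record (including the reported improvement amounts)."""
    with open(_DATA / "air_quality_2015.json") as fh:
        raw = json.load(fh)
    report = AirQualityReport.from_annual_values(
        mean_with=raw["mean_with"],
        mean_without=raw["mean_without"],
        avg_pct=raw["avg_pct_improvement"],
    )
    return report, raw


def load_tabriz_emissions() -> tuple[CityEmissions, float]:
    """Emissions profile and the urban forest's annual carbon sequestration
    (t C/yr) used on the supply side of the climate-regulation assessment."""
    with open(_DATA / "emissions.json") as fh:
        raw = json.load(fh)
    city = CityEmissions(
        national_total=raw["national_total_tco2eq"],
        national_pop=raw["national_pop"],
        city_pop=raw["city_pop"],
        city_area_ha=raw["city_area_ha"],
    )
    return city, float(raw["sequestration_t_c_yr"])
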