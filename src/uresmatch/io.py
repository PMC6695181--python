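"""Run configuration and report writing for the assessment pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .carbon import load_traits
from .demand import CityEmissions, load_standards
from .deposition import DEFAULT_VD, DepositionParams, HourlySeries
from .inventory import read_inventory
from .model import URESAssessment, URESAssessmentResults

__all__ = ["RunConfig", "load_config", "build_model", "write_reports"]


@dataclass
class RunConfig:
    """Single-file configuration of a full assessment run."""

    city_area_ha: float
    tree_cover_pct: float = 9.4
    trees_csv: str | None = None
    plots_csv: str | None = None
    strata_csv: str | None = None
    hourly_csv: str | None = None
    air_report_json: str | None = None       # annual-proxy inputs
    standards_file: str | None = None
    traits_file: str | None = None
    emissions: dict | None = None            # national_total_tco2eq, pops, area
    sequestration_co2eq_t_yr: float | None = None
    vd: dict = field(default_factory=lambda: dict(DEFAULT_VD))
    blh: float = 1000.0
    pm_resusp_rate: float = 0.0025
    pm_wind_threshold: float = 4.0
    pm_rain_threshold: float = 1e-5
    seed: int = 0

    def deposition_params(self) -> DepositionParams:
        return DepositionParams(
            vd=dict(self.vd), blh=self.blh,
            pm_resusp_rate=self.pm_resusp_rate,
            pm_wind_threshold=self.pm_wind_threshold,
            pm_rain_threshold=self.pm_rain_threshold,
            tree_cover_pct=self.tree_cover_pct)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"malformed run config {path}: {exc}") from None


def build_model(config: RunConfig) -> URESAssessment:
    """Assemble the assessment model from a run configuration."""
    inventory = None
    if config.trees_csv:
        inventory = read_inventory(
            config.trees_csv, config.plots_csv, config.strata_csv)

    hourly = None
    air_report = None
    if config.hourly_csv:
        hourly = HourlySeries.from_csv(config.hourly_csv)
    elif config.air_report_json:
        from .deposition import AirQualityReport
        with open(config.air_report_json) as fh:
            raw = json.load(fh)
        air_report = AirQualityReport.from_annual_values(
            mean_with=raw["mean_with"], mean_without=raw["mean_without"],
            avg_pct=raw.get("avg_pct_improvement"))
    else:
        raise FileNotFoundError(
            "deposition stage: no hourly_csv and no air_report_json configured")

    emissions = None
    if config.emissions:
        emissions = CityEmissions(
            national_total=config.emissions["national_total_tco2eq"],
            national_pop=config.emissions["national_pop"],
            city_pop=config.emissions["city_pop"],
            city_area_ha=config.emissions.get("city_area_ha", config.city_area_ha))

    return URESAssessment(
        city_area_ha=config.city_area_ha,
        inventory=inventory,
        hourly=hourly,
        air_report=air_report,
        registry=load_standards(config.standards_file),
        emissions=emissions,
        sequestration_co2eq_t_yr=config.sequestration_co2eq_t_yr,
        deposition_params=config.deposition_params(),
        traits=load_traits(config.traits_file),
    )


def _round(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round(v, ndigits) for v in obj]
    return obj


def write_reports(results: URESAssessmentResults, out_dir: str | Path) -> dict[str, Path]:
    """Write CSV/JSON/Markdown reports; returns the paths written.

    JSON output is deterministic (sorted keys, fixed float rounding) so that
    re-running an identical configuration produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["air_quality_csv"] = out / "air_quality.csv"
    results.air_report.frame.round(6).to_csv(paths["air_quality_csv"],
                                             index_label="pollutant")

    matrix_records = results.matrix.to_records()
    paths["matrix_csv"] = out / "mismatch_matrix.csv"
    import pandas as pd
    pd.DataFrame(matrix_records).to_csv(paths["matrix_csv"], index=False)
    paths["matrix_md"] = out / "mismatch_matrix.md"
    paths["matrix_md"].write_text(results.matrix.to_markdown() + "\n")

    summary = {
        "city_area_ha": results.model.city_area_ha,
        "population": None,
        "carbon": _round(results.carbon),
        "sequestration_co2eq_t_yr": _round(results.sequestration_co2eq_t_yr),
        "ghg_demands_t_yr": _round(dict(results.ghg_demands)),
        "air_quality": _round(
            results.air_report.frame.to_dict(orient="index")),
        "mismatch_matrix": _round(matrix_records),
        "n_mismatch": results.n_mismatch,
    }
    if results.population is not None:
        summary["population"] = {
            "city_total": _round(results.population.city_total),
            "city_se": _round(results.population.city_se),
            "relative_se": _round(results.population.relative_se),
            "per_stratum": {k: [_round(v[0]), _round(v[1])]
                            for k, v in results.population.per_stratum.items()},
            "density_per_ha": _round(results.tree_density_per_ha),
        }
    paths["summary_json"] = out / "assessment.json"
    with open(paths["summary_json"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
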