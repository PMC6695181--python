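"""Top-level model/results API tying the four assessment stages together.

:class:`URESAssessment` is built from the data a city assessment needs
(tree inventory, hourly pollution year or an annual summary, standards
registry, emissions profile); :meth:`URESAssessment.fit` runs supply
estimation, demand computation and mismatch classification and returns a
:class:`URESAssessmentResults` carrying the estimates, their standard
errors and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import carbon as _carbon
from .carbon import CarbonConstants, TraitsDB, load_traits
from .demand import (CityEmissions, DEFAULT_TARGETS, EQSRegistry, GHGTarget,
                     ghg_demand, load_standards)
from .deposition import (AirQualityReport, DepositionParams, HourlySeries,
                         annual_air_quality_report)
from .inventory import (PopulationEstimate, TreeInventory, estimate_population,
                        tree_density)
from .mismatch import MismatchMatrix, assessment_matrix

__all__ = ["URESAssessment", "URESAssessmentResults"]


class URESAssessment:
    """Supply-demand assessment model for urban regulating services.

    Parameters
    ----------
    city_area_ha : total municipal area, hectares.
    inventory : stratified plot survey (drives the carbon supply side);
        optional when ``sequestration_co2eq_t_yr`` is given directly.
    hourly : one calendar year of hourly concentrations/weather; optional
        when ``air_report`` (an annual summary) is given, in which case
        short-window standards are evaluated in annual-proxy mode.
    registry : standards registry; defaults to the bundled one.
    emissions : city emissions profile (per-capita downscaled).
    targets : GHG reduction targets (default: 4% / 12% by 2030).
    deposition_params, traits, constants : stage configuration.
    """

    def __init__(
        self,
        city_area_ha: float,
        *,
        inventory: TreeInventory | None = None,
        hourly: HourlySeries | None = None,
        air_report: AirQualityReport | None = None,
        registry: EQSRegistry | None = None,
        emissions: CityEmissions | None = None,
        targets: tuple[GHGTarget, ...] = DEFAULT_TARGETS,
        sequestration_co2eq_t_yr: float | None = None,
        deposition_params: DepositionParams | None = None,
        traits: TraitsDB | None = None,
        constants: CarbonConstants = CarbonConstants(),
    ) -> None:
        if city_area_ha <= 0:
            raise ValueError("city area must be > 0 ha")
        if hourly is None and air_report is None:
            raise ValueError("need hourly data or an annual air-quality report")
        if inventory is None and sequestration_co2eq_t_yr is None:
            raise ValueError(
                "need a tree inventory or a sequestration total for the "
                "climate-regulation supply side")
        self.city_area_ha = city_area_ha
        self.inventory = inventory
        self.hourly = hourly
        self.air_report = air_report
        self.registry = registry if registry is not None else load_standards()
        self.emissions = emissions
        self.targets = targets
        self.sequestration_co2eq_t_yr = sequestration_co2eq_t_yr
        self.deposition_params = deposition_params or DepositionParams()
        self.traits = traits if traits is not None else load_traits()
        self.constants = constants

    def fit(self) -> "URESAssessmentResults":
        """Run the four assessment stages and collect the results."""
        population = None
        carbon_totals = None
        seq_co2eq = self.sequestration_co2eq_t_yr

        if self.inventory is not None and len(self.inventory) >= 0 and self.inventory.plots:
            population = estimate_population(self.inventory)
            carbon_totals = _carbon.city_carbon(
                self.inventory, population, self.traits, self.constants,
                city_area_ha=self.city_area_ha)
            if seq_co2eq is None:
                seq_co2eq = carbon_totals["co2eq_t_yr"]

        if self.hourly is not None:
            report = annual_air_quality_report(
                self.hourly, self.deposition_params, self.city_area_ha)
        else:
            report = self.air_report

        ghg_demands: dict[str, float] = {}
        ghg_classes = {}
        if self.emissions is not None:
            ghg_demands = {
                t.name: ghg_demand(self.emissions, t) for t in self.targets}

        matrix = assessment_matrix(
            report, self.registry, seq_co2eq if seq_co2eq is not None else 0.0,
            ghg_demands, hourly_series=self.hourly)

        return URESAssessmentResults(
            model=self,
            population=population,
            carbon=carbon_totals,
            air_report=report,
            sequestration_co2eq_t_yr=seq_co2eq,
            ghg_demands=ghg_demands,
            matrix=matrix,
        )


@dataclass
class URESAssessmentResults:
    """Fitted assessment: supply estimates, demand indicators, mismatch grid."""

    model: URESAssessment
    population: PopulationEstimate | None
    carbon: dict[str, float] | None
    air_report: AirQualityReport
    sequestration_co2eq_t_yr: float | None
    ghg_demands: Mapping[str, float]
    matrix: MismatchMatrix

    @property
    def tree_density_per_ha(self) -> float | None:
        if self.population is None:
            return None
        return tree_density(self.population.city_total, self.model.city_area_ha)

    @property
    def n_mismatch(self) -> int:
        return self.matrix.n_mismatch

    def summary(self) -> str:
        """Human-readable assessment summary (2-dp presentation rounding)."""
        lines = ["Urban regulating ecosystem services: supply-demand assessment",
                 "=" * 62]
        if self.population is not None:
            lines += [
                f"Estimated tree population: {self.population.city_total:,.0f}"
                f" (SE {self.population.relative_se * 100:.1f}%)",
                f"Tree density: {self.tree_density_per_ha:.0f} trees/ha",
            ]
        if self.carbon is not None:
            lines += [
                f"Carbon storage: {self.carbon['storage_t']:,.2f} t C",
                f"Net sequestration: {self.carbon['sequestration_t_yr']:,.2f} t C/yr"
                f" ({self.carbon['co2eq_t_yr']:,.2f} t CO2-eq/yr)",
            ]
        lines += ["", "Air quality (annual means, ug/m3):",
                  self.air_report.frame.round(4).to_string()]
        if self.ghg_demands:
            lines.append("")
            for name, demand in self.ghg_demands.items():
                cell = self.matrix.ghg[name]
                comp = (f", contribution {cell.compensation_pct:.2f}%"
                        if cell.compensation_pct is not None else "")
                lines.append(
                    f"GHG target {name}: demand {demand:,.2f} t CO2-eq/yr"
                    f" -> {cell.value}{comp}")
        lines += ["", "Match/mismatch matrix (M match, Mo modest, S significant):",
                  self.matrix.to_frame().to_string(),
                  f"Air-quality mismatches: {self.n_mismatch}"]
        return "\n".join(lines)
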