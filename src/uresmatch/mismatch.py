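"""Match/mismatch classification of ecosystem-service supply against demand.

Air quality: a pollutant x authority pair matches when the with-purification
metric does not exceed the limit value.  Otherwise, compensation =
improvement_amount / exceedance x 100; compensation of at most 20%
(including negative values, PM2.5 resuspension) is a significant mismatch,
above 20% a modest mismatch.  A pair with no standard is "not assessed".

Climate regulation: contribution = sequestration (CO2-eq) / required
reduction x 100; below 20% significant, 20-100% modest, above 100% the
supply fulfils the demand (match).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .demand import EQSRegistry, EQSStandard, GHGTarget, WindowMetric, exceedance
from .deposition import AirQualityReport, POLLUTANTS

__all__ = [
    "MATCH", "MODEST", "SIGNIFICANT", "NOT_ASSESSED",
    "MatchClass",
    "MismatchMatrix",
    "classify_air",
    "classify_ghg",
    "assessment_matrix",
]

MATCH = "match"
MODEST = "modest_mismatch"
SIGNIFICANT = "significant_mismatch"
NOT_ASSESSED = "not_assessed"

#: ordering used when one cell aggregates several averaging windows
_SEVERITY = {NOT_ASSESSED: -1, MATCH: 0, MODEST: 1, SIGNIFICANT: 2}

_SYMBOL = {MATCH: "M", MODEST: "Mo", SIGNIFICANT: "S", NOT_ASSESSED: "-"}

COMPENSATION_THRESHOLD_PCT = 20.0


@dataclass(frozen=True)
class MatchClass:
    """Classification of one supply-demand comparison.

    ``compensation_pct`` is present iff a positive exceedance existed (it may
    be negative under net resuspension); ``proxy`` marks short-term windows
    evaluated against an annual mean.
    """

    value: str
    compensation_pct: float | None = None
    proxy: bool = False
    window: str | None = None

    def __post_init__(self) -> None:
        if self.value not in _SEVERITY:
            raise ValueError(f"unknown class {self.value!r}")
        if self.value in (MODEST, SIGNIFICANT) and self.compensation_pct is None:
            raise ValueError("mismatch classes require a compensation value")
        if self.value in (MATCH, NOT_ASSESSED) and self.compensation_pct is not None:
            raise ValueError(f"{self.value} carries no compensation")

    @property
    def symbol(self) -> str:
        return _SYMBOL[self.value]


def classify_air(metric: WindowMetric | float, improvement_amount: float,
                 standard: EQSStandard | None) -> MatchClass:
    """Classify one pollutant against one standard entry.

    ``metric`` is the with-purification statistic for the standard's
    averaging window in ug/m3 (or a :class:`~uresmatch.demand.WindowMetric`
    carrying its proxy flag); ``improvement_amount`` is the canopy's annual
    improvement in ug/m3.
    """
    if standard is None:
        return MatchClass(NOT_ASSESSED)
    if isinstance(metric, WindowMetric):
        value, proxy = metric.value, metric.proxy
    else:
        value, proxy = float(metric), False
    exc = exceedance(value, standard)
    if exc == 0.0:
        return MatchClass(MATCH, proxy=proxy, window=standard.window)
    comp = improvement_amount / exc * 100.0
    cls = SIGNIFICANT if comp <= COMPENSATION_THRESHOLD_PCT else MODEST
    return MatchClass(cls, compensation_pct=comp, proxy=proxy,
                      window=standard.window)


def classify_ghg(sequestration_co2eq_t_yr: float, demand_t_yr: float) -> MatchClass:
    """Classify the urban forest's contribution to a GHG reduction target."""
    if demand_t_yr <= 0:
        raise ValueError("GHG demand must be > 0")
    contribution = sequestration_co2eq_t_yr / demand_t_yr * 100.0
    if contribution > 100.0:
        return MatchClass(MATCH)
    cls = SIGNIFICANT if contribution < COMPENSATION_THRESHOLD_PCT else MODEST
    return MatchClass(cls, compensation_pct=contribution)


@dataclass
class MismatchMatrix:
    """Authority x pollutant grid of classes plus the GHG target row."""

    air: dict[str, dict[str, MatchClass]]   # authority -> pollutant -> class
    ghg: dict[str, MatchClass]              # target name -> class

    @property
    def n_mismatch(self) -> int:
        """Number of air cells classified as modest or significant."""
        return sum(
            1
            for row in self.air.values()
            for cell in row.values()
            if cell.value in (MODEST, SIGNIFICANT)
        )

    def to_frame(self) -> pd.DataFrame:
        """Symbol grid (M / Mo / S / -), authorities as rows."""
        return pd.DataFrame(
            {auth: {p: cell.symbol for p, cell in row.items()}
             for auth, row in self.air.items()}
        ).T

    def to_records(self) -> list[dict]:
        recs = []
        for auth, row in self.air.items():
            for pollutant, cell in row.items():
                recs.append({
                    "service": "air_purification", "authority": auth,
                    "pollutant": pollutant, "class": cell.value,
                    "compensation_pct": cell.compensation_pct,
                    "proxy": cell.proxy, "window": cell.window,
                })
        for target, cell in self.ghg.items():
            recs.append({
                "service": "climate_regulation", "authority": "GHG target",
                "pollutant": target, "class": cell.value,
                "compensation_pct": cell.compensation_pct,
                "proxy": False, "window": None,
            })
        return recs

    def to_markdown(self) -> str:
        lines = ["| EQS | " + " | ".join(POLLUTANTS) + " |",
                 "|" + "---|" * (len(POLLUTANTS) + 1)]
        for auth, row in self.air.items():
            cells = [row[p].symbol if p in row else "-" for p in POLLUTANTS]
            lines.append(f"| {auth} | " + " | ".join(cells) + " |")
        ghg = " | ".join(f"{t}: {c.symbol}" for t, c in self.ghg.items())
        lines.append(f"| GHG reduction targets | {ghg} |")
        return "\n".join(lines)


def assessment_matrix(
    report: AirQualityReport,
    registry: EQSRegistry,
    sequestration_co2eq_t_yr: float,
    ghg_demands: Mapping[str, float],
    *,
    hourly_series=None,
    authorities: tuple[str, ...] = ("WHO", "EU", "EPA", "IRAN"),
) -> MismatchMatrix:
    """Build the full assessment matrix.

    For every authority x pollutant pair each registry entry is evaluated at
    its averaging window — against hourly rolling metrics when
    ``hourly_series`` is given, otherwise against the report's annual mean
    flagged as a proxy — and the severest class becomes the cell.  Pairs with
    no standard, or pollutants absent from the report, are "not assessed".
    """
    from .demand import window_metric  # local import avoids cycle at module load

    air: dict[str, dict[str, MatchClass]] = {}
    for auth in authorities:
        row: dict[str, MatchClass] = {}
        for pollutant in POLLUTANTS:
            entries = registry.get(auth, pollutant)
            if not entries or pollutant not in report.frame.index:
                row[pollutant] = MatchClass(NOT_ASSESSED)
                continue
            annual_mean = float(report.pollutant(pollutant)["mean_with"])
            improvement = float(report.pollutant(pollutant)["improvement_amount"])
            cells = []
            for std in entries:
                metric = window_metric(
                    hourly_series, std.window, pollutant,
                    annual_proxy=annual_mean)
                cells.append(classify_air(metric, improvement, std))
            row[pollutant] = max(cells, key=lambda c: _SEVERITY[c.value])
        air[auth] = row

    ghg = {
        name: classify_ghg(sequestration_co2eq_t_yr, demand)
        for name, demand in ghg_demands.items()
    }
    return MismatchMatrix(air=air, ghg=ghg)
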