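"""Hourly dry-deposition modelling of air-quality improvement by tree cover.

For each hour the pollutant flux to the canopy is F = vd * C (deposition
velocity times concentration).  The hourly air-quality improvement per unit
tree cover is

    I_unit = F / (F + M_total) * 100,

where M_total is the pollutant mass in the boundary-layer column per unit
ground area and hour; for the actual urban tree cover Tc (%),

    I_total = (F * Tc/100) / (F * Tc/100 + M_total) * 100,

and the concentration change attributable to the canopy is

    dC = C / (1 - I_total/100) - C,

so that C + dC is the level expected with no air purification.

PM2.5 is special: deposited particles are not taken up by the leaf and can be
resuspended by strong wind in the absence of rain, making the net flux — and
hence the annual improvement — negative in arid, windy years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "POLLUTANTS",
    "HourlySeries",
    "DepositionParams",
    "AirQualityReport",
    "CoverageError",
    "pollutant_flux",
    "unit_improvement",
    "total_improvement",
    "concentration_change",
    "annual_air_quality_report",
]

POLLUTANTS = ("CO", "NO2", "O3", "PM2.5", "SO2")

UG_PER_G = 1e6
G_PER_T = 1e6
M2_PER_HA = 1e4

#: default dry-deposition velocities, m/h (gases near i-Tree annual medians)
DEFAULT_VD = {"CO": 0.03, "NO2": 12.6, "O3": 14.4, "PM2.5": 0.9, "SO2": 17.3}


class CoverageError(ValueError):
    """Too many missing hours for a trustworthy annual aggregate."""


@dataclass
class HourlySeries:
    """One calendar year of hourly concentrations and weather.

    ``data`` is indexed by hourly timestamps (8760 or 8784 rows, strictly
    increasing, no duplicates) with one column per pollutant (ug/m3; NaN =
    missing) plus ``wind_speed_ms`` and ``precip_m``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.data.index)
        if len(idx) not in (8760, 8784):
            raise ValueError(
                f"expected one calendar year of hourly rows (8760 or 8784), "
                f"got {len(idx)}")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("timestamps must be strictly increasing and unique")
        for col in ("wind_speed_ms", "precip_m"):
            if col not in self.data.columns:
                raise ValueError(f"missing weather column {col!r}")
        for p in self.pollutants:
            if (self.data[p].dropna() < 0).any():
                raise ValueError(f"negative concentrations in {p}")
        self.data = self.data.copy()
        self.data.index = idx.rename(None)

    @property
    def pollutants(self) -> list[str]:
        return [c for c in self.data.columns if c in POLLUTANTS]

    @classmethod
    def from_csv(cls, path) -> "HourlySeries":
        df = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="timestamp")


@dataclass(frozen=True)
class DepositionParams:
    """Deposition model configuration.

    vd in m/h per pollutant; ``blh`` is the boundary-layer (mixing) height in
    m used to convert a concentration into column mass; ``pm_resusp_rate`` is
    the fraction of the PM2.5 column resuspended per hour when wind exceeds
    ``pm_wind_threshold`` (m/s) and precipitation stays below
    ``pm_rain_threshold`` (m/h); ``tree_cover_pct`` is total urban tree cover.
    """

    vd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VD))
    blh: float = 1000.0
    pm_resusp_rate: float = 0.0025
    pm_wind_threshold: float = 4.0
    pm_rain_threshold: float = 1e-5
    tree_cover_pct: float = 9.4

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.vd.values()):
            raise ValueError("deposition velocities must be >= 0")
        if self.blh <= 0:
            raise ValueError("boundary-layer height must be > 0")
        if not 0.0 <= self.tree_cover_pct <= 100.0:
            raise ValueError("tree cover must lie in [0, 100] %")


@dataclass
class AirQualityReport:
    """Annual air-quality improvement summary, one row per pollutant.

    ``frame`` columns: mean_with (ug/m3, observed), mean_without (ug/m3, the
    hypothetical no-purification level), avg_pct_improvement (%),
    improvement_amount (ug/m3, = mean_without - mean_with) and
    removal_t_yr (tonnes removed by the whole canopy per year; negative for
    net resuspension).
    """

    frame: pd.DataFrame

    COLUMNS = ["mean_with", "mean_without", "avg_pct_improvement",
               "improvement_amount", "removal_t_yr"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"report missing columns: {missing}")

    def pollutant(self, name: str) -> pd.Series:
        return self.frame.loc[name]

    @classmethod
    def from_annual_values(
        cls,
        mean_with: dict[str, float],
        mean_without: dict[str, float],
        avg_pct: dict[str, float] | None = None,
        removal_t_yr: dict[str, float] | None = None,
    ) -> "AirQualityReport":
        """Build a report directly from annual summary values (no hourly
        data), e.g. from a published monitoring summary; used in
        annual-proxy assessments."""
        rows = {}
        for p in mean_with:
            amount = mean_without[p] - mean_with[p]
            rows[p] = {
                "mean_with": mean_with[p],
                "mean_without": mean_without[p],
                "avg_pct_improvement": (avg_pct or {}).get(
                    p, 100.0 * amount / mean_without[p] if mean_without[p] else 0.0),
                "improvement_amount": amount,
                "removal_t_yr": (removal_t_yr or {}).get(p, np.nan),
            }
        return cls(pd.DataFrame.from_dict(rows, orient="index")[cls.COLUMNS])


def _vd_for(params: DepositionParams, pollutant: str) -> float:
    if pollutant not in params.vd:
        raise KeyError(f"unknown pollutant {pollutant!r}: no deposition velocity")
    return params.vd[pollutant]


def pollutant_flux(concentration, wind, precip, params: DepositionParams,
                   pollutant: str):
    """Hourly pollutant flux F in g m^-2 h^-1 (vectorised over arrays).

    Gases: F = vd * C (never negative).  PM2.5: wind above the threshold with
    no rain resuspends a fraction of the boundary-layer column per hour,
    an effective upward velocity pm_resusp_rate * blh subtracted from vd, so
    F can be negative.
    """
    vd = _vd_for(params, pollutant)
    c = np.asarray(concentration, dtype=float)
    f = vd * c / UG_PER_G
    if pollutant == "PM2.5":
        w = np.asarray(wind, dtype=float)
        r = np.asarray(precip, dtype=float)
        active = (w > params.pm_wind_threshold) & (r < params.pm_rain_threshold)
        resusp = params.pm_resusp_rate * params.blh * c / UG_PER_G
        f = f - np.where(active, resusp, 0.0)
    return f if f.ndim else float(f)


def unit_improvement(F, M_total):
    """Hourly air-quality improvement per unit tree cover, percent."""
    F = np.asarray(F, dtype=float)
    M = np.asarray(M_total, dtype=float)
    if np.any(M <= 0):
        raise ValueError("M_total must be > 0")
    denom = F + M
    if np.any(denom == 0):
        raise ValueError("degenerate: F + M_total = 0")
    out = F / denom * 100.0
    return out if out.ndim else float(out)


def total_improvement(F, M_total, tree_cover_pct):
    """Hourly improvement for the actual tree cover Tc (%), percent."""
    if not 0.0 <= tree_cover_pct <= 100.0:
        raise ValueError("tree cover must lie in [0, 100] %")
    F = np.asarray(F, dtype=float)
    scaled = F * tree_cover_pct / 100.0
    return unit_improvement(scaled, M_total)


def concentration_change(concentration, I_total_pct):
    """Concentration change dC (ug/m3) removed by the canopy.

    The no-purification level is C + dC = C / (1 - I_total/100).
    """
    c = np.asarray(concentration, dtype=float)
    i = np.asarray(I_total_pct, dtype=float)
    if np.any(i >= 100.0):
        raise ValueError("improvement must be < 100 %")
    out = c / (1.0 - i / 100.0) - c
    return out if out.ndim else float(out)


def annual_air_quality_report(
    series: HourlySeries,
    params: DepositionParams,
    city_area_ha: float,
    *,
    max_missing_fraction: float = 0.20,
) -> AirQualityReport:
    """Aggregate hourly deposition to the annual per-pollutant report.

    Per pollutant and hour: F, M_total = C x blh (column mass), I_total and
    dC; annual means are taken over non-missing hours only.  The removal
    mass integrates F x (Tc/100) over the year and the whole city area.
    Raises :class:`CoverageError` above ``max_missing_fraction`` missing.
    """
    if city_area_ha <= 0:
        raise ValueError("city area must be > 0 ha")
    rows = {}
    wind = series.data["wind_speed_ms"].to_numpy()
    precip = series.data["precip_m"].to_numpy()
    n_hours = len(series.data)
    area_m2 = city_area_ha * M2_PER_HA
    tc = params.tree_cover_pct / 100.0

    for p in series.pollutants:
        c = series.data[p].to_numpy(dtype=float)
        valid = ~np.isnan(c)
        missing_frac = 1.0 - valid.sum() / n_hours
        if missing_frac > max_missing_fraction:
            raise CoverageError(
                f"{p}: {missing_frac:.1%} of hours missing "
                f"(limit {max_missing_fraction:.0%})")
        cv = c[valid]
        f = pollutant_flux(cv, wind[valid], precip[valid], params, p)
        m_total = cv * params.blh / UG_PER_G
        ok = m_total > 0
        i_tot = np.zeros_like(cv)
        i_tot[ok] = total_improvement(f[ok], m_total[ok], params.tree_cover_pct)
        dc = concentration_change(cv, i_tot)
        removal_g = float(np.sum(f * tc * area_m2))
        rows[p] = {
            "mean_with": float(cv.mean()),
            "mean_without": float((cv + dc).mean()),
            "avg_pct_improvement": float(i_tot.mean()),
            "improvement_amount": float(dc.mean()),
            "removal_t_yr": removal_g / G_PER_T,
        }
    return AirQualityReport(pd.DataFrame.from_dict(rows, orient="index")[
        AirQualityReport.COLUMNS])
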