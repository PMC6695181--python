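"""Urban-forest inventory: stratified random-plot survey data and city-scale
population estimates.

A survey measures trees on fixed-area plots placed at random within land-use
strata.  Each plot yields a tree density (trees per hectare); a stratum's tree
population is estimated as its area times the mean plot density, with a
standard error of area x sd(densities)/sqrt(n_plots).  City totals and their
standard error follow by summation (independent strata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TreeRecord",
    "Plot",
    "Stratum",
    "TreeInventory",
    "PopulationEstimate",
    "InventorySchemaError",
    "InventoryValidationError",
    "read_inventory",
    "estimate_population",
    "species_summary",
    "tree_density",
]

M2_PER_HA = 10_000.0

#: trait group assigned to species missing from the traits database
DEFAULT_GROUP = "hardwood"
DEFAULT_PHENOLOGY = "deciduous"

TREE_COLUMNS = [
    "tree_id", "species", "dbh_cm", "height_m", "condition",
    "group", "phenology", "open_grown", "plot_id",
]
PLOT_COLUMNS = ["plot_id", "stratum", "area_m2"]
STRATA_COLUMNS = ["stratum", "area_ha"]


class InventorySchemaError(ValueError):
    """A required column is missing from an input table."""


class InventoryValidationError(ValueError):
    """A row violates an invariant (non-positive DBH, dangling reference...)."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured tree (or shrub) on a survey plot.

    ``condition`` is a crown-condition fraction in [0, 1] (1 = excellent),
    used downstream as a growth-rate multiplier.  ``shrub`` records are kept
    in the inventory (they contribute leaf cover to deposition) but are
    excluded from DBH-based carbon allometry.
    """

    tree_id: str
    species: str
    dbh: float           # cm
    height: float        # m
    condition: float     # fraction [0, 1]
    group: str           # conifer | hardwood
    phenology: str       # deciduous | evergreen
    open_grown: bool
    plot_id: str
    shrub: bool = False

    def __post_init__(self) -> None:
        if not self.dbh > 0:
            raise InventoryValidationError(
                f"tree {self.tree_id!r}: dbh must be > 0, got {self.dbh}")
        if not self.height > 0:
            raise InventoryValidationError(
                f"tree {self.tree_id!r}: height must be > 0, got {self.height}")
        if not 0.0 <= self.condition <= 1.0:
            raise InventoryValidationError(
                f"tree {self.tree_id!r}: condition must lie in [0, 1], "
                f"got {self.condition}")
        if self.group not in ("conifer", "hardwood"):
            raise InventoryValidationError(
                f"tree {self.tree_id!r}: unknown trait group {self.group!r}")


@dataclass(frozen=True)
class Plot:
    plot_id: str
    stratum: str
    area_m2: float

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise InventoryValidationError(
                f"plot {self.plot_id!r}: area must be > 0, got {self.area_m2}")


@dataclass(frozen=True)
class Stratum:
    name: str
    area_ha: float

    def __post_init__(self) -> None:
        if self.area_ha < 0:
            raise InventoryValidationError(
                f"stratum {self.name!r}: area must be >= 0, got {self.area_ha}")


@dataclass
class TreeInventory:
    """Validated survey: trees grouped by plot, plots grouped by stratum."""

    trees: list[TreeRecord]
    plots: dict[str, Plot]
    strata: dict[str, Stratum]

    def __post_init__(self) -> None:
        for p in self.plots.values():
            if p.stratum not in self.strata:
                raise InventoryValidationError(
                    f"plot {p.plot_id!r} references unknown stratum {p.stratum!r}")
        for i, t in enumerate(self.trees):
            if t.plot_id not in self.plots:
                raise InventoryValidationError(
                    f"tree row {i} ({t.tree_id!r}) references unknown plot "
                    f"{t.plot_id!r}")

    def __len__(self) -> int:
        return len(self.trees)

    def trees_in_plot(self, plot_id: str) -> list[TreeRecord]:
        return [t for t in self.trees if t.plot_id == plot_id]

    def plots_in_stratum(self, stratum: str) -> list[Plot]:
        return [p for p in self.plots.values() if p.stratum == stratum]

    def stratum_of_tree(self, tree: TreeRecord) -> str:
        return self.plots[tree.plot_id].stratum

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tree_id": t.tree_id, "species": t.species, "dbh_cm": t.dbh,
                    "height_m": t.height, "condition": t.condition,
                    "group": t.group, "phenology": t.phenology,
                    "open_grown": t.open_grown, "plot_id": t.plot_id,
                    "stratum": self.plots[t.plot_id].stratum,
                    "shrub": t.shrub,
                }
                for t in self.trees
            ],
            columns=[
                "tree_id", "species", "dbh_cm", "height_m", "condition",
                "group", "phenology", "open_grown", "plot_id", "stratum",
                "shrub",
            ],
        )


@dataclass
class PopulationEstimate:
    """City-scale tree-population totals expanded from plot densities."""

    per_stratum: dict[str, tuple[float, float]]  # name -> (total, SE)

    @property
    def city_total(self) -> float:
        return float(sum(t for t, _ in self.per_stratum.values()))

    @property
    def city_se(self) -> float:
        return math.sqrt(sum(se ** 2 for _, se in self.per_stratum.values()))

    @property
    def relative_se(self) -> float:
        total = self.city_total
        return self.city_se / total if total > 0 else 0.0


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InventorySchemaError(
            f"{table} table is missing required column(s): {', '.join(missing)}")


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("1", "true", "yes", "y")


def read_inventory(
    tree_table: str | Path | pd.DataFrame,
    plot_table: str | Path | pd.DataFrame,
    strata_table: str | Path | pd.DataFrame,
    *,
    default_group: str = DEFAULT_GROUP,
    default_phenology: str = DEFAULT_PHENOLOGY,
) -> TreeInventory:
    """Read and validate the three survey CSVs (or pre-loaded frames).

    Rows with an empty trait ``group``/``phenology`` (unknown species) fall
    back to the configurable defaults.  Raises :class:`InventorySchemaError`
    for missing columns and :class:`InventoryValidationError` for invariant
    violations, citing the offending row.
    """
    trees_df = tree_table if isinstance(tree_table, pd.DataFrame) else pd.read_csv(tree_table)
    plots_df = plot_table if isinstance(plot_table, pd.DataFrame) else pd.read_csv(plot_table)
    strata_df = strata_table if isinstance(strata_table, pd.DataFrame) else pd.read_csv(strata_table)

    _require_columns(trees_df, TREE_COLUMNS, "tree")
    _require_columns(plots_df, PLOT_COLUMNS, "plot")
    _require_columns(strata_df, STRATA_COLUMNS, "strata")

    strata = {
        str(r.stratum): Stratum(str(r.stratum), float(r.area_ha))
        for r in strata_df.itertuples()
    }
    if len(strata) != len(strata_df):
        raise InventoryValidationError("stratum names must be unique")
    plots = {
        str(r.plot_id): Plot(str(r.plot_id), str(r.stratum), float(r.area_m2))
        for r in plots_df.itertuples()
    }

    trees: list[TreeRecord] = []
    for i, r in enumerate(trees_df.itertuples()):
        group = str(r.group).strip() if pd.notna(r.group) and str(r.group).strip() else default_group
        phen = (str(r.phenology).strip()
                if pd.notna(r.phenology) and str(r.phenology).strip()
                else default_phenology)
        try:
            trees.append(TreeRecord(
                tree_id=str(r.tree_id),
                species=str(r.species),
                dbh=float(r.dbh_cm),
                height=float(r.height_m),
                condition=float(r.condition),
                group=group,
                phenology=phen,
                open_grown=_as_bool(r.open_grown),
                plot_id=str(r.plot_id),
                shrub=_as_bool(getattr(r, "shrub", False)),
            ))
        except InventoryValidationError as exc:
            raise InventoryValidationError(f"tree table row {i}: {exc}") from None

    return TreeInventory(trees=trees, plots=plots, strata=strata)


def estimate_population(inventory: TreeInventory) -> PopulationEstimate:
    """Expand plot samples to per-stratum and city tree totals.

    stratum total = area_ha x mean(plot densities /ha);
    stratum SE    = area_ha x sd(densities, ddof=1)/sqrt(n_plots)  (0 if n=1).
    Strata with no plots contribute (0, 0) only if their area is 0; a stratum
    with positive area and no plots is unsampled and raises.
    """
    if not inventory.plots:
        raise InventoryValidationError("inventory has no plots; cannot expand")

    counts: dict[str, int] = {pid: 0 for pid in inventory.plots}
    for t in inventory.trees:
        counts[t.plot_id] += 1

    per_stratum: dict[str, tuple[float, float]] = {}
    for name, stratum in inventory.strata.items():
        plots = inventory.plots_in_stratum(name)
        if not plots:
            if stratum.area_ha > 0:
                raise InventoryValidationError(
                    f"stratum {name!r} has area {stratum.area_ha} ha but no plots")
            per_stratum[name] = (0.0, 0.0)
            continue
        if stratum.area_ha == 0:
            raise InventoryValidationError(
                f"stratum {name!r} has plots but zero area")
        densities = np.array(
            [counts[p.plot_id] / (p.area_m2 / M2_PER_HA) for p in plots])
        total = stratum.area_ha * float(densities.mean())
        if len(densities) > 1:
            se = stratum.area_ha * float(densities.std(ddof=1)) / math.sqrt(len(densities))
        else:
            se = 0.0
        per_stratum[name] = (total, se)

    return PopulationEstimate(per_stratum=per_stratum)


def species_summary(
    per_tree_services: pd.DataFrame,
    *,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Per-species structure/service table with percentage shares.

    ``per_tree_services`` has one row per tree (or per species with a
    ``count`` column) and columns ``species``, ``carbon_storage_t``,
    ``net_sequestration_t_yr``, ``pollution_removal_t_yr``.  Returns a frame
    indexed by species with count, % of population and service totals with
    their % shares; a ``Total`` row holds the column sums.  With ``top_n``,
    only the ``top_n`` most numerous species are listed plus a summed
    ``Top`` row and the grand ``Total``.
    """
    value_cols = ["carbon_storage_t", "net_sequestration_t_yr", "pollution_removal_t_yr"]
    if per_tree_services.empty:
        out = pd.DataFrame(columns=["count", "count_pct", *value_cols,
                                    *[c + "_pct" for c in value_cols]])
        out.loc["Total"] = 0.0
        return out

    df = per_tree_services.copy()
    if "count" not in df.columns:
        df["count"] = 1
    if (df[value_cols] < 0).any().any():
        raise ValueError("service values must be nonnegative")

    grouped = df.groupby("species", sort=False)[["count", *value_cols]].sum()
    grouped = grouped.sort_values("count", ascending=False)

    totals = grouped.sum()
    out = grouped.copy()
    out["count_pct"] = 100.0 * out["count"] / totals["count"]
    for c in value_cols:
        out[c + "_pct"] = (100.0 * out[c] / totals[c]) if totals[c] > 0 else 0.0

    if top_n is not None:
        head = out.iloc[:top_n]
        top_row = head.sum()
        out = pd.concat([head, pd.DataFrame([top_row], index=["Top"])])

    total_row = pd.Series(
        {**totals, "count_pct": 100.0,
         **{c + "_pct": (100.0 if totals[c] > 0 else 0.0) for c in value_cols}})
    out = pd.concat([out, pd.DataFrame([total_row], index=["Total"])])
    ordered = ["count", "count_pct"]
    for c in value_cols:
        ordered += [c, c + "_pct"]
    return out[ordered]


def tree_density(total_trees: float, city_area_ha: float) -> float:
    """Trees per hectare (report layer rounds to the nearest integer)."""
    if city_area_ha <= 0:
        raise ValueError(f"city area must be > 0 ha, got {city_area_ha}")
    if total_trees < 0:
        raise ValueError("tree count must be >= 0")
    return total_trees / city_area_ha
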