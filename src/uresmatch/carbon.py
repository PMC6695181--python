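"""Tree carbon storage and annual sequestration.

Above-ground fresh biomass comes from a power-law allometry on stem size,
B_fresh = a * (dbh^2 * height)^b.  Whole-tree carbon follows the standard
urban-forestry factor chain: add below-ground biomass with a root-to-shoot
ratio of 0.26, convert fresh to dry weight (0.48 conifer / 0.56 hardwood),
downrate open-grown trees by 0.8 (forest-derived equations over-predict
maintained urban trees), and take carbon as 0.5 of dry biomass.
Sequestration is the first difference of storage under one year of diameter
growth, and CO2-equivalents use the 44/12 molar ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .inventory import PopulationEstimate, TreeInventory, TreeRecord

__all__ = [
    "SpeciesTraits",
    "CarbonConstants",
    "TraitsDB",
    "load_traits",
    "aboveground_fresh_biomass",
    "tree_carbon_storage",
    "tree_carbon_sequestration",
    "city_carbon",
]

logger = logging.getLogger(__name__)

CO2_PER_C = 44.0 / 12.0

#: fresh-to-dry conversion by trait group
DRY_FACTORS = {"conifer": 0.48, "hardwood": 0.56}


@dataclass(frozen=True)
class SpeciesTraits:
    """Allometric and growth parameters for one species (or trait group).

    ``allometric_a``/``allometric_b`` parameterise fresh above-ground biomass
    in kg with dbh in cm and height in m; ``growth_dbh`` is the annual
    diameter increment (cm/yr) of a tree in perfect condition — the record's
    condition fraction multiplies it.
    """

    group: str                       # conifer | hardwood
    dry_factor: float | None = None  # default by group
    allometric_a: float = 0.10
    allometric_b: float = 0.95
    growth_dbh: float = 0.6          # cm/yr at condition = 1

    def __post_init__(self) -> None:
        if self.group not in DRY_FACTORS:
            raise ValueError(f"unknown trait group {self.group!r}")
        if self.allometric_a <= 0:
            raise ValueError("allometric_a must be > 0")
        if self.dry_factor is not None and self.dry_factor <= 0:
            raise ValueError("dry_factor must be > 0")

    @property
    def effective_dry_factor(self) -> float:
        return self.dry_factor if self.dry_factor is not None else DRY_FACTORS[self.group]


@dataclass(frozen=True)
class CarbonConstants:
    root_to_shoot: float = 0.26
    open_grown_adjust: float = 0.8
    carbon_fraction: float = 0.5
    co2_per_c: float = CO2_PER_C
    #: height growth per cm of dbh growth (m/cm); 0 keeps height static
    height_growth_per_cm_dbh: float = 0.0

    def __post_init__(self) -> None:
        for name in ("root_to_shoot", "open_grown_adjust", "carbon_fraction", "co2_per_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class TraitsDB:
    """Species -> traits lookup with a configurable per-group fallback."""

    def __init__(
        self,
        species: dict[str, SpeciesTraits] | None = None,
        group_defaults: dict[str, SpeciesTraits] | None = None,
    ) -> None:
        self.species = dict(species or {})
        self.group_defaults = dict(group_defaults or {
            "conifer": SpeciesTraits(group="conifer", allometric_a=0.08, growth_dbh=0.4),
            "hardwood": SpeciesTraits(group="hardwood", allometric_a=0.10, growth_dbh=0.6),
        })

    def resolve(self, tree: TreeRecord) -> SpeciesTraits:
        if tree.species in self.species:
            return self.species[tree.species]
        if tree.group in self.group_defaults:
            return self.group_defaults[tree.group]
        raise KeyError(
            f"no traits for species {tree.species!r} (group {tree.group!r})")


def load_traits(path: str | Path | None = None) -> TraitsDB:
    """Load a traits database from YAML; ``None`` loads the bundled default."""
    if path is None:
        path = Path(__file__).parent / "data" / "traits.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    species = {
        name: SpeciesTraits(**params) for name, params in (raw.get("species") or {}).items()
    }
    group_defaults = {
        name: SpeciesTraits(**params)
        for name, params in (raw.get("group_defaults") or {}).items()
    }
    return TraitsDB(species=species, group_defaults=group_defaults or None)


def aboveground_fresh_biomass(tree: TreeRecord, traits: SpeciesTraits) -> float:
    """Fresh above-ground biomass (kg) from the power-law allometry."""
    return traits.allometric_a * (tree.dbh ** 2 * tree.height) ** traits.allometric_b


def tree_carbon_storage(
    tree: TreeRecord,
    traits: SpeciesTraits,
    constants: CarbonConstants = CarbonConstants(),
    *,
    fresh_aboveground_kg: float | None = None,
) -> float:
    """Whole-tree stored carbon (kg C).

    ``fresh_aboveground_kg`` overrides the allometric biomass (useful when an
    external biomass estimate exists); otherwise it is computed from dbh and
    height.  Shrub records store no DBH-based carbon.
    """
    if tree.shrub:
        return 0.0
    if fresh_aboveground_kg is None:
        fresh_aboveground_kg = aboveground_fresh_biomass(tree, traits)
    whole_fresh = fresh_aboveground_kg * (1.0 + constants.root_to_shoot)
    dry = whole_fresh * traits.effective_dry_factor
    if tree.open_grown:
        dry *= constants.open_grown_adjust
    return dry * constants.carbon_fraction


def tree_carbon_sequestration(
    tree: TreeRecord,
    traits: SpeciesTraits,
    constants: CarbonConstants = CarbonConstants(),
) -> float:
    """Annual carbon sequestration (kg C/yr): storage next year minus now.

    Diameter grows by ``growth_dbh x condition``; height optionally grows in
    proportion (``height_growth_per_cm_dbh``).  Negative configured growth is
    permitted (senescence) but logged.
    """
    if tree.shrub:
        return 0.0
    growth = traits.growth_dbh * tree.condition
    if growth < 0:
        logger.warning(
            "negative diameter growth %.3f cm/yr for tree %s (senescence)",
            growth, tree.tree_id)
    grown = replace(
        tree,
        dbh=tree.dbh + growth,
        height=tree.height + constants.height_growth_per_cm_dbh * growth,
    )
    return tree_carbon_storage(grown, traits, constants) - tree_carbon_storage(
        tree, traits, constants)


def city_carbon(
    inventory: TreeInventory,
    estimate: PopulationEstimate,
    traits_db: TraitsDB,
    constants: CarbonConstants = CarbonConstants(),
    *,
    city_area_ha: float | None = None,
) -> dict[str, float]:
    """Scale sampled per-tree carbon to the city.

    Each sampled tree in stratum *s* carries an expansion factor
    (estimated stratum total / number sampled in *s*).  Returns totals in
    tonnes: ``storage_t``, ``sequestration_t_yr``, ``co2eq_t_yr`` and, when
    ``city_area_ha`` is given, ``sequestration_t_ha_yr``.
    """
    sampled: dict[str, list[TreeRecord]] = {}
    for t in inventory.trees:
        sampled.setdefault(inventory.stratum_of_tree(t), []).append(t)

    storage_kg = 0.0
    seq_kg = 0.0
    for stratum, (total, _se) in estimate.per_stratum.items():
        trees = sampled.get(stratum, [])
        if total > 0 and not trees:
            raise ValueError(
                f"stratum {stratum!r} has an estimated population of {total:.0f}"
                " trees but no sampled trees to scale")
        if not trees:
            continue
        expansion = total / len(trees)
        for t in trees:
            tr = traits_db.resolve(t)
            storage_kg += expansion * tree_carbon_storage(t, tr, constants)
            seq_kg += expansion * tree_carbon_sequestration(t, tr, constants)

    out = {
        "storage_t": storage_kg / 1000.0,
        "sequestration_t_yr": seq_kg / 1000.0,
        "co2eq_t_yr": seq_kg / 1000.0 * constants.co2_per_c,
    }
    if city_area_ha is not None:
        out["sequestration_t_ha_yr"] = out["sequestration_t_yr"] / city_area_ha
    return out
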