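import numpy as np
import pandas as pd
import pytest

from uresmatch.deposition import HourlySeries
from uresmatch.inventory import Plot, Stratum, TreeInventory, TreeRecord


def make_tree(tree_id="t1", species="Robinia pseudoacacia", dbh=20.0,
              height=10.0, condition=1.0, group="hardwood",
              phenology="deciduous", open_grown=False, plot_id="p1",
              shrub=False) -> TreeRecord:
    return TreeRecord(tree_id=tree_id, species=species, dbh=dbh, height=height,
                      condition=condition, group=group, phenology=phenology,
                      open_grown=open_grown, plot_id=plot_id, shrub=shrub)


def make_inventory(trees, plot_specs, strata_specs) -> TreeInventory:
    """plot_specs: (plot_id, stratum, area_m2); strata_specs: (name, area_ha)."""
    return TreeInventory(
        trees=list(trees),
        plots={pid: Plot(pid, s, a) for pid, s, a in plot_specs},
        strata={n: Stratum(n, a) for n, a in strata_specs},
    )


def constant_year(pollutants: dict[str, float], wind=1.0, precip=0.0,
                  year=2015) -> HourlySeries:
    idx = pd.date_range(f"{year}-01-01", f"{year + 1}-01-01", freq="h",
                        inclusive="left")
    df = pd.DataFrame({p: np.full(len(idx), c) for p, c in pollutants.items()},
                      index=idx)
    df["wind_speed_ms"] = wind
    df["precip_m"] = precip
    return HourlySeries(df)


@pytest.fixture
def two_tree_inventory():
    """One conifer + one hardwood on two plots in one 10-ha stratum."""
    trees = [
        make_tree("c1", "Pinus nigra", dbh=15, height=8, group="conifer",
                  phenology="evergreen", plot_id="p1"),
        make_tree("h1", "Robinia pseudoacacia", dbh=25, height=12,
                  group="hardwood", plot_id="p2"),
    ]
    return make_inventory(
        trees,
        [("p1", "residential", 1000.0), ("p2", "residential", 1000.0)],
        [("residential", 10.0)],
    )


@pytest.fixture
def survey_csvs(tmp_path):
    """Valid tree/plot/strata CSV files on disk."""
    trees = tmp_path / "trees.csv"
    trees.write_text(
        "tree_id,species,dbh_cm,height_m,condition,group,phenology,open_grown,plot_id\n"
        "c1,Pinus nigra,15,8,1.0,conifer,evergreen,false,p1\n"
        "h1,Robinia pseudoacacia,25,12,0.8,hardwood,deciduous,true,p2\n")
    plots = tmp_path / "plots.csv"
    plots.write_text("plot_id,stratum,area_m2\np1,residential,1000\np2,residential,1000\n")
    strata = tmp_path / "strata.csv"
    strata.write_text("stratum,area_ha\nresidential,10\n")
    return trees, plots, strata
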