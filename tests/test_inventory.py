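"""Survey reading, population expansion and species summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uresmatch.inventory import (InventorySchemaError, InventoryValidationError,
                                 PopulationEstimate, estimate_population,
                                 read_inventory, species_summary, tree_density)

from conftest import make_inventory, make_tree


class TestReadInventory:
    def test_two_row_fixture_resolves_strata(self, survey_csvs):
        inv = read_inventory(*survey_csvs)
        assert len(inv) == 2
        by_id = {t.tree_id: t for t in inv.trees}
        assert by_id["c1"].group == "conifer"
        assert by_id["h1"].open_grown is True
        assert inv.stratum_of_tree(by_id["c1"]) == "residential"
        assert inv.plots["p1"].area_m2 == 1000

    def test_empty_tree_table(self, survey_csvs, tmp_path):
        trees, plots, strata = survey_csvs
        empty = tmp_path / "empty.csv"
        empty.write_text(
            "tree_id,species,dbh_cm,height_m,condition,group,phenology,open_grown,plot_id\n")
        inv = read_inventory(empty, plots, strata)
        assert len(inv) == 0

    def test_missing_column_names_it(self, survey_csvs, tmp_path):
        _, plots, strata = survey_csvs
        bad = tmp_path / "bad.csv"
        bad.write_text("tree_id,species,height_m,condition,group,phenology,open_grown,plot_id\n")
        with pytest.raises(InventorySchemaError, match="dbh_cm"):
            read_inventory(bad, plots, strata)

    def test_negative_dbh_cites_row(self, survey_csvs, tmp_path):
        _, plots, strata = survey_csvs
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "tree_id,species,dbh_cm,height_m,condition,group,phenology,open_grown,plot_id\n"
            "x,Ulmus,-3,5,1,hardwood,deciduous,false,p1\n")
        with pytest.raises(InventoryValidationError, match="row 0"):
            read_inventory(bad, plots, strata)

    def test_dangling_plot_reference(self, survey_csvs, tmp_path):
        trees, plots, strata = survey_csvs
        bad = tmp_path / "badtree.csv"
        bad.write_text(
            "tree_id,species,dbh_cm,height_m,condition,group,phenology,open_grown,plot_id\n"
            "x,Ulmus,10,5,1,hardwood,deciduous,false,nope\n")
        with pytest.raises(InventoryValidationError, match="nope"):
            read_inventory(bad, plots, strata)

    def test_unknown_species_defaults_to_hardwood(self, survey_csvs, tmp_path):
        _, plots, strata = survey_csvs
        t = tmp_path / "t.csv"
        t.write_text(
            "tree_id,species,dbh_cm,height_m,condition,group,phenology,open_grown,plot_id\n"
            "x,Mystery sp.,10,5,1,,,false,p1\n")
        inv = read_inventory(t, plots, strata)
        assert inv.trees[0].group == "hardwood"
        assert inv.trees[0].phenology == "deciduous"


class TestEstimatePopulation:
    def test_uniform_density(self):
        trees = [make_tree(f"t{i}", plot_id="p1") for i in range(5)]
        trees += [make_tree(f"u{i}", plot_id="p2") for i in range(5)]
        inv = make_inventory(trees,
                             [("p1", "s", 1000.0), ("p2", "s", 1000.0)],
                             [("s", 10.0)])
        est = estimate_population(inv)
        assert est.city_total == pytest.approx(500.0)
        assert est.city_se == pytest.approx(0.0)

    def test_unequal_densities_se(self):
        # densities 40 and 60 /ha -> total 500, SE = 10 * sd({40,60})/sqrt(2) = 100
        trees = [make_tree(f"t{i}", plot_id="p1") for i in range(4)]
        trees += [make_tree(f"u{i}", plot_id="p2") for i in range(6)]
        inv = make_inventory(trees,
                             [("p1", "s", 1000.0), ("p2", "s", 1000.0)],
                             [("s", 10.0)])
        est = estimate_population(inv)
        assert est.city_total == pytest.approx(500.0)
        assert est.city_se == pytest.approx(100.0)

    def test_empty_stratum_contributes_zero(self):
        inv = make_inventory([make_tree(plot_id="p1")],
                             [("p1", "s", 1000.0)],
                             [("s", 10.0), ("void", 0.0)])
        est = estimate_population(inv)
        assert est.per_stratum["void"] == (0.0, 0.0)

    def test_unsampled_stratum_with_area_raises(self):
        inv = make_inventory([make_tree(plot_id="p1")],
                             [("p1", "s", 1000.0)],
                             [("s", 10.0), ("park", 5.0)])
        with pytest.raises(InventoryValidationError, match="park"):
            estimate_population(inv)

    def test_no_plots_raises(self):
        inv = make_inventory([], [], [("s", 0.0)])
        with pytest.raises(InventoryValidationError):
            estimate_population(inv)

    @given(st.lists(st.tuples(st.floats(0, 1e4), st.floats(0, 1e3)),
                    min_size=1, max_size=6))
    def test_city_se_is_root_sum_of_squares(self, per_stratum):
        est = PopulationEstimate(
            per_stratum={f"s{i}": v for i, v in enumerate(per_stratum)})
        expected = math.sqrt(sum(se ** 2 for _, se in per_stratum))
        assert est.city_se == pytest.approx(expected)
        assert est.city_total == pytest.approx(sum(t for t, _ in per_stratum))


class TestSpeciesSummary:
    def test_totals_equal_brute_force_sums(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "species": rng.choice(list("abcd"), size=40),
            "carbon_storage_t": rng.uniform(0, 5, 40),
            "net_sequestration_t_yr": rng.uniform(0, 1, 40),
            "pollution_removal_t_yr": rng.uniform(0, 0.1, 40),
        })
        out = species_summary(df)
        # independent brute-force recount
        for col in ("carbon_storage_t", "net_sequestration_t_yr",
                    "pollution_removal_t_yr"):
            total = 0.0
            for _, row in df.iterrows():
                total += row[col]
            assert out.loc["Total", col] == pytest.approx(total)
        assert out.loc["Total", "count"] == 40
        species_rows = out.drop(index=["Total"])
        assert species_rows["count_pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_species_share_is_100(self):
        df = pd.DataFrame({"species": ["x"], "carbon_storage_t": [1.0],
                           "net_sequestration_t_yr": [0.5],
                           "pollution_removal_t_yr": [0.1]})
        out = species_summary(df)
        assert out.loc["x", "count_pct"] == pytest.approx(100.0)

    def test_empty_input_zeroed(self):
        out = species_summary(pd.DataFrame(
            columns=["species", "carbon_storage_t", "net_sequestration_t_yr",
                     "pollution_removal_t_yr"]))
        assert (out.loc["Total"] == 0).all()

    def test_negative_service_rejected(self):
        df = pd.DataFrame({"species": ["x"], "carbon_storage_t": [-1.0],
                           "net_sequestration_t_yr": [0.0],
                           "pollution_removal_t_yr": [0.0]})
        with pytest.raises(ValueError):
            species_summary(df)


class TestTreeDensity:
    @pytest.mark.parametrize("total,area,expected", [
        (1_927_566, 24_480, 78.74),
        (0, 10, 0.0),
        (100, 4, 25.0),
    ])
    def test_density(self, total, area, expected):
        assert tree_density(total, area) == pytest.approx(expected, abs=0.005)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            tree_density(10, 0)
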