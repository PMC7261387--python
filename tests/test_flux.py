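"""Biomass stock and flux accounting: unit conversions and conservation."""

import numpy as np
import pandas as pd
import pytest

import forestdyn as fd

from conftest import make_table, row

WD = pd.DataFrame({"species": ["spA"], "wd_g_cm3": [0.6], "measured": [1]})


def analysis(table, wd=WD):
    bio = fd.effective_biomass(table, wd)
    return bio


class TestStock:
    def test_unit_conversion_to_mg_per_ha(self):
        # two 300 kg trees on 600 m2 -> 0.6 Mg / 0.06 ha = 10 Mg/ha
        table = make_table([row("P1", "t1", 2000, 10.0), row("P1", "t2", 2000, 10.0)])
        bio = analysis(table)
        bio["agb_kg"] = 300.0  # force known per-tree biomass
        s = fd.stock(table, bio, "P1", 2000.0)
        assert s.agb_stock == pytest.approx(10.0)
        assert s.n_stems == 2
        assert s.carbon_stock == pytest.approx(4.7)

    def test_empty_plot_has_zero_stock(self):
        rows = [row("P1", "t1", 2000, 10.0)]
        plots = [{"plot_id": p, "area_m2": 600, "site": "NF", "sector": ""}
                 for p in ("P1", "P2")]
        table = make_table(rows, plots)
        s = fd.stock(table, analysis(table), "P2", 2000.0)
        assert s.agb_stock == 0.0 and s.n_stems == 0

    def test_missing_biomass_names_the_tree(self):
        table = make_table([row("P1", "t1", 2000, 10.0),
                            row("P1", "t2", 2000, 12.0)])
        bio = analysis(table)
        bio = bio.loc[bio["tree_id"] != "t2"]
        with pytest.raises(ValueError, match="t2"):
            fd.stock(table, bio, "P1", 2000.0)


def _ha_plot_rows():
    return [{"plot_id": "P1", "area_m2": 10_000.0, "site": "NF", "sector": ""}]


class TestProductivity:
    def test_hand_summed_components(self):
        # 1-ha plot, t=2: growth 100->110 and 200->230 kg, recruit at 50 kg
        table = make_table(
            [row("P1", "s1", 2000, 10.0), row("P1", "s2", 2000, 20.0),
             row("P1", "s1", 2002, 11.0), row("P1", "s2", 2002, 21.0),
             row("P1", "rec", 2002, 5.5)],
            _ha_plot_rows())
        bio = analysis(table)
        forced = {("s1", 2000.0): 100.0, ("s1", 2002.0): 110.0,
                  ("s2", 2000.0): 200.0, ("s2", 2002.0): 230.0,
                  ("rec", 2002.0): 50.0}
        bio["agb_kg"] = [forced[(t, y)] for t, y in
                         zip(bio["tree_id"], bio["census_year"])]
        pb = fd.productivity(table, bio, "P1", "I1")
        assert pb == pytest.approx(0.045)

    def test_static_stand_has_zero_productivity(self):
        table = make_table([row("P1", "t1", 2000, 10.0),
                            row("P1", "t1", 2002, 10.0)], _ha_plot_rows())
        assert fd.productivity(table, analysis(table), "P1", "I1") == \
            pytest.approx(0.0)

    def test_area_weighted_split_invariance(self):
        """PB of one plot equals the area-weighted mean over two half plots."""
        rows_full, rows_a, rows_b = [], [], []
        rng = np.random.default_rng(3)
        for i in range(40):
            d0 = float(rng.uniform(6, 40))
            d1 = d0 + float(rng.uniform(0, 2))
            half = "A" if i < 20 else "B"
            for store, pid in ((rows_full, "P1"),
                               (rows_a if half == "A" else rows_b, half)):
                store.append(row(pid, f"t{i}", 2000, d0))
                store.append(row(pid, f"t{i}", 2003, d1))
        full = make_table(rows_full, _ha_plot_rows())
        halves = make_table(rows_a + rows_b, [
            {"plot_id": "A", "area_m2": 5000.0, "site": "NF", "sector": ""},
            {"plot_id": "B", "area_m2": 5000.0, "site": "NF", "sector": ""}])
        pb_full = fd.productivity(full, analysis(full), "P1", "I1")
        bio_h = analysis(halves)
        pb_a = fd.productivity(halves, bio_h, "A", "I1")
        pb_b = fd.productivity(halves, bio_h, "B", "I1")
        assert pb_full == pytest.approx(0.5 * pb_a + 0.5 * pb_b, rel=1e-9)


class TestNetBiomassChange:
    def _stocks(self, s0, s1, t_years):
        return pd.DataFrame({"plot_id": "P1",
                             "census_year": [2000.0, 2000.0 + t_years],
                             "agb_mg_ha": [s0, s1]})

    def test_equal_stocks_give_zero(self):
        iv = fd.Interval("I1", 2000.0, 2004.0)
        assert fd.net_biomass_change(self._stocks(120, 120, 4), "P1", iv) == 0.0

    def test_gain_annualized(self):
        iv = fd.Interval("I1", 2000.0, 2004.0)
        assert fd.net_biomass_change(self._stocks(120, 150, 4), "P1", iv) == \
            pytest.approx(7.5)

    def test_decline_is_negative(self):
        iv = fd.Interval("I1", 2000.0, 2006.0)
        assert fd.net_biomass_change(self._stocks(150, 120, 6), "P1", iv) == \
            pytest.approx(-5.0)


class TestMortalityFlux:
    def test_single_large_death(self):
        table = make_table(
            [row("P1", "big", 2000, 40.0), row("P1", "small", 2000, 7.0),
             row("P1", "big", 2004, None, None, "dead"),
             row("P1", "small", 2004, 7.5)],
            _ha_plot_rows())
        bio = analysis(table)
        bio.loc[bio["tree_id"] == "big", "agb_kg"] = 2000.0
        mf = fd.mortality_flux(table, bio, "P1", "I1")
        assert mf["L"] == pytest.approx(0.5)
        assert mf["S"] == 0.0 and mf["M"] == 0.0
        assert mf["total"] == pytest.approx(0.5)

    def test_no_deaths_all_zero(self):
        table = make_table([row("P1", "t1", 2000, 10.0),
                            row("P1", "t1", 2002, 10.5)])
        mf = fd.mortality_flux(table, analysis(table), "P1", "I1")
        assert mf["total"] == 0.0

    def test_death_classed_by_start_census_dbh(self):
        # 34.9 cm at start (M class) even though it would be L if grown
        table = make_table(
            [row("P1", "t1", 2000, 34.9), row("P1", "t2", 2000, 10.0),
             row("P1", "t1", 2004, None, None, "dead"),
             row("P1", "t2", 2004, 10.5)],
            _ha_plot_rows())
        mf = fd.mortality_flux(table, analysis(table), "P1", "I1")
        assert mf["M"] > 0 and mf["L"] == 0.0


class TestConservation:
    def test_nbc_equals_pb_minus_mortality_on_simulations(self):
        """The master identity NBC = PB - mortality flux, many seeds."""
        for seed in range(6):
            table, truth, _ = fd.preset_run("tiny", seed)
            wd = truth.wood_density.copy()
            wd["measured"] = 1
            f = fd.flux_table(table, fd.effective_biomass(table, wd))
            lhs = f["nbc_mg_ha_yr"].to_numpy()
            rhs = (f["pb_mg_ha_yr"] - f["mort_flux_total_mg_ha_yr"]).to_numpy()
            np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)
            parts = f[["mort_flux_S_mg_ha_yr", "mort_flux_M_mg_ha_yr",
                       "mort_flux_L_mg_ha_yr"]].sum(axis=1).to_numpy()
            np.testing.assert_allclose(f["mort_flux_total_mg_ha_yr"], parts,
                                       rtol=0, atol=0)

    def test_conservation_on_paper_like(self, paper_like_analysis):
        f = paper_like_analysis["fluxes"]
        np.testing.assert_allclose(
            f["nbc_mg_ha_yr"],
            f["pb_mg_ha_yr"] - f["mort_flux_total_mg_ha_yr"],
            rtol=1e-9, atol=1e-12)


class TestUnitScaling:
    def test_fluxes_scale_with_area(self):
        """Same trees on a plot declared twice as large -> half the flux."""
        rows = [row("P1", "t1", 2000, 12.0), row("P1", "t2", 2000, 30.0),
                row("P1", "t1", 2004, 13.0),
                row("P1", "t2", 2004, None, None, "dead"),
                row("P1", "r1", 2004, 6.0)]
        small = make_table(rows, [{"plot_id": "P1", "area_m2": 5000.0,
                                   "site": "NF", "sector": ""}])
        large = make_table(rows, [{"plot_id": "P1", "area_m2": 10_000.0,
                                   "site": "NF", "sector": ""}])
        fs = fd.flux_table(small, analysis(small)).iloc[0]
        fl = fd.flux_table(large, analysis(large)).iloc[0]
        for col in ("pb_mg_ha_yr", "nbc_mg_ha_yr", "mort_flux_total_mg_ha_yr"):
            assert fs[col] == pytest.approx(2.0 * fl[col], rel=1e-12)
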