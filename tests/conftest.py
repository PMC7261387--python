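import pandas as pd
import pytest

import forestdyn as fd


def make_table(obs_rows, plot_rows=None):
    """Build a validated CensusTable from row dicts (test helper)."""
    obs = pd.DataFrame(obs_rows, columns=["plot_id", "tree_id", "species",
                                          "census_year", "dbh_cm", "height_m",
                                          "status"])
    if plot_rows is None:
        plot_rows = [{"plot_id": p, "area_m2": 600.0, "site": "NF", "sector": ""}
                     for p in sorted(obs["plot_id"].unique())]
    plots = pd.DataFrame(plot_rows)
    return fd.CensusTable(obs=obs, plots=plots)


def row(plot, tree, year, dbh, h=10.0, status="alive", species="spA"):
    return {"plot_id": plot, "tree_id": tree, "species": species,
            "census_year": float(year), "dbh_cm": dbh, "height_m": h,
            "status": status}


@pytest.fixture
def three_row_table():
    """Minimal well-formed table: one plot, one census, three trees."""
    return make_table([row("P1", "t1", 2000, 10.0),
                       row("P1", "t2", 2000, 20.0),
                       row("P1", "t3", 2000, 7.5)])


@pytest.fixture
def two_census_table():
    """One plot, two censuses (t=2): 3 survivors, 1 death, 1 recruit."""
    rows = [row("P1", "t1", 2000, 10.0), row("P1", "t2", 2000, 20.0),
            row("P1", "t3", 2000, 7.0), row("P1", "t4", 2000, 30.0),
            row("P1", "t1", 2002, 11.0), row("P1", "t2", 2002, 21.0),
            row("P1", "t3", 2002, 7.5),
            row("P1", "t4", 2002, None, None, "dead"),
            row("P1", "t5", 2002, 5.5)]
    return make_table(rows)


@pytest.fixture(scope="session")
def paper_like():
    """One paper_like simulation shared across the session (18 plots)."""
    table, truth, drought = fd.preset_run("paper_like", 12345)
    return table, truth, drought


@pytest.fixture(scope="session")
def paper_like_analysis(paper_like):
    """Wood density, biomass, rates and fluxes for the shared simulation."""
    table, truth, _ = paper_like
    wd = truth.wood_density.copy()
    wd["measured"] = 1
    biomass = fd.effective_biomass(table, wd)
    rates = fd.rates_table(table)
    fluxes = fd.flux_table(table, biomass)
    stocks = fd.stock_table(table, biomass)
    return {"table": table, "wd": wd, "biomass": biomass, "rates": rates,
            "fluxes": fluxes, "stocks": stocks}
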