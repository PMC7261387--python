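"""Biomass stock and flux accounting per plot and census interval.

Stocks are stand totals of per-tree aboveground biomass, expressed in
Mg ha^-1.  Over a census interval of length t years on a plot of area A ha:

* productivity  PB  = [sum of recruit AGB at the end census
                       + sum over survivors of (AGB_end - AGB_start)] / (A t)
* net change    NBC = (stock_end - stock_start) / t
* mortality flux    = sum of AGB of stems dying in the interval, valued at
                      their last live (start) census, / (A t), reported in
                      total and split by size class assigned from the
                      start-census DBH.

Valuation conventions — dead stems at start-census biomass, recruits at
their first recorded biomass — make NBC = PB - mortality_flux an exact
accounting identity, the module's master invariant.  Negative survivor
growth (shrinkage or measurement noise) is kept by default and logged;
``truncate_negative_growth`` zeroes it for sensitivity analysis, at the cost
of breaking the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import CARBON_FRACTION, classify_size, compute_agb, tree_biomass_table
from .census import CensusTable, Interval, alive_matrix, build_intervals
from .dynamics import _interval_of

__all__ = [
    "StockResult",
    "effective_biomass",
    "stock",
    "stock_table",
    "productivity",
    "net_biomass_change",
    "mortality_flux",
    "flux_table",
]

logger = logging.getLogger(__name__)

KG_PER_MG = 1000.0
M2_PER_HA = 1e4


@dataclass(frozen=True)
class StockResult:
    """Stand biomass state of one plot at one census."""

    plot_id: str
    census_year: float
    agb_stock: float  # Mg ha^-1
    n_stems: int
    carbon_stock: float  # Mg ha^-1


def effective_biomass(table: CensusTable, wd_table: pd.DataFrame) -> pd.DataFrame:
    """Per-tree AGB at every census at which the tree is effectively alive.

    Recorded alive stems use their measured DBH and height.  Recording gaps
    (tree alive on both sides of a missed census) are filled by linear
    interpolation of DBH and height in census-year time, flagged in the
    ``interpolated`` column and logged.  Returns columns ``tree_id, plot_id,
    census_year, dbh_cm, agb_kg, size_class, interpolated``.
    """
    bio = tree_biomass_table(table, wd_table)
    alive = alive_matrix(table)
    if alive.empty:
        bio["interpolated"] = False
        return bio[["tree_id", "plot_id", "census_year", "dbh_cm", "agb_kg",
                    "size_class", "interpolated"]]
    recorded = set(zip(bio["tree_id"], bio["census_year"]))
    stacked = alive.stack()
    gap_pairs = [(tid, yr) for (tid, yr), v in stacked.items()
                 if v and (tid, yr) not in recorded]
    bio = bio[["tree_id", "plot_id", "census_year", "dbh_cm", "height_m",
               "wd_g_cm3", "agb_kg", "size_class"]].copy()
    bio["interpolated"] = False
    if gap_pairs:
        logger.warning("effective_biomass: interpolating %d gap record(s)",
                       len(gap_pairs))
        by_tree = {tid: g.sort_values("census_year")
                   for tid, g in bio.groupby("tree_id")}
        new_rows = []
        for tid, yr in gap_pairs:
            g = by_tree[tid]
            dbh = float(np.interp(yr, g["census_year"], g["dbh_cm"]))
            h = float(np.interp(yr, g["census_year"], g["height_m"]))
            wd = float(g["wd_g_cm3"].iloc[0])
            new_rows.append({
                "tree_id": tid, "plot_id": g["plot_id"].iloc[0],
                "census_year": yr, "dbh_cm": dbh, "height_m": h,
                "wd_g_cm3": wd, "agb_kg": compute_agb(dbh, h, wd),
                "size_class": classify_size(dbh), "interpolated": True,
            })
        bio = pd.concat([bio, pd.DataFrame(new_rows)], ignore_index=True)
    return bio[["tree_id", "plot_id", "census_year", "dbh_cm", "agb_kg",
                "size_class", "interpolated"]].reset_index(drop=True)


def _plot_census_slice(table: CensusTable, biomass: pd.DataFrame,
                       plot_id: str, census_year: float) -> pd.DataFrame:
    if census_year not in table.census_years:
        raise KeyError(f"{census_year} is not a census year of this table")
    if plot_id not in set(table.plot_ids):
        raise KeyError(f"unknown plot_id: {plot_id!r}")
    return biomass.loc[(biomass["plot_id"] == plot_id)
                       & (biomass["census_year"] == census_year)]


def stock(table: CensusTable, biomass: pd.DataFrame, plot_id: str,
          census_year: float, _alive: pd.DataFrame | None = None) -> StockResult:
    """AGB stock (Mg ha^-1), stem count and carbon stock of one plot-census.

    ``biomass`` is the output of :func:`effective_biomass`; a stem that is
    effectively alive but missing from it is an error naming the tree.
    """
    sub = _plot_census_slice(table, biomass, plot_id, census_year)
    alive = _alive if _alive is not None else alive_matrix(table)
    if not alive.empty:
        tree_plot = table.obs.drop_duplicates("tree_id").set_index("tree_id")["plot_id"]
        expect = alive.index[(tree_plot.reindex(alive.index) == plot_id)
                             & alive[census_year]]
        missing = set(expect) - set(sub["tree_id"])
        if missing:
            raise ValueError(
                f"no biomass for alive stem(s) in {plot_id} @ {census_year}: "
                + ", ".join(sorted(map(str, missing))[:10]))
    area_ha = table.plot_info(plot_id).area_ha
    agb = float(sub["agb_kg"].sum()) / KG_PER_MG / area_ha
    return StockResult(plot_id, census_year, agb, int(len(sub)),
                       CARBON_FRACTION * agb)


def stock_table(table: CensusTable, biomass: pd.DataFrame) -> pd.DataFrame:
    """Per-plot, per-census stocks (columns include site, agb / carbon Mg ha^-1)."""
    site = table.site_of()
    alive = alive_matrix(table)
    rows = []
    for pid in table.plot_ids:
        for yr in table.census_years:
            s = stock(table, biomass, pid, yr, _alive=alive)
            rows.append({"plot_id": pid, "site": site[pid], "census_year": yr,
                         "agb_mg_ha": s.agb_stock, "n_stems": s.n_stems,
                         "carbon_mg_ha": s.carbon_stock})
    return pd.DataFrame(rows)


def _cohorts(table: CensusTable, biomass: pd.DataFrame, plot_id: str,
             iv: Interval) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a plot-interval into survivors (wide), recruits and deaths."""
    start = _plot_census_slice(table, biomass, plot_id, iv.start_year)
    end = _plot_census_slice(table, biomass, plot_id, iv.end_year)
    prior = biomass.loc[(biomass["plot_id"] == plot_id)
                        & (biomass["census_year"] < iv.end_year), "tree_id"]
    seen_before = set(prior)
    surv = start.merge(end, on="tree_id", suffixes=("_start", "_end"))
    recruits = end.loc[~end["tree_id"].isin(seen_before)]
    deaths = start.loc[~start["tree_id"].isin(set(end["tree_id"]))]
    return surv, recruits, deaths


def productivity(table: CensusTable, biomass: pd.DataFrame, plot_id: str,
                 interval: Interval | str,
                 truncate_negative_growth: bool = False) -> float:
    """Aboveground biomass productivity PB (Mg ha^-1 yr^-1) of one plot-interval.

    Recruit biomass at the end census plus survivor growth, divided by plot
    area and interval length.  Negative survivor growth is kept (and logged)
    unless ``truncate_negative_growth``.
    """
    iv = _interval_of(table, interval)
    surv, recruits, _ = _cohorts(table, biomass, plot_id, iv)
    growth = surv["agb_kg_end"].to_numpy() - surv["agb_kg_start"].to_numpy()
    n_neg = int((growth < 0).sum())
    if n_neg:
        logger.info("productivity: %d survivor(s) with negative growth in %s/%s",
                    n_neg, plot_id, iv.label)
    if truncate_negative_growth:
        growth = np.maximum(growth, 0.0)
    total_kg = float(recruits["agb_kg"].sum()) + float(growth.sum())
    area_ha = table.plot_info(plot_id).area_ha
    return total_kg / KG_PER_MG / (area_ha * iv.t)


def net_biomass_change(stocks: pd.DataFrame, plot_id: str,
                       interval: Interval) -> float:
    """NBC (Mg ha^-1 yr^-1): later minus earlier AGB stock, annualized.

    ``stocks`` is the output of :func:`stock_table`.  Decline is negative.
    """
    sub = stocks.loc[stocks["plot_id"] == plot_id].set_index("census_year")
    for yr in (interval.start_year, interval.end_year):
        if yr not in sub.index:
            raise KeyError(f"no stock for plot {plot_id!r} at census {yr}")
    return (float(sub.loc[interval.end_year, "agb_mg_ha"])
            - float(sub.loc[interval.start_year, "agb_mg_ha"])) / interval.t


def mortality_flux(table: CensusTable, biomass: pd.DataFrame, plot_id: str,
                   interval: Interval | str) -> dict[str, float]:
    """Biomass lost to mortality (Mg ha^-1 yr^-1), total and per size class.

    Dying stems are valued at their last live (start-census) AGB and
    classed by their start-census DBH.  Returns keys ``total, S, M, L``.
    """
    iv = _interval_of(table, interval)
    _, _, deaths = _cohorts(table, biomass, plot_id, iv)
    area_ha = table.plot_info(plot_id).area_ha
    denom = KG_PER_MG * area_ha * iv.t
    out = {"S": 0.0, "M": 0.0, "L": 0.0}
    for cls, grp in deaths.groupby("size_class"):
        out[str(cls)] = float(grp["agb_kg"].sum()) / denom
    out["total"] = out["S"] + out["M"] + out["L"]
    return out


def flux_table(table: CensusTable, biomass: pd.DataFrame,
               truncate_negative_growth: bool = False) -> pd.DataFrame:
    """Per-plot, per-interval flux accounting.

    Columns: plot_id, site, interval, t, pb_mg_ha_yr, nbc_mg_ha_yr,
    mort_flux_total/S/M/L (_mg_ha_yr), stock_start_mg_ha, stock_end_mg_ha.
    """
    stocks = stock_table(table, biomass)
    s = stocks.set_index(["plot_id", "census_year"])
    site = table.site_of()
    rows = []
    for pid in table.plot_ids:
        for iv in build_intervals(table):
            pb = productivity(table, biomass, pid, iv,
                              truncate_negative_growth=truncate_negative_growth)
            nbc = net_biomass_change(stocks, pid, iv)
            mf = mortality_flux(table, biomass, pid, iv)
            rows.append({
                "plot_id": pid, "site": site[pid], "interval": iv.label, "t": iv.t,
                "pb_mg_ha_yr": pb, "nbc_mg_ha_yr": nbc,
                "mort_flux_total_mg_ha_yr": mf["total"],
                "mort_flux_S_mg_ha_yr": mf["S"],
                "mort_flux_M_mg_ha_yr": mf["M"],
                "mort_flux_L_mg_ha_yr": mf["L"],
                "stock_start_mg_ha": float(s.loc[(pid, iv.start_year), "agb_mg_ha"]),
                "stock_end_mg_ha": float(s.loc[(pid, iv.end_year), "agb_mg_ha"]),
            })
    return pd.DataFrame(rows)
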