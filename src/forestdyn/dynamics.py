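"""Stem demography: annualized mortality and recruitment with interval correction.

For a plot-interval with N0 initial live stems, Nm deaths, Nr recruits and
Nt final stems, annual rates follow the survivor-fraction (exponential)
forms of Sheil et al.:

    M = 100 * [1 - ((N0 - Nm) / N0)^(1/t)]        (% yr^-1)
    R = 100 * [1 - (1 - Nr / Nt)^(1/t)]           (% yr^-1)

Longer census intervals bias annual turnover low because stems that both
enter and die (or die and are replaced) within the interval go unseen; the
Lewis et al. census-interval correction rescales either rate as

    lambda_corr = lambda * t^0.08.

Counting conventions: a recruit is a tree whose first alive record is the
interval's end census; a tree that vanishes permanently without a dead
record counts as a death (logged); stem conservation Nt = N0 - Nm + Nr is
an exact integer identity under these definitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CensusTable, Interval, alive_matrix, build_intervals

__all__ = [
    "LEWIS_EXPONENT",
    "IntervalCounts",
    "count_interval",
    "count_all_intervals",
    "mortality_rate",
    "recruitment_rate",
    "interval_correction",
    "rates_table",
    "site_rates",
]

logger = logging.getLogger(__name__)

#: Exponent of the Lewis et al. census-interval correction t^0.08.
LEWIS_EXPONENT = 0.08


@dataclass(frozen=True)
class IntervalCounts:
    """Stem counts for one plot-interval: N0, Nm, Nr, Nt and t (years)."""

    plot_id: str
    interval: str
    t: float
    n0: int
    nm: int
    nr: int
    nt: int

    def __post_init__(self) -> None:
        if self.nt != self.n0 - self.nm + self.nr:
            raise ValueError(
                f"stem conservation violated for {self.plot_id}/{self.interval}: "
                f"nt={self.nt} != n0-nm+nr={self.n0 - self.nm + self.nr}")
        if not (0 <= self.nm <= self.n0 and 0 <= self.nr <= self.nt and self.t > 0):
            raise ValueError(f"invalid interval counts: {self}")


def _interval_of(table: CensusTable, interval: Interval | str) -> Interval:
    ivs = build_intervals(table)
    if isinstance(interval, str):
        by_label = {iv.label: iv for iv in ivs}
        if interval not in by_label:
            raise KeyError(f"unknown interval {interval!r}; have {sorted(by_label)}")
        return by_label[interval]
    if interval not in ivs:
        raise KeyError(f"{interval} is not a consecutive census interval of this table")
    return interval


def count_interval(table: CensusTable, plot_id: str,
                   interval: Interval | str,
                   _alive: pd.DataFrame | None = None) -> IntervalCounts:
    """Count N0, Nm, Nr, Nt for one plot over one census interval.

    Uses the effective-alive matrix (recording gaps interpolated, permanent
    disappearance = death).  Raises ``KeyError`` on an unknown plot or
    interval.
    """
    iv = _interval_of(table, interval)
    if plot_id not in set(table.plot_ids):
        raise KeyError(f"unknown plot_id: {plot_id!r}")
    alive = _alive if _alive is not None else alive_matrix(table)
    tree_plot = (table.obs.drop_duplicates("tree_id").set_index("tree_id")["plot_id"])
    in_plot = alive.index[tree_plot.reindex(alive.index) == plot_id]
    sub = alive.loc[in_plot]
    if sub.empty:
        return IntervalCounts(plot_id, iv.label, iv.t, 0, 0, 0, 0)
    start_alive = sub[iv.start_year].to_numpy()
    end_alive = sub[iv.end_year].to_numpy()
    arr = sub.to_numpy()
    first_alive_idx = np.where(arr.any(axis=1), arr.argmax(axis=1), len(sub.columns))
    end_idx = list(sub.columns).index(iv.end_year)
    n0 = int(start_alive.sum())
    nm = int((start_alive & ~end_alive).sum())
    nr = int((end_alive & (first_alive_idx == end_idx)).sum())
    nt = int(end_alive.sum())
    return IntervalCounts(plot_id, iv.label, iv.t, n0, nm, nr, nt)


def count_all_intervals(table: CensusTable) -> list[IntervalCounts]:
    """All plot-interval counts for a table (one alive-matrix pass)."""
    alive = alive_matrix(table)
    return [count_interval(table, pid, iv, _alive=alive)
            for pid in table.plot_ids for iv in build_intervals(table)]


def mortality_rate(n0: int, nm: int, t: float) -> float:
    """Annual mortality rate M (% yr^-1) from the survivor-fraction form.

    Undefined (NaN) when ``n0 == 0`` — a flagged missing value, never 0.
    """
    if t <= 0:
        raise ValueError("interval length t must be positive")
    if not 0 <= nm <= max(n0, 0):
        raise ValueError(f"require 0 <= nm <= n0, got nm={nm}, n0={n0}")
    if n0 == 0:
        return math.nan
    return 100.0 * (1.0 - ((n0 - nm) / n0) ** (1.0 / t))


def recruitment_rate(nr: int, nt: int, t: float) -> float:
    """Annual recruitment rate R (% yr^-1), based on the final stem count.

    Undefined (NaN) when ``nt == 0``.
    """
    if t <= 0:
        raise ValueError("interval length t must be positive")
    if not 0 <= nr <= max(nt, 0):
        raise ValueError(f"require 0 <= nr <= nt, got nr={nr}, nt={nt}")
    if nt == 0:
        return math.nan
    return 100.0 * (1.0 - (1.0 - nr / nt) ** (1.0 / t))


def interval_correction(rate: float, t: float) -> float:
    """Lewis census-interval correction: rate * t^0.08 (identity at t = 1)."""
    if t <= 0:
        raise ValueError("interval length t must be positive")
    return rate * t**LEWIS_EXPONENT


def rates_table(table: CensusTable) -> pd.DataFrame:
    """Per-plot, per-interval demographic rates.

    Columns: plot_id, site, interval, t, n0, nm, nr, nt, M, R, M_corr,
    R_corr (rates in % yr^-1; NaN where undefined).
    """
    site = table.site_of()
    rows = []
    for c in count_all_intervals(table):
        m = mortality_rate(c.n0, c.nm, c.t)
        r = recruitment_rate(c.nr, c.nt, c.t)
        rows.append({
            "plot_id": c.plot_id, "site": site[c.plot_id], "interval": c.interval,
            "t": c.t, "n0": c.n0, "nm": c.nm, "nr": c.nr, "nt": c.nt,
            "M": m, "R": r,
            "M_corr": interval_correction(m, c.t),
            "R_corr": interval_correction(r, c.t),
        })
    return pd.DataFrame(rows)


def site_rates(per_plot: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Per-site, per-interval summaries of corrected rates.

    Default: arithmetic mean and sample SD of per-plot corrected rates
    (plots with undefined rates excluded, with a logged count; a single
    valid plot gives SD = NaN).  ``pooled=True`` instead sums counts across
    plots within a site before applying the rate formulas.
    """
    if pooled:
        agg = (per_plot.groupby(["site", "interval"], as_index=False)
               .agg(t=("t", "first"), n0=("n0", "sum"), nm=("nm", "sum"),
                    nr=("nr", "sum"), nt=("nt", "sum")))
        agg["M_corr"] = [interval_correction(mortality_rate(r.n0, r.nm, r.t), r.t)
                         for r in agg.itertuples()]
        agg["R_corr"] = [interval_correction(recruitment_rate(r.nr, r.nt, r.t), r.t)
                         for r in agg.itertuples()]
        return agg

    n_missing = int(per_plot[["M_corr", "R_corr"]].isna().any(axis=1).sum())
    if n_missing:
        logger.info("site_rates: %d plot-interval(s) with undefined rates excluded",
                    n_missing)
    out = (per_plot.groupby(["site", "interval"], as_index=False)
           .agg(t=("t", "first"),
                n_plots=("plot_id", "count"),
                M_corr_mean=("M_corr", "mean"), M_corr_sd=("M_corr", "std"),
                R_corr_mean=("R_corr", "mean"), R_corr_sd=("R_corr", "std")))
    return out
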