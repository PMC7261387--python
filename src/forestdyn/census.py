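"""Multi-census stem tables: data model, validation, readers/writers.

The substrate of the whole pipeline is a long-format census table — one row
per tree per census — plus a plot table assigning each plot an area and a
fire stratum (FF = burned in 2010, NF = unburned), and an optional drought
index series.  Everything downstream (demographic rates, biomass fluxes,
repeated-measures models) consumes the validated :class:`CensusTable`.

Conventions
-----------
* Time is decimal years; census intervals are consecutive census-year pairs
  and the interval length ``t`` is their difference.
* Recruits are not a stored status: a recruit is a tree whose first alive
  record is the end census of an interval.
* A tree absent from one census but recorded alive on both sides is treated
  as alive (interpolated) for counting; the gap is flagged in diagnostics.
* One row per tree: multi-stemmed individuals must be pre-merged upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_VALUES",
    "CENSUS_COLUMNS",
    "PLOT_COLUMNS",
    "DROUGHT_COLUMNS",
    "MIN_DBH_CM",
    "CensusValidationError",
    "StemObservation",
    "PlotInfo",
    "CensusTable",
    "Interval",
    "read_census",
    "write_census",
    "read_drought",
    "write_drought",
    "build_intervals",
    "alive_matrix",
]

logger = logging.getLogger(__name__)

#: Minimum diameter at breast height for inclusion in the census (cm).
MIN_DBH_CM = 5.0

STATUS_VALUES = ("alive", "dead", "not_recorded")

CENSUS_COLUMNS = [
    "plot_id",
    "tree_id",
    "species",
    "census_year",
    "dbh_cm",
    "height_m",
    "status",
]
PLOT_COLUMNS = ["plot_id", "area_m2", "site", "sector"]
DROUGHT_COLUMNS = ["year", "index_value"]


class CensusValidationError(ValueError):
    """Raised when a census table violates a structural invariant.

    Carries row-level diagnostics in :attr:`details` (list of strings).
    """

    def __init__(self, message: str, details: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.details = list(details)


@dataclass(frozen=True)
class StemObservation:
    """One tree at one census — the atomic census record."""

    tree_id: str
    plot_id: str
    species: str
    census_year: float
    dbh: float | None  # cm
    height: float | None  # m
    status: str  # alive | dead | not_recorded


@dataclass(frozen=True)
class PlotInfo:
    """Static plot metadata: area, fire stratum, topographic sector."""

    plot_id: str
    area_m2: float
    site: str  # FF (burned 2010) or NF (unburned)
    sector: str = ""

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 1e4


@dataclass
class CensusTable:
    """Validated collection of stem observations plus plot metadata.

    ``obs`` is a long-format DataFrame with columns :data:`CENSUS_COLUMNS`;
    ``plots`` has columns :data:`PLOT_COLUMNS`.  ``census_years`` is the
    strictly increasing list of decimal census years.
    """

    obs: pd.DataFrame
    plots: pd.DataFrame
    census_years: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.census_years:
            self.census_years = sorted(self.obs["census_year"].unique().tolist())
        validate_census(self.obs, self.plots, self.census_years)

    # -- convenience accessors -------------------------------------------------

    def plot_info(self, plot_id: str) -> PlotInfo:
        row = self.plots.loc[self.plots["plot_id"] == plot_id]
        if row.empty:
            raise KeyError(f"unknown plot_id: {plot_id!r}")
        r = row.iloc[0]
        return PlotInfo(str(r["plot_id"]), float(r["area_m2"]), str(r["site"]),
                        str(r.get("sector", "")))

    @property
    def plot_ids(self) -> list[str]:
        return self.plots["plot_id"].astype(str).tolist()

    def site_of(self) -> dict[str, str]:
        return dict(zip(self.plots["plot_id"].astype(str), self.plots["site"]))

    def __eq__(self, other: object) -> bool:  # field-for-field round-trip equality
        if not isinstance(other, CensusTable):
            return NotImplemented
        a = self.obs.sort_values(["plot_id", "tree_id", "census_year"]).reset_index(drop=True)
        b = other.obs.sort_values(["plot_id", "tree_id", "census_year"]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a[CENSUS_COLUMNS], b[CENSUS_COLUMNS],
                                          check_dtype=False, check_exact=False, rtol=1e-9)
            pd.testing.assert_frame_equal(
                self.plots.sort_values("plot_id").reset_index(drop=True)[PLOT_COLUMNS],
                other.plots.sort_values("plot_id").reset_index(drop=True)[PLOT_COLUMNS],
                check_dtype=False, check_exact=False, rtol=1e-9)
        except AssertionError:
            return False
        return self.census_years == other.census_years


@dataclass(frozen=True)
class Interval:
    """One census interval: consecutive census years and the elapsed time."""

    label: str
    start_year: float
    end_year: float

    @property
    def t(self) -> float:
        return self.end_year - self.start_year


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_census(obs: pd.DataFrame, plots: pd.DataFrame,
                    census_years: Sequence[float]) -> None:
    """Check every structural invariant; raise with row-level diagnostics.

    Validation is total: a table either passes every invariant or the error
    lists each offending row.  Nothing is silently dropped.
    """
    details: list[str] = []

    missing = [c for c in CENSUS_COLUMNS if c not in obs.columns]
    if missing:
        raise CensusValidationError(
            f"census table missing required column(s): {', '.join(missing)}")
    missing_p = [c for c in PLOT_COLUMNS if c not in plots.columns and c != "sector"]
    if missing_p:
        raise CensusValidationError(
            f"plot table missing required column(s): {', '.join(missing_p)}")

    years = list(census_years)
    if any(b <= a for a, b in zip(years, years[1:])):
        raise CensusValidationError(f"census years not strictly increasing: {years}")

    bad_status = obs.loc[~obs["status"].isin(STATUS_VALUES)]
    for _, r in bad_status.iterrows():
        details.append(f"tree {r.tree_id} @ {r.census_year}: unknown status {r.status!r}")

    bad_site = plots.loc[~plots["site"].isin(["FF", "NF"])]
    for _, r in bad_site.iterrows():
        details.append(f"plot {r.plot_id}: site must be FF or NF, got {r.site!r}")
    bad_area = plots.loc[~(plots["area_m2"] > 0)]
    for _, r in bad_area.iterrows():
        details.append(f"plot {r.plot_id}: non-positive area {r.area_m2}")

    unknown_plot = obs.loc[~obs["plot_id"].isin(plots["plot_id"])]
    for pid in unknown_plot["plot_id"].unique():
        details.append(f"observations reference unknown plot {pid!r}")
    unknown_year = obs.loc[~obs["census_year"].isin(years)]
    for yr in unknown_year["census_year"].unique():
        details.append(f"observations at {yr} not in census year list {years}")

    dup = obs.duplicated(subset=["tree_id", "census_year"], keep=False)
    if dup.any():
        for (tid, yr), _ in obs.loc[dup].groupby(["tree_id", "census_year"]):
            details.append(f"duplicate observation: tree {tid} @ {yr}")

    alive = obs["status"] == "alive"
    bad_dbh = obs.loc[alive & ~(obs["dbh_cm"] > 0)]
    for _, r in bad_dbh.iterrows():
        details.append(f"tree {r.tree_id} @ {r.census_year}: non-positive dbh {r.dbh_cm}")
    bad_h = obs.loc[alive & obs["height_m"].notna() & ~(obs["height_m"] > 0)]
    for _, r in bad_h.iterrows():
        details.append(f"tree {r.tree_id} @ {r.census_year}: non-positive height {r.height_m}")

    # inclusion criterion: first alive appearance must be at DBH >= 5 cm
    first_alive = (obs.loc[alive].sort_values("census_year")
                   .groupby("tree_id", sort=False).first())
    small = first_alive.loc[first_alive["dbh_cm"] < MIN_DBH_CM]
    for tid, r in small.iterrows():
        details.append(
            f"tree {tid} @ {r.census_year}: dbh {r.dbh_cm} cm violates the "
            f"inclusion criterion (DBH >= {MIN_DBH_CM} cm at first alive record)")

    # a tree never transitions dead -> alive
    srt = obs.sort_values(["tree_id", "census_year"])
    for tid, grp in srt.groupby("tree_id", sort=False):
        seen_dead = False
        for _, r in grp.iterrows():
            if r["status"] == "dead":
                seen_dead = True
            elif r["status"] == "alive" and seen_dead:
                details.append(f"tree {tid}: alive at {r.census_year} after an "
                               f"earlier dead record (dead -> alive transition)")
                break

    if details:
        raise CensusValidationError(
            f"census validation failed with {len(details)} problem(s)", details)


# ---------------------------------------------------------------------------
# readers / writers (delimited text, documented headers)
# ---------------------------------------------------------------------------

def read_census(path: str | Path, plot_path: str | Path) -> CensusTable:
    """Read and validate a census CSV and its plot CSV.

    Expected columns: census — ``plot_id, tree_id, species, census_year,
    dbh_cm, height_m, status``; plots — ``plot_id, area_m2, site, sector``.
    Raises :class:`CensusValidationError` with row-level diagnostics on any
    invariant violation.
    """
    obs = pd.read_csv(path, dtype={"plot_id": str, "tree_id": str, "species": str,
                                   "status": str})
    plots = pd.read_csv(plot_path, dtype={"plot_id": str, "site": str})
    if "sector" not in plots.columns:
        plots["sector"] = ""
    plots["sector"] = plots["sector"].fillna("").astype(str)
    if "census_year" in obs.columns:
        obs["census_year"] = obs["census_year"].astype(float)
    return CensusTable(obs=obs, plots=plots)


def write_census(table: CensusTable, path: str | Path,
                 plot_path: str | Path | None = None) -> None:
    """Write a census table (and optionally its plot table) to CSV.

    Round-trips losslessly: ``read_census(write_census(t)) == t``.  Decimal
    census years are written with full float precision.
    """
    out = table.obs[CENSUS_COLUMNS].sort_values(
        ["plot_id", "tree_id", "census_year"])
    out.to_csv(path, index=False, float_format="%.10g")
    if plot_path is not None:
        table.plots[PLOT_COLUMNS].to_csv(plot_path, index=False, float_format="%.10g")


def read_drought(path: str | Path) -> pd.DataFrame:
    """Read a drought-index series CSV (columns ``year, index_value``)."""
    df = pd.read_csv(path)
    missing = [c for c in DROUGHT_COLUMNS if c not in df.columns]
    if missing:
        raise CensusValidationError(
            f"drought series missing required column(s): {', '.join(missing)}")
    if not df["year"].is_monotonic_increasing or df["year"].duplicated().any():
        raise CensusValidationError("drought series years must be strictly increasing")
    return df


def write_drought(series: pd.DataFrame, path: str | Path) -> None:
    series[DROUGHT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# intervals and effective-alive bookkeeping
# ---------------------------------------------------------------------------

def build_intervals(table: CensusTable | Sequence[float]) -> list[Interval]:
    """Consecutive census-year pairs, labelled I1..I(k-1).

    ``t`` is the decimal-year difference, so the study's 1996/1999/2003/2006/
    2010/2016 design yields t = 3, 4, 3, 4, 6.
    """
    years = (table.census_years if isinstance(table, CensusTable)
             else sorted(table))
    if len(years) < 2:
        raise ValueError("at least two census years are required to form intervals")
    return [Interval(f"I{i + 1}", float(a), float(b))
            for i, (a, b) in enumerate(zip(years, years[1:]))]


def alive_matrix(table: CensusTable) -> pd.DataFrame:
    """Effective alive status per tree per census (trees x census years).

    A tree is *effectively alive* at a census if recorded alive there, or if
    it has alive records both before and after (a recording gap, interpolated
    as alive).  Death is absorbing; permanent disappearance after a last
    alive record counts as death at the next census (standard plot-network
    convention).  The result is a boolean DataFrame indexed by tree_id with
    one column per census year, plus attrs ``gap_filled`` (count of
    interpolated cells) and ``presumed_dead`` (trees with no dead record that
    vanished) for audit logging.
    """
    years = table.census_years
    alive_obs = table.obs.loc[table.obs["status"] == "alive"]
    piv = (alive_obs.assign(v=True)
           .pivot_table(index="tree_id", columns="census_year", values="v",
                        aggfunc="any", fill_value=False)
           .reindex(columns=years, fill_value=False))
    piv = piv.astype(bool)
    if piv.empty:
        out = pd.DataFrame(columns=years, dtype=bool)
        out.attrs["gap_filled"] = 0
        out.attrs["presumed_dead"] = 0
        return out

    arr = piv.to_numpy()
    n, k = arr.shape
    idx = np.arange(k)
    first = np.where(arr.any(axis=1), arr.argmax(axis=1), k)
    last = np.where(arr.any(axis=1), k - 1 - arr[:, ::-1].argmax(axis=1), -1)
    filled = (idx[None, :] >= first[:, None]) & (idx[None, :] <= last[:, None])
    gap_filled = int((filled & ~arr).sum())
    if gap_filled:
        logger.warning("alive_matrix: %d census gap(s) interpolated as alive", gap_filled)

    # trees that vanish with no explicit dead record
    dead_obs = table.obs.loc[table.obs["status"] == "dead", "tree_id"].unique()
    vanished = [tid for tid, l in zip(piv.index, last)
                if l < k - 1 and tid not in set(dead_obs)]
    if vanished:
        logger.warning("alive_matrix: %d tree(s) vanished without a dead record; "
                       "counted as deaths", len(vanished))

    out = pd.DataFrame(filled, index=piv.index, columns=years)
    out.attrs["gap_filled"] = gap_filled
    out.attrs["presumed_dead"] = len(vanished)
    return out
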