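"""Wood-density assignment and per-tree aboveground biomass.

Aboveground biomass (AGB, kg) of a live stem is estimated from the tropical
moist-forest allometry

    AGB = 0.0673 * (WD * H * DBH^2)^0.976

with WD the species wood density (g cm^-3), H total height (m) and DBH the
diameter at 1.3 m (cm).  Carbon is taken as a fixed fraction of biomass,
C = 0.47 * AGB.

Wood density is a species-level trait measured directly for the species that
dominate the stand; the remaining species receive the stem-abundance-weighted
mean of the measured species (weights taken from the most recent census), and
are flagged as fallback values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .census import CensusTable

__all__ = [
    "AGB_COEF",
    "AGB_EXP",
    "CARBON_FRACTION",
    "SIZE_CLASS_BOUNDS",
    "compute_agb",
    "carbon_from_agb",
    "classify_size",
    "assign_wood_density",
    "tree_biomass_table",
]

AGB_COEF = 0.0673
AGB_EXP = 0.976
#: Carbon content as a fraction of aboveground biomass.
CARBON_FRACTION = 0.47

#: Size-class partition of the DBH axis (cm): S = [5, 10], M = (10, 35], L > 35.
SIZE_CLASS_BOUNDS = (10.0, 35.0)


def compute_agb(dbh, height, wd):
    """Aboveground biomass (kg) from DBH (cm), height (m) and wood density.

    Vectorized over array inputs.  All inputs must be strictly positive.

    >>> round(compute_agb(1.0, 1.0, 1.0), 4)
    0.0673
    """
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    wd = np.asarray(wd, dtype=float)
    if np.any(dbh <= 0) or np.any(height <= 0) or np.any(wd <= 0):
        raise ValueError("dbh, height and wood density must all be positive")
    out = AGB_COEF * (wd * height * dbh**2) ** AGB_EXP
    return float(out) if out.ndim == 0 else out


def carbon_from_agb(agb):
    """Carbon stock (same units as ``agb``): a fixed 0.47 fraction of biomass."""
    return CARBON_FRACTION * np.asarray(agb, dtype=float)


def classify_size(dbh):
    """Size class from DBH (cm): 'S' in [5, 10], 'M' in (10, 35], 'L' above 35.

    The medium class is reported in the field as 10.1–35 cm at 0.1 cm
    measurement resolution; the boundaries are implemented half-open so the
    classes partition [5, inf) with no gaps or overlaps.  DBH below the 5 cm
    inclusion threshold is an error.
    """
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr < 5.0):
        raise ValueError("size classes are defined only for DBH >= 5 cm")
    lo, hi = SIZE_CLASS_BOUNDS
    out = np.where(arr <= lo, "S", np.where(arr <= hi, "M", "L"))
    return str(out) if out.ndim == 0 else out


def assign_wood_density(table: CensusTable, measured: pd.DataFrame,
                        weighted: bool = True) -> pd.DataFrame:
    """Complete the wood-density table over every species in the census.

    ``measured`` has columns ``species, wd_g_cm3`` (and optionally
    ``measured``).  Species absent from it receive the mean wood density of
    the measured species, weighted by their stem abundance in the latest
    census (``weighted=False`` switches to the unweighted mean).  Fallback
    rows are flagged ``measured = 0``.

    Raises ``ValueError`` on an empty measured table or any density outside
    (0, 1.5) g cm^-3.
    """
    if measured is None or len(measured) == 0:
        raise ValueError("measured wood-density table is empty")
    wd = measured.copy()
    if "wd_g_cm3" not in wd.columns:
        raise ValueError("wood-density table requires a 'wd_g_cm3' column")
    bad = wd.loc[~((wd["wd_g_cm3"] > 0) & (wd["wd_g_cm3"] < 1.5))]
    if not bad.empty:
        raise ValueError(
            "wood density outside (0, 1.5) g cm^-3 for species: "
            + ", ".join(bad["species"].astype(str)))

    latest = max(table.census_years)
    counts = (table.obs.loc[(table.obs["census_year"] == latest)
                            & (table.obs["status"] == "alive")]
              .groupby("species").size())

    meas_map = dict(zip(wd["species"], wd["wd_g_cm3"]))
    if weighted:
        w = counts.reindex(meas_map.keys()).fillna(0.0)
        if w.sum() > 0:
            fallback = float(np.average(list(meas_map.values()), weights=w.to_numpy()))
        else:  # none of the measured species present in the latest census
            fallback = float(np.mean(list(meas_map.values())))
    else:
        fallback = float(np.mean(list(meas_map.values())))

    all_species = sorted(table.obs["species"].astype(str).unique())
    rows = []
    for sp in all_species:
        if sp in meas_map:
            rows.append({"species": sp, "wd_g_cm3": float(meas_map[sp]), "measured": 1})
        else:
            rows.append({"species": sp, "wd_g_cm3": fallback, "measured": 0})
    # keep measured species not present in the census, too (harmless, auditable)
    for sp, v in meas_map.items():
        if sp not in all_species:
            rows.append({"species": sp, "wd_g_cm3": float(v), "measured": 1})
    return pd.DataFrame(rows)


def tree_biomass_table(table: CensusTable, wd_table: pd.DataFrame) -> pd.DataFrame:
    """Per-tree, per-census AGB and carbon for every alive record.

    Returns a DataFrame with columns ``tree_id, plot_id, census_year, dbh_cm,
    height_m, wd_g_cm3, agb_kg, carbon_kg, size_class``.  Every alive record
    must have a positive DBH and height; species missing from ``wd_table``
    are an error (use :func:`assign_wood_density` first).
    """
    alive = table.obs.loc[table.obs["status"] == "alive"].copy()
    if alive.empty:
        return pd.DataFrame(columns=["tree_id", "plot_id", "census_year", "dbh_cm",
                                     "height_m", "wd_g_cm3", "agb_kg", "carbon_kg",
                                     "size_class"])
    wd_map = dict(zip(wd_table["species"], wd_table["wd_g_cm3"]))
    missing = sorted(set(alive["species"]) - set(wd_map))
    if missing:
        raise ValueError("no wood density for species: " + ", ".join(missing))
    if alive["height_m"].isna().any():
        bad = alive.loc[alive["height_m"].isna(), "tree_id"].unique()
        raise ValueError("alive records missing height for tree(s): "
                         + ", ".join(map(str, bad[:10])))
    alive["wd_g_cm3"] = alive["species"].map(wd_map).astype(float)
    alive["agb_kg"] = compute_agb(alive["dbh_cm"], alive["height_m"], alive["wd_g_cm3"])
    alive["carbon_kg"] = carbon_from_agb(alive["agb_kg"])
    alive["size_class"] = classify_size(alive["dbh_cm"])
    cols = ["tree_id", "plot_id", "census_year", "dbh_cm", "height_m",
            "wd_g_cm3", "agb_kg", "carbon_kg", "size_class"]
    return alive[cols].reset_index(drop=True)
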