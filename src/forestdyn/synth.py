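"""Synthetic census generator: a stochastic individual-based stand simulator.

Emulates the monitoring design of a fire- and drought-affected tropical
valley forest: 18 permanent plots of 600 m^2 (8 in the burned FF stratum,
10 unburned NF), six censuses (1996, 1999, 2003, 2006, 2010, 2016), stems
included at DBH >= 5 cm, background annual mortality of a few percent,
drought episodes that elevate mortality — more strongly for large stems —
and a single fire pulse in 2010 hitting FF plots only.

The simulator steps annually between censuses (so the census-interval
correction has real bias to correct): each year every live stem dies with
probability 1 - exp(-h), where the hazard h multiplies a base hazard by a
drought factor exp(effect * drought_deficit) (boosted for large stems), and
by a fire factor in the fire year on FF plots; survivors add a stochastic
DBH increment; recruits arrive as a Poisson stream and become visible to
the census once DBH >= 5 cm.  Heights follow a saturating DBH-height curve
with per-tree lognormal noise.  Observations are emitted only at census
years; a stem's first census after death carries an explicit ``dead``
record.  All randomness flows from one seeded generator, so outputs are
byte-identical per (config, seed).

Ground truth (hazards applied, realized death and recruitment events) is
returned alongside the census table for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .census import CensusTable, write_census, write_drought

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "generate_drought_series",
    "simulate_census",
    "make_fixture",
    "PRESETS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All stochastic parameters of the stand simulator.

    Defaults reproduce the study design: 8 FF + 10 NF plots of 600 m^2,
    censuses 1996-2016, background annual mortality hazard ~3.5 % (within
    the 3-5 %/yr background range typical of these hyperdynamic stands),
    and recruitment roughly balancing mortality.
    """

    n_plots_ff: int = 8
    n_plots_nf: int = 10
    plot_area_m2: float = 600.0
    census_years: tuple = (1996.0, 1999.0, 2003.0, 2006.0, 2010.0, 2016.0)
    initial_density: float = 1600.0  # stems ha^-1 at DBH >= 5 cm
    # initial DBH: 5 cm + Weibull(shape, scale) — right-skewed, truncated at 5
    dbh_shape: float = 1.0
    dbh_scale: float = 9.0
    growth_mean: float = 0.25  # cm yr^-1
    growth_sd: float = 0.12
    base_hazard: float = 0.0357  # annual mortality hazard; p = 1 - exp(-h)
    # background hazard multipliers per size class (S, M, L): small stems die
    # most, large stems rarely — except under drought (drought_l_factor)
    size_hazard: tuple = (1.2, 0.9, 0.25)
    drought_effect: float = 0.18  # hazard log-multiplier per unit excess deficit
    drought_threshold: float = 1.0  # drought index above -threshold is benign
    drought_l_factor: float = 2.5  # extra drought sensitivity of L stems (>35 cm)
    fire_year: float | None = 2010.0
    fire_hazard_boost: float = 4.0  # hazard multiplier, FF plots, fire year only
    recruitment_rate: float = 60.0  # stems ha^-1 yr^-1 crossing 5 cm
    recruit_dbh_scale: float = 0.6  # recruits enter at 5 + Exp(scale) cm
    height_max: float = 26.0  # m, asymptote of the saturating DBH-height curve
    height_k: float = 18.0  # cm, half-saturation DBH
    height_sd: float = 0.12  # lognormal noise (log scale), fixed per tree
    n_species: int = 30
    wd_mean: float = 0.62  # g cm^-3
    wd_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        years = list(self.census_years)
        if len(years) < 2 or any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("census_years must be >= 2 strictly increasing years")
        for name in ("plot_area_m2", "initial_density", "recruitment_rate",
                     "base_hazard", "growth_sd", "dbh_shape", "dbh_scale",
                     "height_max", "height_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.base_hazard > 5:
            raise ValueError("base_hazard is an annual hazard; must be modest")
        if self.n_plots_ff < 0 or self.n_plots_nf < 0 or \
                self.n_plots_ff + self.n_plots_nf == 0:
            raise ValueError("need at least one plot")

    @property
    def area_ha(self) -> float:
        return self.plot_area_m2 / 1e4

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        """Load simulator parameters from a YAML mapping of config fields."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("census_years", "size_hazard"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedTruth:
    """Ground truth of one simulation run.

    ``events``: realized per-tree events (columns tree_id, plot_id, event in
    {recruit_entry, death}, year).  ``hazards``: mean applied annual hazard
    per (site, year, size_class).  Reconciles exactly with the emitted
    census table.
    """

    events: pd.DataFrame
    hazards: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def generate_drought_series(years, episodes=(), seed: int = 0,
                            episode_depth: float = 2.5, trend: float = 0.0,
                            phi: float = 0.6, sigma: float = 0.6) -> pd.DataFrame:
    """Autocorrelated scPDSI-like drought index (negative = drier).

    An AR(1) background (coefficient ``phi``, innovation SD ``sigma``) plus
    an optional linear ``trend`` per year and negative excursions of
    ``episode_depth`` at each episode year.  Deterministic given ``seed``.
    """
    years = np.asarray(sorted(years), dtype=float)
    for ep in episodes:
        if not years.min() <= ep <= years.max():
            raise ValueError(f"episode year {ep} outside series range "
                             f"[{years.min()}, {years.max()}]")
    rng = np.random.default_rng(seed)
    n = len(years)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / np.sqrt(1 - phi**2))
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0.0, sigma)
    x += trend * (years - years[0])
    ep_set = set(float(e) for e in episodes)
    x -= episode_depth * np.isin(years, list(ep_set))
    return pd.DataFrame({"year": years, "index_value": x})


def _heights(dbh: np.ndarray, eps: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    return cfg.height_max * dbh / (cfg.height_k + dbh) * np.exp(eps)


def simulate_census(config: SimulationConfig,
                    drought: pd.DataFrame | None = None
                    ) -> tuple[CensusTable, SimulatedTruth]:
    """Run the annual birth-death-growth process and emit censuses.

    ``drought`` is a (year, index_value) series covering the simulated
    years; omitted, the stand sees no drought forcing.  The returned table
    passes every census-data invariant; the truth object carries the event
    log and the mean hazards actually applied.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    years = [float(y) for y in cfg.census_years]
    y0, y1 = years[0], years[-1]
    all_years = np.arange(y0, y1 + 1)

    didx = {}
    if drought is not None:
        didx = dict(zip(drought["year"].astype(float), drought["index_value"]))

    species = np.array([f"sp{i:02d}" for i in range(cfg.n_species)])
    # skewed relative abundance, so a measured-species subset can cover ~80 %
    ab = rng.dirichlet(np.full(cfg.n_species, 0.35))
    wd = np.clip(rng.normal(cfg.wd_mean, cfg.wd_sd, cfg.n_species), 0.2, 1.2)

    plot_rows = []
    sites = ["FF"] * cfg.n_plots_ff + ["NF"] * cfg.n_plots_nf
    for i, site in enumerate(sites):
        plot_rows.append({"plot_id": f"P{i + 1:02d}", "area_m2": cfg.plot_area_m2,
                          "site": site, "sector": ("low", "middle", "top")[i % 3]})
    plots = pd.DataFrame(plot_rows)

    obs_rows: list[dict] = []
    event_rows: list[dict] = []
    hazard_rows: list[dict] = []

    for prow in plot_rows:
        pid, site = prow["plot_id"], prow["site"]
        n_init = rng.poisson(cfg.initial_density * cfg.area_ha)
        dbh = 5.0 + cfg.dbh_scale * rng.weibull(cfg.dbh_shape, n_init)
        sp = rng.choice(cfg.n_species, size=n_init, p=ab)
        heps = rng.normal(0.0, cfg.height_sd, n_init)
        alive = np.ones(n_init, dtype=bool)
        visible = np.ones(n_init, dtype=bool)  # initial stand all >= 5 cm
        death_reported = np.zeros(n_init, dtype=bool)
        tid = [f"{pid}-T{j + 1:04d}" for j in range(n_init)]
        counter = n_init

        def record_census(year: float) -> None:
            h = _heights(dbh, heps, cfg)
            for j in np.nonzero(alive)[0]:
                if not visible[j] and dbh[j] >= 5.0:
                    visible[j] = True
                if visible[j]:
                    obs_rows.append({
                        "plot_id": pid, "tree_id": tid[j],
                        "species": species[sp[j]], "census_year": year,
                        "dbh_cm": round(max(dbh[j], 5.0), 2),
                        "height_m": round(float(h[j]), 2), "status": "alive"})
            for j in np.nonzero(~alive & visible & ~death_reported)[0]:
                obs_rows.append({
                    "plot_id": pid, "tree_id": tid[j], "species": species[sp[j]],
                    "census_year": year, "dbh_cm": np.nan, "height_m": np.nan,
                    "status": "dead"})
                death_reported[j] = True

        record_census(y0)
        for y in all_years[:-1]:
            y_next = float(y + 1)
            deficit = max(0.0, -didx.get(y_next, 0.0) - cfg.drought_threshold)
            size_mult = np.where(dbh > 35.0, cfg.drought_l_factor, 1.0)
            s_h, m_h, l_h = cfg.size_hazard
            bg_mult = np.where(dbh <= 10.0, s_h, np.where(dbh <= 35.0, m_h, l_h))
            hazard = (cfg.base_hazard * bg_mult
                      * np.exp(cfg.drought_effect * deficit * size_mult))
            if (cfg.fire_year is not None and site == "FF"
                    and float(y) == float(cfg.fire_year)):
                hazard = hazard * cfg.fire_hazard_boost
            p_die = 1.0 - np.exp(-hazard)
            dies = alive & (rng.random(len(dbh)) < p_die)
            for j in np.nonzero(dies)[0]:
                event_rows.append({"tree_id": tid[j], "plot_id": pid,
                                   "event": "death", "year": y_next})
            alive &= ~dies
            if alive.any():
                for cls, mask in (("SM", alive & (dbh <= 35.0)),
                                  ("L", alive & (dbh > 35.0))):
                    if mask.any():
                        hazard_rows.append({
                            "site": site, "year": y_next, "size_class": cls,
                            "mean_hazard": float(hazard[mask].mean())})
            grow = rng.normal(cfg.growth_mean, cfg.growth_sd, len(dbh))
            dbh = np.where(alive, np.maximum(dbh + grow, 1.0), dbh)
            n_rec = rng.poisson(cfg.recruitment_rate * cfg.area_ha)
            if n_rec:
                rdbh = 5.0 + rng.exponential(cfg.recruit_dbh_scale, n_rec)
                rsp = rng.choice(cfg.n_species, size=n_rec, p=ab)
                rheps = rng.normal(0.0, cfg.height_sd, n_rec)
                rtid = [f"{pid}-T{counter + j + 1:04d}" for j in range(n_rec)]
                counter += n_rec
                for t, yy in zip(rtid, [y_next] * n_rec):
                    event_rows.append({"tree_id": t, "plot_id": pid,
                                       "event": "recruit_entry", "year": yy})
                dbh = np.concatenate([dbh, rdbh])
                sp = np.concatenate([sp, rsp])
                heps = np.concatenate([heps, rheps])
                alive = np.concatenate([alive, np.ones(n_rec, dtype=bool)])
                visible = np.concatenate([visible, np.zeros(n_rec, dtype=bool)])
                death_reported = np.concatenate(
                    [death_reported, np.zeros(n_rec, dtype=bool)])
                tid.extend(rtid)
            if y_next in years:
                record_census(y_next)

    obs = pd.DataFrame(obs_rows, columns=["plot_id", "tree_id", "species",
                                          "census_year", "dbh_cm", "height_m",
                                          "status"])
    table = CensusTable(obs=obs, plots=plots, census_years=years)
    truth = SimulatedTruth(
        events=pd.DataFrame(event_rows, columns=["tree_id", "plot_id",
                                                 "event", "year"]),
        hazards=pd.DataFrame(hazard_rows, columns=["site", "year", "size_class",
                                                   "mean_hazard"]),
        config=cfg)
    truth.wood_density = pd.DataFrame({"species": species, "wd_g_cm3": wd})
    truth.abundance = pd.DataFrame({"species": species, "p": ab})
    return table, truth


# ---------------------------------------------------------------------------
# fixture presets
# ---------------------------------------------------------------------------

_STUDY_EPISODES = (2002.0, 2005.0, 2010.0, 2016.0)

PRESETS: dict[str, dict] = {
    # <= 5 plots, 2 censuses; runs end-to-end in seconds
    "tiny": {
        "config": SimulationConfig(
            n_plots_ff=1, n_plots_nf=2, census_years=(2000.0, 2003.0),
            initial_density=500.0, n_species=8, fire_year=None),
        "episodes": (), "trend": 0.0, "depth": 0.0,
    },
    # the full study design: 18 plots, 6 censuses, droughts + 2010 fire
    "paper_like": {
        "config": SimulationConfig(),
        "episodes": _STUDY_EPISODES, "trend": -0.08, "depth": 2.5,
    },
    # drought-dominated run, no fire: deepening droughts drive large-stem
    # mortality up and net biomass change down over time
    "drought_pulse": {
        "config": SimulationConfig(
            n_plots_ff=0, n_plots_nf=8, fire_year=None,
            drought_effect=0.30, drought_l_factor=3.0),
        "episodes": _STUDY_EPISODES, "trend": -0.15, "depth": 3.5,
    },
    # fire-only contrast: no drought forcing, strong 2010 pulse on FF plots
    "fire_contrast": {
        "config": SimulationConfig(
            n_plots_ff=5, n_plots_nf=5, drought_effect=0.0,
            fire_hazard_boost=5.0),
        "episodes": (), "trend": 0.0, "depth": 0.0,
    },
}


def preset_run(name: str, seed: int):
    """Simulate one preset: returns (CensusTable, SimulatedTruth, drought)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from "
                       + ", ".join(sorted(PRESETS)))
    p = PRESETS[name]
    cfg = replace(p["config"], seed=int(seed) % (2**31 - 1))
    years = np.arange(cfg.census_years[0], cfg.census_years[-1] + 1)
    drought = generate_drought_series(
        years, episodes=p["episodes"], seed=cfg.seed + 7919,
        episode_depth=p["depth"], trend=p["trend"])
    table, truth = simulate_census(cfg, drought)
    return table, truth, drought


def make_fixture(preset_name: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a preset's census/plot/wood-density/drought CSVs to ``outdir``.

    The wood-density file covers the measured species only — those jointly
    accounting for ~80 % of stems in the final census — so the fallback
    (abundance-weighted mean) path is exercised downstream.  Deterministic
    per (preset, seed); returns the written paths.
    """
    table, truth, drought = preset_run(preset_name, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.csv"
             for k in ("census", "plots", "wood_density", "drought")}
    write_census(table, paths["census"], paths["plots"])

    last = max(table.census_years)
    counts = (table.obs.loc[(table.obs["census_year"] == last)
                            & (table.obs["status"] == "alive")]
              .groupby("species").size().sort_values(ascending=False))
    cum = counts.cumsum() / counts.sum()
    n_measured = max(1, int((cum < 0.80).sum()) + 1)
    measured_sp = counts.index[:n_measured]
    wdt = truth.wood_density
    wd_out = wdt.loc[wdt["species"].isin(measured_sp)].copy()
    wd_out["measured"] = 1
    wd_out.sort_values("species").to_csv(paths["wood_density"], index=False,
                                         float_format="%.10g")
    write_drought(drought, paths["drought"])
    return paths
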