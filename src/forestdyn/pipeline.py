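"""End-to-end orchestration: validate -> wood density -> biomass -> rates ->
fluxes -> models -> report.

`run_pipeline` drives the whole analysis from four CSV inputs (census,
plots, wood density, optional drought series) to a deterministic result
bundle on disk: per-census stock table, per-interval rates and flux tables,
site x interval summaries, GEE model summaries with Bonferroni letter
displays, and a JSON manifest with content hashes of every output.
Identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .allometry import assign_wood_density
from .census import CensusTable, read_census, read_drought
from .dynamics import rates_table, site_rates
from .flux import effective_biomass, flux_table, stock_table
from .models import (ModelSpec, bonferroni_contrasts, compact_letter_display,
                     fit_longitudinal)

__all__ = ["RunConfig", "run_pipeline", "summarize_sites"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run (paths, conventions, model settings)."""

    census_path: str
    plot_path: str
    wood_density_path: str
    drought_path: str | None = None
    output_dir: str = "forestdyn_out"
    aggregation: str = "per_plot"  # per_plot | pooled
    wd_weighted: bool = True
    truncate_negative_growth: bool = False
    correlation: str = "exchangeable"
    cov_type: str = "bias_reduced"
    alpha: float = 0.05
    fit_models: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggregation not in ("per_plot", "pooled"):
            raise ValueError("aggregation must be 'per_plot' or 'pooled'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a YAML mapping of RunConfig fields."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def summarize_sites(rates: pd.DataFrame, fluxes: pd.DataFrame) -> pd.DataFrame:
    """Site x interval report: mean +/- SD of rates and fluxes, plus trends.

    Combines the per-plot rates and flux tables into one summary row per
    (site, interval) with mean and sample SD of corrected mortality and
    recruitment, productivity, net biomass change and mortality flux (total
    and by size class), and appends a per-site least-squares trend slope of
    each mean quantity against the interval midpoint year as a descriptive
    diagnostic (column ``trend_slope_per_yr`` on rows labelled
    ``interval == 'trend'``).
    """
    merged = rates.merge(fluxes, on=["plot_id", "site", "interval", "t"])
    num_cols = ["M_corr", "R_corr", "pb_mg_ha_yr", "nbc_mg_ha_yr",
                "mort_flux_total_mg_ha_yr", "mort_flux_S_mg_ha_yr",
                "mort_flux_M_mg_ha_yr", "mort_flux_L_mg_ha_yr"]
    agg = {f"{c}_mean": (c, "mean") for c in num_cols}
    agg.update({f"{c}_sd": (c, "std") for c in num_cols})
    out = (merged.groupby(["site", "interval"], as_index=False)
           .agg(n_plots=("plot_id", "nunique"), t=("t", "first"), **agg))

    # descriptive trend: slope of each site's mean quantity vs interval midpoint
    import numpy as np
    order = sorted(out["interval"].unique())
    trend_rows = []
    for site, grp in out.groupby("site"):
        grp = grp.set_index("interval").loc[[i for i in order
                                             if i in grp["interval"].values]]
        mid = grp["t"].cumsum() - grp["t"] / 2  # midpoints relative to first census
        row = {"site": site, "interval": "trend", "n_plots": int(grp["n_plots"].max()),
               "t": float("nan")}
        for c in num_cols:
            y = grp[f"{c}_mean"].to_numpy(dtype=float)
            ok = np.isfinite(y)
            row[f"{c}_mean"] = (float(np.polyfit(mid[ok], y[ok], 1)[0])
                                if ok.sum() >= 2 else float("nan"))
            row[f"{c}_sd"] = float("nan")
        trend_rows.append(row)
    return pd.concat([out, pd.DataFrame(trend_rows)], ignore_index=True)


def _model_stage(table: CensusTable, stocks: pd.DataFrame, rates: pd.DataFrame,
                 cfg: RunConfig) -> dict[str, dict]:
    """Fit the three longitudinal models and build letter displays."""
    out: dict[str, dict] = {}
    frames = {
        "AGB": stocks.rename(columns={"agb_mg_ha": "value"})[
            ["plot_id", "site", "census_year", "value"]],
        "NS": stocks.rename(columns={"n_stems": "value"})[
            ["plot_id", "site", "census_year", "value"]],
        "M": rates.rename(columns={"M_corr": "value", "interval": "census_year"})[
            ["plot_id", "site", "census_year", "value"]],
    }
    for resp, df in frames.items():
        spec = ModelSpec(response=resp, correlation=cfg.correlation,
                         cov_type=cfg.cov_type, alpha=cfg.alpha)
        try:
            res = fit_longitudinal(df, spec)
            contrasts = bonferroni_contrasts(res)
            levels = sorted(df["census_year"].unique())
            letters = compact_letter_display(levels, contrasts, alpha=cfg.alpha)
            out[resp] = {"result": res, "contrasts": contrasts,
                         "letters": letters, "error": None}
        except Exception as exc:  # surfaced in the report, never silent
            logger.warning("model stage failed for %s: %s", resp, exc)
            out[resp] = {"result": None, "contrasts": None, "letters": None,
                         "error": str(exc)}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; write the result bundle; return it in memory.

    Any stage error aborts with the stage name attached; partially written
    outputs are removed.  Returns a dict with the tables, model results and
    manifest.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read/validate"
    try:
        table = read_census(config.census_path, config.plot_path)
        measured = pd.read_csv(config.wood_density_path)
        drought = (read_drought(config.drought_path)
                   if config.drought_path else None)

        stage = "wood density"
        wd = assign_wood_density(table, measured, weighted=config.wd_weighted)

        stage = "biomass"
        biomass = effective_biomass(table, wd)

        stage = "dynamics"
        rates = rates_table(table)
        sites = site_rates(rates, pooled=(config.aggregation == "pooled"))

        stage = "flux"
        stocks = stock_table(table, biomass)
        fluxes = flux_table(
            table, biomass,
            truncate_negative_growth=config.truncate_negative_growth)

        stage = "summaries"
        summary = summarize_sites(rates, fluxes)

        stage = "models"
        models = _model_stage(table, stocks, rates, config) if config.fit_models \
            else {}

        stage = "write"
        tables = {"stocks.csv": stocks, "rates.csv": rates,
                  "site_rates.csv": sites, "fluxes.csv": fluxes,
                  "site_summary.csv": summary}
        if drought is not None:
            tables["drought.csv"] = drought
        for name, df in tables.items():
            p = outdir / name
            df.to_csv(p, index=False, float_format="%.10g")
            written.append(p)
        model_lines = []
        for resp, m in models.items():
            model_lines.append(f"== {resp} ==")
            if m["error"]:
                model_lines.append(f"  NOT FITTED: {m['error']}")
                continue
            if not m["result"].converged:
                model_lines.append("  WARNING: fit flagged non-converged")
            wt = m["result"].wald_terms
            for r in wt.itertuples(index=False):
                vals = [f"{v:.4g}" if isinstance(v, float) else str(v)
                        for v in r]
                model_lines.append("  " + "  ".join(vals))
            model_lines.append("  letters: " + "  ".join(
                f"{lv}:{m['letters'][lv]}" for lv in sorted(m["letters"])))
            cpath = outdir / f"contrasts_{resp}.csv"
            m["contrasts"].to_csv(cpath, index=False, float_format="%.10g")
            written.append(cpath)
        mpath = outdir / "models.txt"
        mpath.write_text("\n".join(model_lines) + "\n")
        written.append(mpath)

        manifest = {
            "forestdyn_version": __version__,
            "config": {k: v for k, v in vars(config).items()},
            "n_observations": int(len(table.obs)),
            "n_plots": int(len(table.plots)),
            "census_years": table.census_years,
            "gap_filled": int(biomass["interpolated"].sum()),
            "outputs": {},
        }
        for p in written:
            manifest["outputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        man_path = outdir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written.append(man_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {"table": table, "wood_density": wd, "biomass": biomass,
            "rates": rates, "site_rates": sites, "stocks": stocks,
            "fluxes": fluxes, "summary": summary, "models": models,
            "manifest": manifest}
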