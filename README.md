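# forestdyn

Analysis toolkit for long-term permanent-plot forest censuses, built around
the questions a 20-year monitoring record of a drought- and fire-affected
tropical valley forest raises: how do stem density and aboveground biomass
change over decades, and how do mortality, recruitment and biomass fluxes
respond to drought episodes and a fire pulse?

It is a library for ecologists working with long-format stem census tables
(one row per tree per census) from permanent plot networks, plus a thin CLI
(`forestdyn validate|simulate|run`) for file-based workflows.

## What it computes

**Per-tree biomass.** Aboveground biomass of a live stem from the
moist-tropical allometry

```
AGB (kg) = 0.0673 · (WD · H · DBH²)^0.976
```

with wood density WD (g cm⁻³), height H (m) and diameter at breast height
DBH (cm); carbon = 0.47 · AGB. Species without a measured wood density
receive the stem-abundance-weighted mean of measured species. Stems are
classed small (5–10 cm), medium (10.1–35 cm) or large (> 35 cm).

**Stem turnover.** For each plot and census interval (length *t* years),
annual mortality and recruitment from the survivor-fraction forms

```
M = 100 · [1 − ((N₀ − N_m)/N₀)^(1/t)]      R = 100 · [1 − (1 − N_r/N_t)^(1/t)]
```

with the census-interval correction λ_corr = λ · t^0.08 applied to both, so
rates from 3-, 4- and 6-year intervals are comparable.

**Biomass fluxes.** Per plot-interval, in Mg ha⁻¹ yr⁻¹: productivity
PB (recruit biomass + survivor growth), net biomass change
NBC = (stock_end − stock_start)/t, and mortality flux (biomass of dying
stems at their last live census, total and by size class). The valuation
conventions make NBC = PB − mortality flux an exact identity.

**Inference.** Plot-level responses (AGB, stem count NS, mortality rate)
are modelled by GEE — population-averaged GLMs with plots as
repeated-measures clusters (Gamma/log for AGB, Poisson/log for NS),
predictors census × site (burned FF vs unburned NF) — with omnibus Wald
chi-square tests per term and Bonferroni-adjusted pairwise contrasts
rendered as compact letter displays.

**Simulation.** An individual-based stand simulator reproduces the study
design (18 × 600 m² plots = 1.08 ha, censuses 1996/1999/2003/2006/2010/2016,
DBH ≥ 5 cm inclusion) with annual time steps: size-dependent background
mortality, drought episodes that multiply hazards (most strongly for large
stems), an optional 2010 fire pulse on FF plots, stochastic growth and
Poisson recruitment. Every analysis stage is therefore testable without any
field data.

## Worked example

```python
import forestdyn as fd

n0, nm, nr, nt, t = 100, 12, 9, 97, 4.0
m = fd.mortality_rate(n0, nm, t)           # 3.145 %/yr
m_corr = fd.interval_correction(m, t)      # 3.514 %/yr
agb = fd.compute_agb(dbh=22.0, height=16.0, wd=0.62)   # 263.6 kg
```

A plot losing 12 of 100 stems over four years has an annual mortality of
3.145 %/yr; the interval correction (4^0.08 = 1.117) raises it to
3.514 %/yr, inside the 3–5 %/yr background band of hyperdynamic transition
forests. A 22 cm, 16 m tree of wood density 0.62 carries ≈ 264 kg of
aboveground biomass (≈ 124 kg carbon).

End-to-end, from a synthetic study:

```python
paths = fd.make_fixture("paper_like", seed=1, outdir="fixture")
cfg = fd.RunConfig(census_path=paths["census"], plot_path=paths["plots"],
                   wood_density_path=paths["wood_density"],
                   drought_path=paths["drought"], output_dir="out")
bundle = fd.run_pipeline(cfg)
```

writes per-census stocks, per-interval rates and fluxes, site summaries,
GEE model reports with letter displays, and a hash manifest. On this
fixture the burned site's corrected mortality jumps to 7.4 ± 1.6 %/yr in
the post-fire interval against 4.9 ± 0.5 %/yr in the unburned site, while
earlier intervals sit in the 3–5 %/yr background in both.

The `examples/` directory holds one short script per capability
(allometry, turnover rates, flux accounting, the full pipeline, the GEE
stage); each prints its numbers with a line on what they mean.

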