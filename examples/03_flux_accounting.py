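"""Biomass stocks and fluxes on a simulated stand, with the conservation law.

Productivity (PB) counts recruit biomass plus survivor growth; mortality
flux counts the biomass of dying stems at their last live census; net
biomass change (NBC) is the annualized stock difference.  By construction
NBC = PB - mortality flux, exactly.
"""

import forestdyn as fd

table, truth, _ = fd.preset_run("tiny", seed=4)
wd = truth.wood_density.copy()
wd["measured"] = 1
biomass = fd.effective_biomass(table, wd)
fluxes = fd.flux_table(table, biomass)

cols = ["plot_id", "pb_mg_ha_yr", "nbc_mg_ha_yr", "mort_flux_total_mg_ha_yr"]
print(fluxes[cols].round(3).to_string(index=False))
resid = (fluxes["nbc_mg_ha_yr"] - fluxes["pb_mg_ha_yr"]
         + fluxes["mort_flux_total_mg_ha_yr"]).abs().max()
print(f"\nmax |NBC - (PB - mortality flux)| = {resid:.2e} Mg/ha/yr")
print("Positive NBC: the stand is accumulating biomass; negative: losing it.")
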