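"""Full pipeline on a synthetic 18-plot, six-census study.

Writes a fixture emulating the monitoring design (8 burned / 10 unburned
plots, censuses 1996-2016, drought episodes, a 2010 fire on FF plots),
runs validate -> wood density -> biomass -> rates -> fluxes -> models, and
prints the site-level summary.
"""

import tempfile

import forestdyn as fd

with tempfile.TemporaryDirectory() as d:
    paths = fd.make_fixture("paper_like", seed=1, outdir=d)
    cfg = fd.RunConfig(
        census_path=str(paths["census"]), plot_path=str(paths["plots"]),
        wood_density_path=str(paths["wood_density"]),
        drought_path=str(paths["drought"]), output_dir=f"{d}/out")
    bundle = fd.run_pipeline(cfg)

site = bundle["site_rates"]
print(site.round(2).to_string(index=False))
print()
print("M_corr/R_corr are corrected annual rates (%/yr), mean +/- SD across")
print("plots in each site.  FF shows the fire's mortality pulse in I5")
print("(2010-2016); both sites sit in the 3-5 %/yr hyperdynamic background.")
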