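"""Per-tree aboveground biomass and carbon from the moist-forest allometry.

AGB (kg) = 0.0673 * (WD * H * DBH^2)^0.976, with wood density WD in g/cm^3,
height H in m and DBH in cm; carbon is 0.47 * AGB.
"""

import forestdyn as fd

trees = [
    ("understory stem", 7.0, 8.0, 0.55),
    ("mid-canopy tree", 22.0, 16.0, 0.62),
    ("emergent tree", 45.0, 24.0, 0.70),
]

print(f"{'tree':>16}  {'DBH cm':>7}  {'H m':>5}  {'WD':>5}  "
      f"{'AGB kg':>9}  {'C kg':>8}  class")
for name, dbh, h, wd in trees:
    agb = fd.compute_agb(dbh, h, wd)
    print(f"{name:>16}  {dbh:7.1f}  {h:5.1f}  {wd:5.2f}  "
          f"{agb:9.1f}  {fd.carbon_from_agb(agb):8.1f}  "
          f"{fd.classify_size(dbh)}")

print()
print("AGB rises steeply with diameter: the emergent tree holds roughly")
print("%.0fx the biomass of the understory stem." % (
    fd.compute_agb(45, 24, 0.70) / fd.compute_agb(7, 8, 0.55)))
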