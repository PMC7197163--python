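"""Kernel home ranges for a small two-species population.

Estimates each animal's utilization distribution with the reference
bandwidth, reports 95% (seasonal) and 50% (core) isopleth areas in
hectares, and tests the species effect on log10 area with a linear model
— the study's Table-1-style summary and size contrast.
"""

import pandas as pd

import predspace as ps

lmap = ps.simulate_landscape(seed=3)
rows = []
areas_95 = {"dingo": [], "cat": []}
for species, n in (("dingo", 4), ("cat", 5)):
    cfg = ps.SimAnimalConfig.for_species(species, n_steps=250)
    tracks, _ = ps.simulate_population(lmap, species, n, cfg, seed=21)
    for tr in tracks:
        scr = ps.screen_track(tr, ps.ScreeningParams.for_species(species),
                              ref_elev=500.0)
        pts = scr.retained[["x", "y"]].to_numpy()
        h = ps.reference_bandwidth(pts)
        ud = ps.kde_ud(pts, h, h / 4)
        for level in (0.95, 0.50):
            hr = ps.isopleth(ud, level, tr.animal_id, polygonize=False)
            rows.append({"animal": tr.animal_id, "species": species,
                         "level": level, "area_ha": round(hr.area_ha, 1)})
        areas_95[species].append(
            ps.isopleth(ud, 0.95, polygonize=False).area_ha)

table = pd.DataFrame(rows).pivot(index=["species", "animal"],
                                 columns="level", values="area_ha")
print(table.to_string())

res = ps.compare_group_areas(areas_95)
print(f"\nspecies effect on log10(95% area): slope={res['slope']:.3f} "
      f"(SE {res['se']:.3f}), t={res['t']:.2f}, p={res['p']:.4f}")
print("A positive slope means dingo ranges are larger; slope is the "
      "log10 area difference, so 1.0 = a tenfold size gap.")
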