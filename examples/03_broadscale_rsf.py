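"""Second-order selection: do cats place home ranges in grassland?

Builds the species availability region (MCP merged with per-fix discs of
the median circular home-range radius), samples 1000 random circular home
ranges, places 'used' home ranges with a known logit-2 grassland
preference, and fits the weighted used-available logistic RSF. The fitted
coefficient should recover the generating preference.
"""

import numpy as np

import predspace as ps

lmap = ps.simulate_landscape(seed=3)
rng = np.random.default_rng(0)
fixes = rng.uniform(4_000, 26_000, (300, 2))

median_area_ha = 2_482  # the study's median circular cat home range
region = ps.availability_region(fixes, median_area_ha, species="cat")
print(f"availability region: {region.area_ha:,.0f} ha, "
      f"circle radius {region.r_median_m:,.0f} m")

used = ps.place_preferential_homeranges(region, lmap, ps.GRASSLAND,
                                        n=120, beta=2.0, seed=11)
avail = ps.sample_circle_hrs(region, lmap, ps.GRASSLAND, n=1_000, seed=12)
fit = ps.fit_weighted_rsf(used, avail)

print(f"used mean grassland proportion      {used['composition'].mean():.3f}")
print(f"available mean grassland proportion {avail['composition'].mean():.3f}")
print(f"available record weight {fit['available_weight']:.4f} "
      f"(n_used/n_available keeps the comparison balanced)")
print(f"\nRSF grassland coefficient: {fit['beta']:.2f} +- {fit['se']:.2f} "
      f"(z={fit['z']:.2f}, p={fit['p']:.4f}); generating value 2.0")
print("beta > 0 with p < 0.05 = home ranges sit in grassland more often "
      "than random placement predicts.")
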