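# predspace

Space use and habitat selection of sympatric GPS-collared predators:
a tested, reusable pipeline for the classic apex-predator /
mesopredator telemetry design (dingo *Canis dingo* and feral cat
*Felis catus* in semi-arid Australia is the motivating system).

The package is aimed at movement ecologists who have collar fixes and a
habitat map and want the full chain of analyses with every rule explicit
and testable:

1. **Screening** — speed-impossible fix removal (gallop ceiling and
   sustained-trot rules), elevation screening, analysis-window clipping,
   moving/resting classification by field-calibrated displacement
   thresholds (>20 m dingo, >35 m cat).
2. **Home ranges** — fixed kernel density estimation with the reference
   bandwidth `h = sqrt((var_x + var_y)/2) * n^(-1/6)`; seasonal (95%) and
   core (50%) isopleths by exact cumulative cell mass; asymptote analysis;
   minimum convex polygons; linear models on log10 area.
3. **Second-order selection** — availability regions (MCP merged with
   per-fix discs of the median circular home-range radius), 1000 random
   circular home ranges, and the weighted used–available logistic RSF
   with available records down-weighted to `n_used / n_available`.
4. **Third-order selection** — step-selection functions: 20 control steps
   per observed step from pooled empirical step-length and turning-angle
   distributions, a 4-level road-by-vegetation factor (reference:
   off-road grassland) plus hydrology and cover terms, fitted by
   conditional logistic regression

   `l(beta) = sum_strata [ x_used' beta - log sum_j exp(x_j' beta) ]`

   maximized by Newton iterations (equivalent to a stratified Cox model
   with one event per stratum), with an optional per-individual Gaussian
   random slope on vegetation estimated by Laplace profile likelihood.
5. **Autocorrelation sensitivity** — per-stratum deviance residuals,
   their ACF after per-animal centering, first non-significant lag
   (alpha = 0.05), and systematic thinning to that lag with a
   coefficient-shift table.
6. **Synthetic data** — a landscape generator (two-class vegetation
   mosaic, buffered roads and hydrology, Jenks-classified cover) and an
   SSF-consistent trajectory generator with known selection coefficients,
   injected resting bouts and positional spikes, so every stage is
   testable end to end with exact truth records.

## Worked example

`examples/04_step_selection.py` simulates eight dingoes on a synthetic
landscape with known selection coefficients, screens the tracks, builds
choice sets and fits the SSF:

```
1378 steps pooled from 8 animals
max |Pearson r| between design terms: 0.39
collinearity flags above 0.7: none

conditional-logistic SSF on 1378 strata (loglik -4180.3):
               coef     se      z  odds_ratio  or_lower  or_upper  true_beta
onroad_grass  2.019  0.679  2.972       7.531     1.988    28.521        1.5
onroad_wood   0.723  0.362  1.998       2.061     1.014     4.192        1.0
offroad_wood  0.232  0.146  1.584       1.261     0.947     1.680        0.5
hydro         0.264  0.140  1.892       1.303     0.990     1.713        0.5
cover_high    0.300  0.087  3.432       1.350     1.137     1.602        0.4
cover_low    -0.137  0.097 -1.422       0.872     0.721     1.053       -0.3
```

Each `coef` is the log odds of choosing a step ending in that habitat
state relative to the reference state (off-road grassland, moderate
cover, off-hydrology); `odds_ratio = exp(coef)`, so this population's
odds of selecting an on-road grassland endpoint are ~7.5 times the
reference. Every estimate brackets its generating value (`true_beta`)
within two standard errors — the recovery property the test suite
asserts at three.

The other examples cover landscape/screening, kernel home ranges and the
species size contrast, the second-order RSF, and the autocorrelation
diagnostic; each prints its numbers with a line on what they mean.

## Command line

The same stages run as a pipeline with a TOML config:

```bash
predspace run-all --out runs/demo --seed 1
predspace stage ssf --out runs/demo      # rerun a single stage
```

Each run writes CSV/GeoJSON/ASCII-grid artifacts plus the resolved
configuration and a log beside them.

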