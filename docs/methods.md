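# Methods

This note documents the models, rules and numerical choices behind each
stage, the design decisions that were genuinely open, and what the
synthetic-data experiments do and do not demonstrate about field data.

## Landscape model and habitat attribution

All geometry lives in a planar metric frame (metres). Coordinates whose
bounds fit inside the lon/lat envelope are rejected outright rather than
reprojected: a silent degree-unit buffer would be wrong by five orders
of magnitude, and reprojection is out of scope.

Roads are buffered by 10 m and hydrological features by 20 m (buffer
widths are stored on the map and reported); the wider hydrology buffer
reflects the lower mapping precision of stream lines. Vegetation is an
exhaustive two-class partition — explicit grassland polygons, woodland
as the complement within the study extent — with samphire shrubland
folded into woodland. Points exactly on a buffer boundary count as
inside (closed polygons, implemented with `intersects` tests); this tie
rule is deterministic and documented rather than left to floating-point
accident.

The continuous cover index is classified into low/moderate/high by Jenks
natural breaks: the exact O(n²k) dynamic program over contiguous
partitions of the sorted sample, with interval costs from prefix sums.
By default all pixels enter the program; an optional seeded subsample
caps the cost for large rasters (the synthetic default uses 4,000
pixels, which pins the two breaks to well under the class widths). Cells
are labelled by their center value; `value <= break_1` is low,
`break_1 < value <= break_2` moderate, else high; non-finite cells are
excluded from proportions and counted.

Region composition is exact polygon-intersection area, clipped to the
study extent, with grassland + woodland summing to 1 within 1e-9.

## Screening rules

Filters run in a fixed order — analysis window, speed, elevation,
movement classification — and the full screen is idempotent. Species
presets: gallop/trot ceilings 16/8.75 km/h (dingo) and 3.2/2.0 km/h
(cat); elevation tolerance ±100 m around the site reference; the first
24 h after release discarded; a window of up to 70 days ending at the
management (baiting) date, upper bound exclusive.

The speed filter is two-tier. The source protocol lists gallop and trot
ceilings without stating their joint rule, so the standard two-tier rule
is adopted: a fix is removed if the straight-line speed from the
previous retained fix exceeds the gallop ceiling, or if the speeds both
into and out of it exceed the trot ceiling (no animal sustains a trot
across two consecutive multi-hour intervals). Speeds are recomputed
after every removal; a sequential variant (gallop pass to fixpoint, then
trot) is available behind a flag. Movement classification uses strict
`>` on the displacement thresholds (20 m / 35 m), so a displacement of
exactly 35 m is resting.

Steps are formed only between consecutive *moving* fixes separated by
exactly one nominal interval within a ±15-minute tolerance (the schedule
jitter of field collars; configurable). Gaps break bursts: a turning
angle exists only when the preceding step ended where the current one
starts.

## Home ranges

The utilization distribution is a fixed isotropic-Gaussian KDE with the
bivariate-normal reference bandwidth `h = sigma * n^(-1/6)`,
`sigma = sqrt((var_x + var_y)/2)` (unbiased variances). The reference
rule oversmooths multimodal ranges; this is a property of the estimator,
asserted directionally in the tests (the 95% KDE area of a large
Gaussian sample exceeds the true 95% ellipse area).

The grid extends 3.5 h beyond the data bounding box (tail truncation
below 1e-6 of mass) and cell masses are renormalized to sum exactly
to 1. Cell size defaults to h/5 and must be at most h/2; coarse grids
distort isopleths, and 95% areas at h/4 and h/8 agree within 2%.
Isopleths take the smallest set of highest-density cells whose
cumulative mass reaches the level, ties broken by cell index — exact
mass accounting with no contour interpolation. Areas are cell count x
cell area, reported in hectares.

Asymptote analysis adds fixes in random order in species-specific
increments (25 for the 2-h schedule, 15 for the 4-h schedule; the
sparser cat schedule halves the fix count, hence the smaller increment)
and recomputes the 95% area at each block with the full-sample
bandwidth. The pass rule — the mean curve reaches 95% of the full-sample
area at or before the 75%-of-fixes increment — is one reading of the
protocol's "75–100% of fixes within 95% of the total area"; the second
reading (fraction of fixes inside the final isopleth) is computed and
returned alongside. Because fixes are added in *random* order, the
diagnostic detects under-sampling (scattered fixes whose kernels barely
overlap keep adding area), not temporal regime shifts; that limitation
is inherent to the randomized protocol and is demonstrated in the tests.

Group comparisons are OLS on log10 area with a two-level indicator,
matching the usual normality/homoscedasticity transformation for area
data.

## Second-order selection

The availability region for a species is the union of the 100% MCP of
all its fixes with per-fix discs of radius
`r = sqrt(median_area / pi)` (the radius of the circle with the median
seasonal home-range area; 48,325 ha gives 12,402–12,403 m and 2,482 ha
gives 2,811 m — the printed field values carry a metre of rounding from
their area medians). Radii are reported rounded to the metre; internal
math is unrounded.

Available home ranges are circles of the median area with centers drawn
uniformly in the region by rejection sampling (seeded). Circles may
overhang the region edge — composition is evaluated on the full circle
clipped to the mapped extent — with a flag to require containment; which
behavior the field protocol used is not stated, so the permissive
default is documented here.

The RSF is a logistic regression of used (1) versus available (0) home
ranges on the focal-class proportion (woodland for the apex predator,
grassland for the mesopredator; a per-species configuration entry).
Available records carry frequency weight `n_used / n_available`, so the
total available weight equals the used sample size: the available sample
sharpens the availability estimate without inflating statistical
precision. Complete separation is flagged, not raised.

## Third-order selection (SSF)

Choice sets pair each observed step with K = 20 control steps whose
lengths and turning angles are resampled independently from the pooled
empirical distributions of the species (marginal resampling; joint
resampling of observed pairs is a switch away, and the first step of a
burst draws a uniform absolute bearing). Control endpoints outside the
mapped extent are redrawn (the alternative — dropping them — is not the
default).

The design encodes road and vegetation as one 4-level factor
(off-road grassland reference) so each road-vegetation combination gets
its own log-odds coefficient, plus hydrology and high/low cover
indicators (moderate reference). Pairwise Pearson correlations among
design columns are reported with a 0.7 flag threshold.

The conditional-logistic likelihood is maximized by Newton-Raphson with
step halving; convergence requires a gradient below 1e-9 (relative);
standard errors come from the observed information. The fit is verified
in the tests against a stratified Cox fit (one event per stratum) and a
grid-search oracle. Terms with no within-stratum variation anywhere are
rejected as inestimable with a named error.

The mixed model adds a per-individual Gaussian deviation on the
vegetation (woodland) slope. For fixed variance the penalized likelihood
is maximized jointly over fixed effects and deviations by Newton; the
variance is then profiled by the Laplace approximation

`l(s2) = pll(theta_hat) - (q/2) log s2 - (1/2) log det(H_bb + I/s2)`

with a bounded 1-D search on log s2. A per-individual *intercept* is
constant within every stratum and cancels from the conditional
likelihood; rather than pretending to estimate it, the fit reports
`intercept_cancels` (it is identifiable only through survival-frailty
devices that change the model). A boundary variance estimate returns the
fixed-effects fit with variance 0.

Diel subsets are labelled by solar elevation (NOAA low-precision solar
position) at the used fix's UTC timestamp and the site coordinates
(default 26.23 S, 121.56 E) — above the horizon is diurnal. Clock-hour
rules would drift across the season; solar position does not. Subsets
with fewer than 30 strata are skipped with a notice (mirroring the
exclusion of a three-animal female sample).

## Autocorrelation sensitivity

With one event per stratum, the Cox martingale residual of the used
alternative is `m = 1 - p_used`, and the deviance residual is
`d = sign(m) * sqrt(-2 (m + ln p_used))`; at beta = 0 with K = 20 every
stratum has `p_used = 1/21` and all residuals coincide, and as
`p_used -> 1` the residual vanishes — both limits are tested. Residual
series are centered per animal (equivalent to the intercept-only
random-intercept adjustment; pooled centering is the alternative), the
sample ACF is computed with ±1.96/sqrt(n) bounds, and the first lag
below the bound is converted to hours via the species fix interval.

"Grouping to the lag" is implemented as systematic thinning — every L-th
stratum per animal, phase 0 by default — because block averaging is
incompatible with refitting a conditional-logistic model. Terms that
lose all within-stratum variation in the thinned data are reported as
NaN rather than dropped silently. On independently generated strata,
thinning shifts every coefficient by less than 3 SE (the "only very
minor changes" regime); this is asserted in the acceptance tests.

## Synthetic data generator

The landscape generator emulates the study system's composition regime:
grassland as a smoothed Gaussian field thresholded at the (1 − 0.19)
quantile (realized fraction = target up to grid discreteness; default
correlation length 2,000 m on a 30 x 30 km extent with 200 m cells);
five roads crossing the extent, buffered 10 m (realized fraction
~0.35%, inside the <1% regime); a stream plus twelve lakes scaled toward
3.8% after the 20 m buffer; and a second correlated field
Jenks-classified into three cover classes. Same seed, same landscape,
byte for byte.

Trajectories follow the data-generating process an SSF consistently
estimates: at each step, 50 candidate endpoints (always more than the
analysis K = 20, to limit generator artefacts) are drawn from gamma step
lengths — truncated above the species movement threshold so every
selected step is classifiable as moving — and von Mises turning angles
(kappa 0.7), and one is selected with probability proportional to
exp(x'beta) under the same covariate encoding the fitting stage uses.
Default coefficients: on-road grassland +1.5, on-road woodland +1.0,
off-road woodland +0.5, hydrology +0.5, high cover +0.4, low cover
−0.3. Step-length scales (gamma(2, 400) for the 2-h schedule,
gamma(2, 150) for the 4-h schedule) give mean displacements of roughly
800 m and 300 m — plausible multi-hour displacements for a wide-ranging
canid and a small felid, chosen once as configuration, not as claims
about the field animals.

Resting bouts displace by a uniform fraction (< 0.8) of the movement
threshold; positional spikes replace the *recorded* location with one
offset by 1.5x the largest speed-legal displacement while the true path
continues, so the speed screen has exact true positives (no back-to-back
spikes, keeping the truth record unambiguous). Population simulation
draws per-animal Gaussian deviations on the vegetation slope and stores
every generating value in a truth record.

What the generator does **not** emulate: GPS fix failure and HDOP error
structure, temporally varying behavior (diel cycles, denning),
predator-predator avoidance, and habitat-dependent step lengths.
Passing recovery tests therefore demonstrate correctness of the
estimation chain under the stated model, not robustness to these field
realities.

## Experiment sizes and power

The SSF recovery experiment uses 30 animals x 300 steps (about 7,000
strata after screening losses), where all six coefficients are recovered
within 3 SE; it runs in well under a minute.

The second-order closure experiment detects a logit-2 grassland
preference with the weighted RSF across 50 seeded replicates. The
placement sample is 120 home ranges per replicate, sized by a standard
power calculation: with the availability composition spread of the
default landscape the model SE at n placements is about
`1.13 * sqrt(25/n)`, and 90%+ power to detect beta = 2 at alpha = 0.05
two-sided requires SE <= 2/3.24 ≈ 0.62, i.e. n >= ~85; 120 gives
comfortable headroom. At the field study's own sample of 25, power is
roughly 50–85% depending on landscape contrast — consistent with the
original cat RSF sitting just past the significance boundary
(z ≈ 2.2) — so a detection-rate experiment at n = 25 would measure
replicate noise, not pipeline correctness. Each replicate redraws its
available sample; the candidate pool for preferential placement is
shared (6,000 circles) since it only proxies the availability density.

## Numerical conventions

- All randomness flows through `numpy.random.Generator` seeds; hierarchical
  seeds via `SeedSequence.spawn`, kept below 2^31.
- Log-sum-exp with per-stratum max subtraction everywhere a softmax
  appears; `p_used` is clipped at 1e-12 (with a warning) before logs.
- Isopleth ties broken by cell index; Jenks ties resolved by the DP's
  first-optimum backtrack; both deterministic.
- Areas in hectares (1 ha = 10^4 m²); speeds in km/h; angles in radians
  wrapped to (-pi, pi].
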