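"""Serial-autocorrelation diagnostic and thinning sensitivity for an SSF.

Fits the step-selection model, computes per-stratum deviance residuals,
finds the first lag where their autocorrelation is non-significant, thins
the strata to that lag and refits. For a well-specified model the
coefficients should barely move (the 'only very minor changes' regime).
"""

import predspace as ps

lmap = ps.simulate_landscape(seed=3)
cfg = ps.SimAnimalConfig.for_species("dingo", n_steps=250)
tracks, _ = ps.simulate_population(lmap, "dingo", 8, cfg, seed=41)

params = ps.ScreeningParams.for_species("dingo")
steps = []
for tr in tracks:
    steps.extend(ps.build_steps(ps.screen_track(tr, params, ref_elev=500.0)))
dists = ps.empirical_move_dists(steps, "dingo")
choices = ps.build_choice_sets(steps, dists, lmap, K=20, seed=42)

from predspace.finescale import estimable_terms

terms = estimable_terms(choices, ps.DESIGN_TERMS)
fit = ps.fit_clogit(choices, terms)

series = ps.deviance_residuals(fit, choices, ps.DINGO.fix_interval_h)
acf = ps.residual_acf(series, max_lag=12)
print("residual ACF (lags 0-6):", [round(v, 3) for v in acf["acf"][:7]])
print(f"significance bound +-{acf['bound']:.3f} (n={acf['n']})")

lag = ps.select_lag(acf, ps.DINGO.fix_interval_h)
print(f"first non-significant lag: {lag['lag']} observations "
      f"({lag['hours']} h at the 2-h dingo schedule)")

L = max(lag["lag"] or 2, 2)
sens = ps.thin_and_refit(choices, L, fit)
print(f"\nthinning to every {L}th stratum "
      f"({sens['n_strata_thinned']} strata remain):")
print(sens["table"].round(3).to_string(index=False))
print("\ndelta_beta within ~1 SE of the full fit indicates the "
      "autocorrelation has little effect on the selection estimates.")
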