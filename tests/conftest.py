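import numpy as np
import pandas as pd
import pytest

import predspace as ps


@pytest.fixture(scope="session")
def lmap():
    """Default synthetic landscape, shared across tests (read-only)."""
    return ps.simulate_landscape(seed=3)


@pytest.fixture(scope="session")
def dingo_population(lmap):
    """Small seeded dingo population with injected rests and spikes."""
    cfg = ps.SimAnimalConfig.for_species("dingo", n_steps=200,
                                         rest_prob=0.1, spike_rate=0.02)
    tracks, truth = ps.simulate_population(lmap, "dingo", 4, cfg, seed=11)
    return tracks, truth


@pytest.fixture(scope="session")
def dingo_choices(lmap, dingo_population):
    """Screened steps -> choice sets for the small dingo population."""
    tracks, _ = dingo_population
    params = ps.ScreeningParams.for_species("dingo")
    steps = []
    for tr in tracks:
        steps.extend(ps.build_steps(ps.screen_track(tr, params,
                                                    ref_elev=500.0)))
    dists = ps.empirical_move_dists(steps, "dingo")
    return ps.build_choice_sets(steps, dists, lmap, K=20, seed=7)


def simulate_choice_table(n_strata, K, beta, rng, animal="a0",
                          binary_cols=()):
    """Direct conditional-logit data generator (oracle-side simulator).

    Covariates are iid across strata (no serial structure), one alternative
    chosen with probability softmax(X beta) — the exact model fit_clogit
    estimates, independent of the movement machinery.
    """
    beta = np.asarray(beta, dtype=float)
    p_cov = len(beta)
    rows = []
    t0 = pd.Timestamp("2014-05-01")
    for s in range(n_strata):
        X = rng.normal(0, 1, (K + 1, p_cov))
        for j in binary_cols:
            X[:, j] = rng.integers(0, 2, K + 1).astype(float)
        u = X @ beta
        prob = np.exp(u - u.max())
        prob /= prob.sum()
        chosen = rng.choice(K + 1, p=prob)
        for k in range(K + 1):
            rows.append(
                (f"{animal}:{s}", animal, t0 + pd.Timedelta(hours=2 * s),
                 int(k == chosen), *X[k])
            )
    cols = ["stratum", "animal_id", "timestamp", "used"] + [
        f"c{j}" for j in range(p_cov)
    ]
    return pd.DataFrame(rows, columns=cols)
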