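"""Serial-autocorrelation diagnostics and thinning sensitivity for SSF fits.

Strata from consecutive steps of one animal are not independent; the
diagnostic computes per-stratum deviance residuals (via the one-event
stratified-Cox identity), examines their autocorrelation function after
per-animal centering (the intercept-only random-intercept adjustment),
finds the first lag at which autocorrelation is non-significant at
alpha = 0.05, and refits the model on data thinned to that lag to show how
little the coefficients move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .finescale import SelectionFit, fit_clogit

__all__ = [
    "ResidualSeries",
    "deviance_residuals",
    "residual_acf",
    "select_lag",
    "thin_and_refit",
]


@dataclass
class ResidualSeries:
    """Time-ordered per-stratum deviance residuals for one animal."""

    animal_id: str
    residuals: np.ndarray
    timestamps: pd.DatetimeIndex
    fix_interval_h: float


def _stratum_p_used(fit: SelectionFit, df: pd.DataFrame) -> pd.DataFrame:
    terms = fit.info.get("terms", list(fit.params.index))
    beta = fit.params.reindex(terms).to_numpy()
    eta = df[terms].to_numpy(dtype=float) @ beta
    tmp = df[["stratum", "animal_id", "timestamp", "used"]].copy()
    tmp["w"] = np.exp(eta - eta.max())
    tot = tmp.groupby("stratum", sort=False)["w"].transform("sum")
    tmp["p"] = tmp["w"] / tot
    used = tmp[tmp["used"] == 1]
    return used[["stratum", "animal_id", "timestamp", "p"]]


def deviance_residuals(fit: SelectionFit, df: pd.DataFrame,
                       fix_interval_h: float = np.nan,
                       *, clip: float = 1e-12) -> list[ResidualSeries]:
    """Per-animal deviance residual series from a conditional-logistic fit.

    With one event per stratum the Cox martingale residual of the used
    alternative is m = 1 - p_used (p_used = its within-stratum choice
    probability), and the deviance residual is

        d = sign(m) * sqrt(-2 * (m + ln p_used)).

    At beta = 0 with K controls every stratum has p_used = 1/(K+1) and all
    residuals coincide; as p_used -> 1 the residual -> 0. Numerically zero
    p_used is clipped (with a warning) before the log.
    """
    used = _stratum_p_used(fit, df)
    p = used["p"].to_numpy()
    if np.any(p < clip):
        import warnings

        warnings.warn(f"{int((p < clip).sum())} stratum probabilities "
                      "clipped at {clip} in deviance residuals")
        p = np.clip(p, clip, None)
    m = 1.0 - p
    arg = -2.0 * (m + np.log(p))
    d = np.sign(m) * np.sqrt(np.maximum(arg, 0.0))
    used = used.assign(resid=d)
    out = []
    for animal, sub in used.groupby("animal_id", sort=True):
        sub = sub.sort_values("timestamp")
        out.append(
            ResidualSeries(
                animal_id=str(animal),
                residuals=sub["resid"].to_numpy(),
                timestamps=pd.DatetimeIndex(sub["timestamp"]),
                fix_interval_h=fix_interval_h,
            )
        )
    return out


def residual_acf(series: list[ResidualSeries] | ResidualSeries,
                 max_lag: int = 20, *, center: str = "per_animal") -> dict:
    """Sample ACF of the pooled residual series with +-1.96/sqrt(n) bounds.

    ``center='per_animal'`` removes each animal's mean first (the
    random-intercept, intercept-only adjustment); ``'pooled'`` removes one
    grand mean. Animals are concatenated; cross-animal lag products are a
    negligible O(n_animals * max_lag / n) contamination and are accepted
    for the pooled diagnostic.
    """
    if isinstance(series, ResidualSeries):
        series = [series]
    parts = []
    for s in series:
        r = np.asarray(s.residuals, dtype=float)
        parts.append(r - r.mean() if center == "per_animal" else r)
    x = np.concatenate(parts)
    if center == "pooled":
        x = x - x.mean()
    n = x.size
    if n < 10:
        raise ValueError(f"need >= 10 residuals for an ACF, got {n}")
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("constant residual series; ACF undefined")
    max_lag = min(max_lag, n - 1)
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for lag in range(1, max_lag + 1):
        acf[lag] = float(np.sum(x[:-lag] * x[lag:]) / denom)
    bound = 1.96 / np.sqrt(n)
    return {"acf": acf, "bound": bound, "n": n, "max_lag": max_lag}


def select_lag(acf_result: dict, fix_interval_h: float) -> dict:
    """First lag where |acf| drops below the significance bound.

    Returns the lag in observations and in hours (lag x fix interval); a
    series still significant at ``max_lag`` is reported as censored.
    """
    acf = acf_result["acf"]
    bound = acf_result["bound"]
    for lag in range(1, len(acf)):
        if abs(acf[lag]) < bound:
            return {"lag": lag, "hours": lag * fix_interval_h,
                    "censored": False}
    return {"lag": None, "hours": None, "censored": True}


def thin_and_refit(df: pd.DataFrame, L: int, original: SelectionFit,
                   *, terms: list[str] | None = None,
                   phase: int = 0) -> dict:
    """Refit on every L-th stratum per animal and tabulate coefficient shifts.

    Strata are ordered by timestamp within animal; the systematic sample
    keeps positions ``phase, phase+L, ...``. L = 1 reproduces the original
    fit. Returns the comparison table (term, beta_full, se_full,
    beta_thinned, se_thinned, delta_beta, delta_se) and the thinned fit.
    """
    if L < 1:
        raise ValueError("thinning lag must be >= 1")
    terms = (list(original.info.get("terms", original.params.index))
             if terms is None else list(terms))
    strata = (
        df[df["used"] == 1][["stratum", "animal_id", "timestamp"]]
        .sort_values(["animal_id", "timestamp"])
    )
    keep: list[str] = []
    for _, sub in strata.groupby("animal_id", sort=False):
        keep.extend(sub["stratum"].iloc[phase::L])
    thinned = df[df["stratum"].isin(keep)]
    n_kept = thinned["stratum"].nunique()
    if n_kept < 30:
        import warnings

        warnings.warn(f"only {n_kept} strata remain after thinning at lag {L}")
    from .finescale import estimable_terms

    fit_terms = estimable_terms(thinned, terms)
    dropped = [t for t in terms if t not in fit_terms]
    if dropped:
        import warnings

        warnings.warn(
            f"terms {dropped} lost all within-stratum variation after "
            f"thinning at lag {L}; reported as NaN"
        )
    refit = fit_clogit(thinned, fit_terms)
    table = pd.DataFrame(
        {
            "term": terms,
            "beta_full": original.params.reindex(terms).to_numpy(),
            "se_full": original.se.reindex(terms).to_numpy(),
            "beta_thinned": refit.params.reindex(terms).to_numpy(),
            "se_thinned": refit.se.reindex(terms).to_numpy(),
        }
    )
    table["delta_beta"] = table["beta_thinned"] - table["beta_full"]
    table["delta_se"] = table["se_thinned"] - table["se_full"]
    return {"table": table, "fit": refit, "n_strata_thinned": n_kept,
            "lag": L, "phase": phase}
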