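"""Third-order habitat selection via step-selection functions (SSF).

Each observed movement step is paired with K=20 control steps drawn from
the species' pooled empirical step-length and turning-angle distributions;
the used-versus-control contrast within each stratum is fitted by
conditional logistic regression (equivalently a stratified Cox model with
one event per stratum). Coefficients are log odds ratios of a habitat
state being chosen relative to the reference state (off-road grassland,
moderate cover, off-hydrology).

The conditional log-likelihood

    l(beta) = sum_strata [ x_used' beta - log sum_j exp(x_j' beta) ]

is maximized by Newton iterations with analytic gradient and Hessian;
standard errors come from the observed information. A penalized Laplace
profile likelihood adds a per-individual Gaussian random slope on
vegetation type; the per-individual random intercept the field convention
also includes is stratum-constant and therefore cancels from the
conditional likelihood — this is detected and reported rather than
silently estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .landscape import LandscapeMap, attribute_points
from .screening import Step
from .solar import SITE_LAT, SITE_LON, is_diurnal
from .species import WOODLAND

__all__ = [
    "DESIGN_TERMS",
    "MoveDistributions",
    "SelectionFit",
    "build_choice_sets",
    "design_matrix",
    "empirical_move_dists",
    "feature_correlations",
    "fit_clogit",
    "fit_clogit_ranef",
    "generate_control_steps",
    "subset_fits",
]

# reference state: off-road grassland, off-hydrology, moderate cover
DESIGN_TERMS = ["onroad_grass", "onroad_wood", "offroad_wood",
                "hydro", "cover_high", "cover_low"]


@dataclass
class MoveDistributions:
    """Pooled empirical movement kernels for one species."""

    species: str
    step_lengths: np.ndarray  # metres
    turn_angles: np.ndarray  # radians in (-pi, pi]

    def summary(self) -> pd.DataFrame:
        q = [0.05, 0.25, 0.5, 0.75, 0.95]
        return pd.DataFrame(
            {
                "quantile": q,
                "step_length_m": np.quantile(self.step_lengths, q),
                "turn_angle_rad": np.quantile(self.turn_angles, q),
            }
        )

    def sample(self, n: int, rng: np.random.Generator,
               *, uniform_angle: bool = False):
        lengths = rng.choice(self.step_lengths, size=n, replace=True)
        if uniform_angle or self.turn_angles.size == 0:
            angles = rng.uniform(-np.pi, np.pi, size=n)
        else:
            angles = rng.choice(self.turn_angles, size=n, replace=True)
        return lengths, angles


def empirical_move_dists(steps: list[Step], species: str,
                         *, min_steps: int = 30) -> MoveDistributions:
    """Pool step lengths and turning angles across all individuals."""
    lengths = np.array([s.length_m for s in steps], dtype=float)
    turns = np.array([s.turn_rad for s in steps if s.turn_rad is not None],
                     dtype=float)
    if lengths.size < min_steps:
        raise ValueError(
            f"need >= {min_steps} pooled steps, got {lengths.size}"
        )
    return MoveDistributions(species=species, step_lengths=lengths,
                             turn_angles=turns)


def generate_control_steps(
    origin: tuple[float, float],
    prev_bearing: float | None,
    dists: MoveDistributions,
    K: int = 20,
    rng: np.random.Generator | None = None,
    *,
    extent=None,
    max_rejections: int = 1000,
) -> np.ndarray:
    """K candidate endpoints from the empirical movement kernels.

    Lengths and turning angles are resampled independently (marginals);
    the endpoint lies at the drawn length along bearing = prev_bearing +
    turn. Without a previous bearing (burst start) the absolute bearing is
    uniform on (-pi, pi]. Endpoints outside ``extent`` are redrawn.
    """
    if K == 0:
        return np.empty((0, 2))
    rng = np.random.default_rng() if rng is None else rng
    x0, y0 = origin
    out = np.empty((K, 2))
    need = np.ones(K, dtype=bool)
    rejections = 0
    while need.any():
        m = int(need.sum())
        lengths, turns = dists.sample(m, rng,
                                      uniform_angle=prev_bearing is None)
        bearing = turns if prev_bearing is None else prev_bearing + turns
        xs = x0 + lengths * np.cos(bearing)
        ys = y0 + lengths * np.sin(bearing)
        if extent is None:
            ok = np.ones(m, dtype=bool)
        else:
            ok = shapely.intersects_xy(extent, xs, ys)
        idx = np.flatnonzero(need)
        out[idx[ok], 0] = xs[ok]
        out[idx[ok], 1] = ys[ok]
        need[idx[ok]] = False
        rejections += m - int(ok.sum())
        if rejections > max_rejections:
            raise ValueError(
                "control-step sampler exceeded rejection budget; origin too "
                "close to the mapped boundary for the movement kernel"
            )
    return out


def design_matrix(attrs: pd.DataFrame) -> pd.DataFrame:
    """Dummy design from habitat attributes.

    road x vegetation as a 4-level factor with off-road grassland as
    reference, plus hydrology and high/low cover indicators (moderate cover
    reference). An extra ``woodland`` column (not a model term) carries the
    plain vegetation indicator used for the random slope.
    """
    rv = attrs["road_veg"].astype(str)
    out = pd.DataFrame(
        {
            "onroad_grass": (rv == "onroad_grass").astype(float),
            "onroad_wood": (rv == "onroad_wood").astype(float),
            "offroad_wood": (rv == "offroad_wood").astype(float),
            "hydro": attrs["on_hydro"].astype(float),
            "cover_high": (attrs["cover"] == "high").astype(float),
            "cover_low": (attrs["cover"] == "low").astype(float),
            "woodland": (attrs["veg"] == WOODLAND).astype(float),
        },
        index=attrs.index,
    )
    return out


def build_choice_sets(
    steps: list[Step],
    dists: MoveDistributions,
    lmap: LandscapeMap,
    K: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format choice sets: one used + K control rows per step.

    Columns: stratum, animal_id, timestamp, used, x, y, the design terms
    and the raw attribute columns. Control endpoints are redrawn until they
    fall inside the mapped extent.
    """
    rng = np.random.default_rng(seed)
    rows_xy = []
    meta = []
    for i, s in enumerate(steps):
        stratum = f"{s.animal_id}:{i}"
        prev_bearing = (None if s.turn_rad is None
                        else s.bearing_rad - s.turn_rad)
        ctrl = generate_control_steps(
            (s.x0, s.y0), prev_bearing, dists, K, rng,
            extent=lmap.study_extent,
        )
        rows_xy.append(np.vstack([[s.x1, s.y1], ctrl]))
        meta.extend(
            (stratum, s.animal_id, s.end_time, int(j == 0))
            for j in range(K + 1)
        )
    xy = np.vstack(rows_xy)
    base = pd.DataFrame(meta, columns=["stratum", "animal_id", "timestamp",
                                       "used"])
    base["x"] = xy[:, 0]
    base["y"] = xy[:, 1]
    attrs = attribute_points(lmap, base["x"].to_numpy(), base["y"].to_numpy())
    design = design_matrix(attrs)
    return pd.concat(
        [base.reset_index(drop=True), attrs.reset_index(drop=True),
         design.reset_index(drop=True)],
        axis=1,
    )


@dataclass
class SelectionFit:
    """Fitted selection model: coefficients are log odds ratios."""

    params: pd.Series
    se: pd.Series
    loglik: float
    n_strata: int
    converged: bool
    ranef_variance: float | None = None
    info: dict = field(default_factory=dict)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, z: float = 1.96) -> pd.DataFrame:
        lo = self.params - z * self.se
        hi = self.params + z * self.se
        return pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.se

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "z": self.zvalues,
                "odds_ratio": self.odds_ratios,
                "or_lower": np.exp(ci["lower"]),
                "or_upper": np.exp(ci["upper"]),
            }
        )


def _stack(df: pd.DataFrame, terms: list[str]):
    df = df.sort_values("stratum", kind="stable")
    codes, _ = pd.factorize(df["stratum"], sort=False)
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    X = df[terms].to_numpy(dtype=float)
    y = df["used"].to_numpy(dtype=int)
    used_per = np.bincount(codes, weights=y)
    if not np.all(used_per == 1):
        raise ValueError("every stratum needs exactly one used alternative")
    return X, y.astype(bool), codes, starts


def _cll_parts(X, used, codes, starts, beta):
    """Conditional log-likelihood, gradient and Hessian at beta."""
    eta = X @ beta
    # per-stratum log-sum-exp via segment max
    seg_max = np.maximum.reduceat(eta, starts)
    lse = seg_max + np.log(np.add.reduceat(np.exp(eta - seg_max[codes]),
                                           starts))
    ll = float(eta[used].sum() - lse.sum())
    p = np.exp(eta - lse[codes])
    grad = X[used].sum(axis=0) - X.T @ p
    S = np.empty((len(starts), X.shape[1]))
    pX = p[:, None] * X
    for j in range(X.shape[1]):
        S[:, j] = np.add.reduceat(pX[:, j], starts)
    hess = -(X.T @ pX - S.T @ S)
    return ll, grad, hess


def conditional_loglik(df: pd.DataFrame, terms: list[str],
                       beta: np.ndarray) -> float:
    """Conditional log-likelihood of a choice-set table at ``beta``."""
    X, used, codes, starts = _stack(df, terms)
    ll, _, _ = _cll_parts(X, used, codes, starts, np.asarray(beta, float))
    return ll


def estimable_terms(df: pd.DataFrame, terms: list[str]) -> list[str]:
    """Terms with within-stratum variation somewhere (the others carry no
    conditional-likelihood signal, e.g. after heavy thinning)."""
    X, _, codes, starts = _stack(df, terms)
    counts = np.diff(np.r_[starts, len(codes)])
    keep = []
    for j, term in enumerate(terms):
        col = X[:, j]
        mean = np.add.reduceat(col, starts) / counts
        if np.max(np.abs(col - mean[codes])) >= 1e-12:
            keep.append(term)
    return keep


def _check_estimable(X, codes, starts, terms):
    # a column constant within every stratum carries no conditional signal
    counts = np.diff(np.r_[starts, len(codes)])
    for j, term in enumerate(terms):
        col = X[:, j]
        mean = np.add.reduceat(col, starts) / counts
        if np.max(np.abs(col - mean[codes])) < 1e-12:
            raise ValueError(
                f"term {term!r} is constant within every stratum; "
                "inestimable in a conditional-logistic model"
            )


def fit_clogit(df: pd.DataFrame, terms: list[str] | None = None,
               *, tol: float = 1e-9, max_iter: int = 60) -> SelectionFit:
    """Conditional logistic regression over used/control strata.

    Newton-Raphson on the conditional log-likelihood with step halving;
    standard errors from the observed information. Potential separation
    (diverging coefficients) is flagged in ``info`` rather than hidden.
    """
    terms = list(DESIGN_TERMS) if terms is None else list(terms)
    X, used, codes, starts = _stack(df, terms)
    _check_estimable(X, codes, starts, terms)
    beta = np.zeros(len(terms))
    ll, grad, hess = _cll_parts(X, used, codes, starts, beta)
    converged = False
    for _ in range(max_iter):
        try:
            delta = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            delta = -np.linalg.pinv(hess) @ grad
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, grad_new, hess_new = _cll_parts(X, used, codes, starts,
                                                    cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
            converged = True
            break
    if not converged and np.max(np.abs(grad)) > 1e-3:
        raise RuntimeError(
            f"conditional-logistic fit did not converge; |grad| = "
            f"{np.max(np.abs(grad)):.3g}"
        )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    separation = bool(np.any(np.abs(beta) > 15))
    return SelectionFit(
        params=pd.Series(beta, index=terms),
        se=pd.Series(se, index=terms),
        loglik=ll,
        n_strata=len(starts),
        converged=True,
        info={"separation_flag": separation,
              "grad_norm": float(np.max(np.abs(grad))),
              "cov": cov, "terms": terms},
    )


def fit_clogit_ranef(
    df: pd.DataFrame,
    terms: list[str] | None = None,
    *,
    random_col: str = "woodland",
    animal_col: str = "animal_id",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SelectionFit:
    """Conditional logistic fit with a per-individual Gaussian random slope.

    Each individual i gets a deviation b_i ~ N(0, sigma^2) on the
    ``random_col`` covariate (vegetation type); sigma^2 is estimated by a
    Laplace-approximate profile likelihood, with the inner penalized
    likelihood maximized jointly over fixed effects and deviations by
    Newton iterations. A per-individual intercept is stratum-constant and
    cancels from the conditional likelihood — reported in
    ``info['intercept_cancels']`` instead of being pretend-estimated. A
    boundary estimate (sigma^2 -> 0) returns the fixed-effects fit with
    ``ranef_variance = 0``.
    """
    terms = list(DESIGN_TERMS) if terms is None else list(terms)
    animals = pd.unique(df[animal_col])
    if len(animals) < 2:
        raise ValueError("random-slope model needs >= 2 individuals")
    df = df.sort_values("stratum", kind="stable")
    X, used, codes, starts = _stack(df, terms)
    _check_estimable(X, codes, starts, terms)
    a_codes, a_levels = pd.factorize(df[animal_col], sort=True)
    q = len(a_levels)
    z = df[random_col].to_numpy(dtype=float)
    # augmented design: fixed terms then per-animal slope deviations
    Z = np.zeros((len(df), q))
    Z[np.arange(len(df)), a_codes] = z
    XA = np.hstack([X, Z])
    p = len(terms)

    def inner(log_s2: float):
        s2 = float(np.exp(log_s2))
        pen = np.r_[np.zeros(p), np.full(q, 1.0 / s2)]
        theta = np.zeros(p + q)
        ll, grad, hess = _cll_parts(XA, used, codes, starts, theta)
        pll = ll - 0.5 * np.sum(pen * theta**2)
        for _ in range(max_iter):
            g = grad - pen * theta
            H = hess - np.diag(pen)
            try:
                delta = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                delta = -np.linalg.pinv(H) @ g
            step = 1.0
            for _ in range(30):
                cand = theta + step * delta
                ll_n, grad_n, hess_n = _cll_parts(XA, used, codes, starts,
                                                  cand)
                pll_n = ll_n - 0.5 * np.sum(pen * cand**2)
                if pll_n >= pll - 1e-12:
                    break
                step /= 2
            theta, ll, grad, hess, pll = cand, ll_n, grad_n, hess_n, pll_n
            if np.max(np.abs(grad - pen * theta)) < tol * max(1.0, abs(pll)):
                break
        # Laplace marginal: pll - q/2 log s2 - 1/2 logdet(Hbb + I/s2)
        Hbb = -hess[p:, p:] + np.eye(q) / s2
        sign, logdet = np.linalg.slogdet(Hbb)
        lap = pll - 0.5 * q * np.log(s2) - 0.5 * logdet
        return lap, theta, hess, s2

    res = minimize_scalar(lambda ls2: -inner(ls2)[0],
                          bounds=(np.log(1e-4), np.log(25.0)),
                          method="bounded",
                          options={"xatol": 1e-3})
    lap, theta, hess, s2 = inner(res.x)
    boundary = s2 <= 2e-4
    if boundary:
        fixed = fit_clogit(df, terms)
        fixed.ranef_variance = 0.0
        fixed.info["ranef_boundary"] = True
        fixed.info["intercept_cancels"] = True
        return fixed
    pen = np.r_[np.zeros(p), np.full(q, 1.0 / s2)]
    cov = np.linalg.inv(-(hess - np.diag(pen)))
    se = np.sqrt(np.diag(cov)[:p])
    ll, _, _ = _cll_parts(XA, used, codes, starts, theta)
    return SelectionFit(
        params=pd.Series(theta[:p], index=terms),
        se=pd.Series(se, index=terms),
        loglik=float(ll),
        n_strata=len(starts),
        converged=True,
        ranef_variance=float(s2),
        info={
            "intercept_cancels": True,
            "ranef_sd": float(np.sqrt(s2)),
            "blups": pd.Series(theta[p:], index=list(a_levels)),
            "laplace_loglik": float(lap),
            "terms": terms,
        },
    )


def subset_fits(
    df: pd.DataFrame,
    by: str,
    *,
    terms: list[str] | None = None,
    sex_map: dict[str, str] | None = None,
    site_lat: float = SITE_LAT,
    site_lon: float = SITE_LON,
    min_strata: int = 30,
) -> dict[str, SelectionFit | str]:
    """Independent fits per diel phase or per sex.

    Diel labels come from solar elevation at the used fix's timestamp and
    the site coordinates (sun above horizon = diurnal). Subsets with fewer
    than ``min_strata`` strata are skipped with a notice string instead of
    an unstable fit — mirroring the exclusion of under-sampled groups such
    as a three-animal female subset.
    """
    if by == "diel":
        used_rows = df[df["used"] == 1]
        lab = pd.Series(
            np.where(is_diurnal(used_rows["timestamp"], site_lat, site_lon),
                     "diurnal", "nocturnal"),
            index=used_rows["stratum"].to_numpy(),
        )
        labels = df["stratum"].map(lab)
    elif by == "sex":
        if sex_map is None:
            raise ValueError("sex subsetting needs a {animal_id: sex} map")
        labels = df["animal_id"].map(sex_map)
        if labels.isna().any():
            raise ValueError("sex_map missing entries for some animals")
    else:
        raise ValueError(f"unknown subset key {by!r}; use 'diel' or 'sex'")
    out: dict[str, SelectionFit | str] = {}
    for value in pd.unique(labels.dropna()):
        sub = df[labels == value]
        n_strata = sub["stratum"].nunique()
        if n_strata < min_strata:
            out[str(value)] = (
                f"skipped: only {n_strata} strata (< {min_strata})"
            )
            continue
        out[str(value)] = fit_clogit(sub, terms)
    return out


def feature_correlations(df: pd.DataFrame, terms: list[str] | None = None,
                         *, threshold: float = 0.7) -> dict:
    """Pairwise Pearson correlations of the design columns over all
    locations; pairs above ``threshold`` in absolute value are flagged.
    Zero-variance columns yield undefined (NaN) correlations, reported."""
    terms = list(DESIGN_TERMS) if terms is None else list(terms)
    M = df[terms].to_numpy(dtype=float)
    sd = M.std(axis=0)
    degenerate = [t for t, s in zip(terms, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(M, rowvar=False)
    corr = pd.DataFrame(corr, index=terms, columns=terms)
    flagged = [
        (terms[i], terms[j], float(corr.iloc[i, j]))
        for i in range(len(terms))
        for j in range(i + 1, len(terms))
        if np.isfinite(corr.iloc[i, j]) and abs(corr.iloc[i, j]) > threshold
    ]
    return {"matrix": corr, "flagged": flagged, "threshold": threshold,
            "degenerate": degenerate}
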