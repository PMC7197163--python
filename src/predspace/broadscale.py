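"""Second-order (home-range placement) habitat selection.

Used home ranges are compared with randomly placed circular home ranges of
median area inside a species availability region — the union of the
species' 100% MCP with discs of the median-circular-home-range radius
around every fix. The used-available contrast is a weighted logistic
resource selection function on the focal vegetation proportion, with the
available records down-weighted to n_used/n_available so the available
sample cannot inflate statistical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .homerange import M2_PER_HA, mcp
from .landscape import LandscapeMap, region_composition

__all__ = [
    "AvailabilityRegion",
    "availability_region",
    "circle_radius_from_area",
    "fit_weighted_rsf",
    "sample_circle_hrs",
]


def circle_radius_from_area(area_ha: float, *, rounded: bool = True) -> float:
    """Radius (m) of the circle with the given area in hectares.

    r = sqrt(area_m2 / pi); reported radii are rounded to the nearest metre
    (presentation convention), internal consumers pass ``rounded=False``.
    """
    if area_ha <= 0:
        raise ValueError(f"area must be positive, got {area_ha}")
    r = float(np.sqrt(area_ha * M2_PER_HA / np.pi))
    return float(round(r)) if rounded else r


@dataclass
class AvailabilityRegion:
    """Landscape considered available to all individuals of a species."""

    species: str
    polygon: shapely.geometry.base.BaseGeometry
    r_median_m: float
    median_hr_area_ha: float

    @property
    def area_ha(self) -> float:
        return self.polygon.area / M2_PER_HA


def availability_region(fixes_xy: np.ndarray, median_hr_area_ha: float,
                        species: str = "") -> AvailabilityRegion:
    """Union of the species 100% MCP with per-fix discs of the
    median-circular-home-range radius."""
    pts = np.asarray(fixes_xy, dtype=float)
    hull = mcp(pts)
    r = circle_radius_from_area(median_hr_area_ha, rounded=False)
    discs = shapely.buffer(shapely.multipoints(pts), r)
    region = shapely.unary_union([hull, discs])
    shapely.prepare(region)
    return AvailabilityRegion(
        species=species, polygon=region, r_median_m=r,
        median_hr_area_ha=median_hr_area_ha,
    )


def sample_circle_hrs(
    region: AvailabilityRegion,
    lmap: LandscapeMap,
    focal_class: str,
    n: int = 1000,
    seed: int | None = None,
    *,
    require_containment: bool = False,
    max_tries: int = 10_000_000,
) -> pd.DataFrame:
    """Randomly placed circular home ranges and their focal-class composition.

    Circle centers are drawn uniformly in the availability region by
    rejection sampling over its bounding box. By default circles may
    overhang the region edge (their composition is still evaluated on the
    full circle clipped to the mapped extent); ``require_containment``
    additionally rejects centers closer than one radius to the region edge.

    Returns a DataFrame with columns cx, cy, composition (focal-class
    proportion), used (False), weight (filled by :func:`fit_weighted_rsf`).
    """
    if n == 0:
        return pd.DataFrame(columns=["cx", "cy", "composition", "used"])
    if region.polygon.is_empty:
        raise ValueError("empty availability region")
    rng = np.random.default_rng(seed)
    r = region.r_median_m
    target = (region.polygon.buffer(-r) if require_containment
              else region.polygon)
    if target.is_empty:
        raise ValueError("region too small to contain a median circle")
    shapely.prepare(target)
    xmin, ymin, xmax, ymax = target.bounds
    centers: list[tuple[float, float]] = []
    tries = 0
    batch = max(4 * n, 1000)
    while len(centers) < n:
        tries += batch
        if tries > max_tries:
            raise ValueError("degenerate region: center acceptance rate < 1e-4")
        xs = rng.uniform(xmin, xmax, batch)
        ys = rng.uniform(ymin, ymax, batch)
        ok = shapely.intersects_xy(target, xs, ys)
        centers.extend(zip(xs[ok], ys[ok]))
    centers = centers[:n]
    comp = np.empty(n)
    for i, (cx, cy) in enumerate(centers):
        circle = shapely.Point(cx, cy).buffer(r, quad_segs=32)
        comp[i] = region_composition(lmap, circle)[focal_class]
    out = pd.DataFrame(centers, columns=["cx", "cy"])
    out["composition"] = comp
    out["used"] = False
    return out


def fit_weighted_rsf(used: pd.DataFrame, available: pd.DataFrame,
                     *, composition_col: str = "composition") -> dict:
    """Weighted used-available logistic RSF on focal-class proportion.

    Used records get weight 1; every available record gets weight
    n_used/n_available, so total available weight equals n_used (a balanced
    comparison that does not inflate precision). Fitting is IRLS via a
    frequency-weighted binomial GLM. Complete separation is flagged rather
    than raised: the coefficient is still reported with a warning marker.
    """
    import statsmodels.api as sm

    n_used, n_avail = len(used), len(available)
    if n_used == 0 or n_avail == 0:
        raise ValueError("both used and available samples must be non-empty")
    w_avail = n_used / n_avail
    y = np.concatenate([np.ones(n_used), np.zeros(n_avail)])
    x = np.concatenate([
        used[composition_col].to_numpy(dtype=float),
        available[composition_col].to_numpy(dtype=float),
    ])
    w = np.concatenate([np.ones(n_used), np.full(n_avail, w_avail)])
    X = sm.add_constant(x)
    separated = False
    with np.errstate(all="ignore"):
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial(),
                         freq_weights=w).fit(maxiter=200)
            beta, se = float(fit.params[1]), float(fit.bse[1])
            z = beta / se if se > 0 else np.inf
            p = float(fit.pvalues[1])
            mu = fit.fittedvalues
            if abs(beta) > 50 or np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
                separated = True
        except Exception:  # perfect separation can break IRLS outright
            separated = True
            beta, se, z, p = np.inf, np.inf, np.nan, np.nan
    if separated:
        import warnings

        warnings.warn("complete separation detected in used-available RSF; "
                      "coefficient unreliable")
    return {
        "beta": beta,
        "se": se,
        "z": float(z),
        "p": p,
        "n_used": n_used,
        "n_available": n_avail,
        "available_weight": w_avail,
        "separation": separated,
    }
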