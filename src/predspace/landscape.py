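"""Analysis-ready habitat map: buffered linear features, a two-class
vegetation mosaic and a Jenks-classified vegetation-cover raster.

The map answers two kinds of question for the selection analyses:
point-level attribution (is this location on a buffered road, on a
hydrological feature, in grassland or woodland, and in which cover class)
and region-level composition (what fraction of a polygon is grassland).
All geometry is planar, in metres; geographic-looking coordinates are
rejected rather than silently reprojected.

Vegetation is an exhaustive two-class partition: grassland polygons are
explicit and woodland is everything else inside the study extent (samphire
shrubland is merged into woodland). Points exactly on a buffer boundary
count as inside (closed-polygon tie rule).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import base as shapely_base
from shapely.geometry import box

from .raster import AsciiGrid
from .species import GRASSLAND, WOODLAND

__all__ = [
    "COVER_LABELS",
    "HabitatAttributes",
    "LandscapeMap",
    "attribute_points",
    "buffer_features",
    "classify_cover",
    "jenks_breaks",
    "region_composition",
]

COVER_LABELS = ("low", "moderate", "high")

ROAD_BUFFER_M = 10.0
HYDRO_BUFFER_M = 20.0


def _looks_geographic(geoms) -> bool:
    """Heuristic guard: lon/lat coordinates masquerading as metres."""
    xmin, ymin, xmax, ymax = shapely.total_bounds(np.asarray(geoms, dtype=object))
    return xmin >= -180 and xmax <= 180 and ymin >= -90 and ymax <= 90


def buffer_features(geoms, width: float) -> shapely_base.BaseGeometry:
    """Union of per-feature buffers of ``width`` metres.

    ``geoms`` is any iterable of shapely lines/polygons in a planar metric
    frame. Coordinates that all fit inside the lon/lat envelope are rejected
    with a message, because a degree-unit buffer of 10 "metres" would be
    silently wrong by five orders of magnitude.
    """
    geoms = [g for g in geoms if g is not None and not g.is_empty]
    if width <= 0:
        raise ValueError(f"buffer width must be positive, got {width}")
    if not geoms:
        return shapely.Polygon()
    if _looks_geographic(geoms):
        raise ValueError(
            "input coordinates fall inside the geographic lon/lat envelope; "
            "buffer widths are metres, so reproject to a planar metric CRS first"
        )
    return shapely.unary_union([g.buffer(width) for g in geoms])


def _class_bounds_from_partition(sorted_values: np.ndarray,
                                 split_idx: list[int]) -> np.ndarray:
    # break value = maximum of each class except the last
    return np.array([sorted_values[i - 1] for i in split_idx])


def jenks_breaks(
    values,
    k: int,
    *,
    subsample: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Jenks natural-breaks classification of a 1-D sample into ``k`` classes.

    Returns the ``k-1`` inner break values (the maximum of each class but
    the last); a value belongs to class ``i`` when ``breaks[i-1] < v <=
    breaks[i]``. Breaks minimise the total within-class sum of squared
    deviations over all contiguous partitions of the sorted sample, found by
    the exact dynamic program (Fisher's method) with O(1) interval costs
    from prefix sums.

    ``subsample`` caps the number of values entering the O(n^2 k) program;
    by default all values are used.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = np.unique(v).size
    if n_distinct < k:
        raise ValueError(
            f"need at least k={k} distinct values, got {n_distinct} distinct "
            f"of {v.size} total"
        )
    if subsample is not None and v.size > subsample:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=subsample, replace=False)
        if np.unique(v).size < k:  # pathological subsample; fall back
            v = np.asarray(values, dtype=float).ravel()
            v = v[np.isfinite(v)]
    v = np.sort(v)
    n = v.size

    s1 = np.concatenate(([0.0], np.cumsum(v)))
    s2 = np.concatenate(([0.0], np.cumsum(v * v)))

    def ssq(i: np.ndarray, j: int) -> np.ndarray:
        # within-class SSQ of v[i:j+1] for vector of starts i (inclusive)
        cnt = j + 1 - i
        tot = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - tot * tot / cnt

    # D[c, j] = optimal cost of splitting v[0:j+1] into c+1 classes
    D = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    ends = np.arange(n)
    cnt = ends + 1
    D[0] = (s2[1:] - s1[1:] ** 2 / cnt)  # one class covering v[0:j+1]
    for c in range(1, k):
        for j in range(c, n):
            starts = np.arange(c, j + 1)
            cost = D[c - 1, starts - 1] + ssq(starts, j)
            best = int(np.argmin(cost))
            D[c, j] = cost[best]
            back[c, j] = starts[best]

    splits: list[int] = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        start = back[c, j]
        splits.append(start)
        j = start - 1
    splits.reverse()
    return _class_bounds_from_partition(v, splits)


def jenks_breaks_bruteforce(values, k: int) -> np.ndarray:
    """Exhaustive-enumeration oracle over all contiguous partitions.

    Exponentially many partitions; intended for n <= 15, k <= 4 only.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = v.size
    best_cost = np.inf
    best_splits: tuple[int, ...] = ()
    for splits in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + splits + (n,)
        cost = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = v[a:b]
            cost += float(np.sum((seg - seg.mean()) ** 2))
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_splits = splits
    return _class_bounds_from_partition(v, list(best_splits))


def classify_cover(raster: AsciiGrid, breaks) -> tuple[np.ndarray, dict]:
    """Label raster cells {0: low, 1: moderate, 2: high} given two breaks.

    A cell is low when ``value <= breaks[0]``, moderate when ``breaks[0] <
    value <= breaks[1]`` and high otherwise. Non-finite/NODATA cells get
    label -1 and are counted in the report but excluded from proportions.

    Returns ``(classes, report)`` where report carries the class proportions
    and the missing-cell count.
    """
    b1, b2 = float(breaks[0]), float(breaks[1])
    if not b1 < b2:
        raise ValueError(f"breaks must be strictly increasing, got ({b1}, {b2})")
    valid = raster.mask_valid()
    vals = raster.values
    classes = np.full(vals.shape, -1, dtype=int)
    classes[valid & (vals <= b1)] = 0
    classes[valid & (vals > b1) & (vals <= b2)] = 1
    classes[valid & (vals > b2)] = 2
    n_valid = int(valid.sum())
    props = {
        lab: (float(np.sum(classes == i)) / n_valid if n_valid else np.nan)
        for i, lab in enumerate(COVER_LABELS)
    }
    report = {"proportions": props, "n_missing": int((~valid).sum()),
              "n_valid": n_valid, "breaks": (b1, b2)}
    return classes, report


@dataclass(frozen=True)
class HabitatAttributes:
    """Habitat state of a single location."""

    on_road: bool
    on_hydro: bool
    veg: str  # grassland | woodland
    cover: str  # low | moderate | high

    @property
    def road_veg(self) -> str:
        """Four-level road-by-vegetation factor; reference = offroad_grass."""
        part = "onroad" if self.on_road else "offroad"
        veg = "grass" if self.veg == GRASSLAND else "wood"
        return f"{part}_{veg}"


@dataclass
class LandscapeMap:
    """Buffered vector layers + classified cover raster for habitat queries.

    ``grassland`` is an explicit polygon set inside ``study_extent``;
    woodland is its complement (exhaustive 2-class partition). Buffer widths
    used to build ``road_zones`` / ``hydro_zones`` are stored for reporting.
    """

    road_zones: shapely_base.BaseGeometry
    hydro_zones: shapely_base.BaseGeometry
    grassland: shapely_base.BaseGeometry
    study_extent: shapely_base.BaseGeometry
    cover_raster: AsciiGrid
    cover_breaks: tuple[float, float]
    cover_classes: np.ndarray = field(default=None)  # type: ignore[assignment]
    road_buffer_m: float = ROAD_BUFFER_M
    hydro_buffer_m: float = HYDRO_BUFFER_M
    crs_note: str = "planar metric CRS (metres); no datum tracked"

    def __post_init__(self) -> None:
        if self.cover_classes is None:
            self.cover_classes, self.cover_report = classify_cover(
                self.cover_raster, self.cover_breaks
            )
        else:
            _, self.cover_report = classify_cover(
                self.cover_raster, self.cover_breaks
            )
        if not self.study_extent.covers(self.grassland):
            # tolerate tiny numerical overhang from polygon unions
            overhang = self.grassland.difference(self.study_extent).area
            if overhang > 1e-6 * max(self.study_extent.area, 1.0):
                raise ValueError("grassland polygons extend outside study extent")
        for geom in (self.road_zones, self.hydro_zones, self.grassland,
                     self.study_extent):
            shapely.prepare(geom)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.study_extent.bounds

    # -- queries ---------------------------------------------------------

    def contains_points(self, x, y) -> np.ndarray:
        return shapely.intersects_xy(self.study_extent, x, y)

    def attribute_points(self, x, y) -> pd.DataFrame:
        return attribute_points(self, x, y)

    def attribute_point(self, x: float, y: float) -> HabitatAttributes:
        row = attribute_points(self, [x], [y]).iloc[0]
        return HabitatAttributes(
            on_road=bool(row.on_road),
            on_hydro=bool(row.on_hydro),
            veg=row.veg,
            cover=row.cover,
        )

    def composition(self, region) -> dict[str, float]:
        return region_composition(self, region)


def attribute_points(lmap: LandscapeMap, x, y) -> pd.DataFrame:
    """Vectorized habitat attribution of many points.

    Columns: on_road, on_hydro, veg, cover, road_veg. Membership tests use
    ``intersects`` so boundary points count as inside. Raises if any point
    falls outside the study extent (callers decide whether to drop or clip
    beforehand).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    inside = shapely.intersects_xy(lmap.study_extent, x, y)
    if not inside.all():
        n_out = int((~inside).sum())
        raise ValueError(
            f"{n_out} point(s) outside the study extent; drop or clip first"
        )
    on_road = shapely.intersects_xy(lmap.road_zones, x, y)
    on_hydro = shapely.intersects_xy(lmap.hydro_zones, x, y)
    in_grass = shapely.intersects_xy(lmap.grassland, x, y)
    row, col = lmap.cover_raster.cell_index(x, y)
    cls = lmap.cover_classes[row, col]
    cover = np.where(cls >= 0,
                     np.array(COVER_LABELS, dtype=object)[np.clip(cls, 0, 2)],
                     "moderate")  # missing cover cells default to the modal class
    veg = np.where(in_grass, GRASSLAND, WOODLAND)
    road_part = np.where(on_road, "onroad", "offroad")
    veg_part = np.where(in_grass, "grass", "wood")
    road_veg = np.char.add(np.char.add(road_part.astype(str), "_"),
                           veg_part.astype(str))
    return pd.DataFrame(
        {
            "on_road": on_road,
            "on_hydro": on_hydro,
            "veg": veg,
            "cover": cover,
            "road_veg": road_veg,
        }
    )


def region_composition(lmap: LandscapeMap, region) -> dict[str, float]:
    """Area-weighted grassland/woodland proportions of ``region``.

    The region is clipped to the study extent first (habitat is undefined
    beyond it). Proportions sum to 1 within 1e-9.
    """
    clipped = region.intersection(lmap.study_extent)
    area = clipped.area
    if area <= 0:
        raise ValueError("region does not overlap the study extent or has zero area")
    grass = clipped.intersection(lmap.grassland).area / area
    grass = min(max(grass, 0.0), 1.0)
    return {GRASSLAND: grass, WOODLAND: 1.0 - grass}
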