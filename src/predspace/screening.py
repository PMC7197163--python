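"""Quality control of raw GPS fixes and movement classification.

Screening runs in a fixed order — analysis window, speed filter, elevation
filter, movement classification — and is idempotent: re-screening screened
output changes nothing. Each removed fix carries exactly one removal reason.

The speed filter is two-tier. A fix is removed when the straight-line speed
from the previous *retained* fix exceeds the species gallop speed, or when
the speeds both into and out of the fix exceed the trot speed (a pace no
animal sustains across two consecutive intervals). Speeds are recomputed
after every removal so a single bad fix cannot drag its neighbours out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .species import SpeciesPreset, get_preset

__all__ = [
    "ScreeningParams",
    "Track",
    "Step",
    "build_steps",
    "classify_movement",
    "clip_window",
    "elevation_filter",
    "screen_track",
    "speed_filter",
]

STATUS_RAW = "raw"
STATUS_REMOVED_WINDOW = "removed_window"
STATUS_REMOVED_SPEED = "removed_speed"
STATUS_REMOVED_ELEV = "removed_elev"
STATUS_RESTING = "resting"
STATUS_MOVING = "moving"

_RETAINED = (STATUS_RAW, STATUS_RESTING, STATUS_MOVING)


@dataclass(frozen=True)
class ScreeningParams:
    """Thresholds controlling the fix screen; species presets supply defaults.

    gallop/trot speeds in km/h, elevation tolerance and movement threshold
    in metres, release discard and window in hours/days.
    """

    gallop_kmh: float
    trot_kmh: float
    move_threshold_m: float
    elev_tolerance_m: float = 100.0
    release_discard_h: float = 24.0
    window_days: float = 70.0
    window_end: pd.Timestamp | None = None
    # gallop and trot rules applied jointly in one sweep (default) or as
    # two sequential passes (gallop first); results rarely differ
    sequential_speed_rules: bool = False

    def __post_init__(self) -> None:
        for name in ("gallop_kmh", "trot_kmh", "move_threshold_m",
                     "elev_tolerance_m", "release_discard_h", "window_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_species(cls, species: str, **overrides) -> "ScreeningParams":
        p: SpeciesPreset = get_preset(species)
        kwargs = dict(
            gallop_kmh=p.gallop_kmh,
            trot_kmh=p.trot_kmh,
            move_threshold_m=p.move_threshold_m,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class Track:
    """Time-ordered fixes for one animal.

    ``fixes`` columns: animal_id, timestamp (UTC), x, y, elevation, status.
    """

    animal_id: str
    species: str
    sex: str
    fixes: pd.DataFrame
    release_time: pd.Timestamp | None = None
    fix_interval_h: float | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.fixes.copy()
        if "status" not in df.columns:
            df["status"] = STATUS_RAW
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        if not df["timestamp"].is_monotonic_increasing:
            df = df.sort_values("timestamp", kind="stable")
        df = df.reset_index(drop=True)
        if df["timestamp"].duplicated().any():
            raise ValueError(f"duplicate timestamps in track {self.animal_id}")
        ids = df.get("animal_id")
        if ids is not None and ids.nunique() > 1:
            raise ValueError("a Track holds fixes of exactly one animal")
        self.fixes = df
        if self.fix_interval_h is None:
            self.fix_interval_h = get_preset(self.species).fix_interval_h

    @property
    def retained(self) -> pd.DataFrame:
        return self.fixes[self.fixes["status"].isin(_RETAINED)]

    @property
    def moving(self) -> pd.DataFrame:
        return self.fixes[self.fixes["status"] == STATUS_MOVING]

    def with_fixes(self, df: pd.DataFrame, **log) -> "Track":
        new_log = dict(self.log)
        new_log.update(log)
        return Track(
            animal_id=self.animal_id,
            species=self.species,
            sex=self.sex,
            fixes=df,
            release_time=self.release_time,
            fix_interval_h=self.fix_interval_h,
            log=new_log,
        )


def _speeds_kmh(df: pd.DataFrame) -> np.ndarray:
    """Straight-line speed (km/h) from each fix to the next, length n-1."""
    dx = np.diff(df["x"].to_numpy())
    dy = np.diff(df["y"].to_numpy())
    dt_h = np.diff(df["timestamp"].to_numpy().astype("datetime64[s]").astype(float)) / 3600.0
    dist_km = np.hypot(dx, dy) / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt_h > 0, dist_km / dt_h, np.inf)


def clip_window(track: Track, params: ScreeningParams) -> Track:
    """Restrict the track to the pre-baiting analysis window.

    Retains fixes in ``[max(release + discard, window_end - window_days),
    window_end)``; everything else is tagged ``removed_window``. The upper
    bound is exclusive: the baiting period itself is never analysed.
    """
    if params.window_end is None:
        raise ValueError("ScreeningParams.window_end must be set for clip_window")
    end = pd.Timestamp(params.window_end)
    start = end - pd.Timedelta(days=params.window_days)
    if track.release_time is not None:
        release_cut = pd.Timestamp(track.release_time) + pd.Timedelta(
            hours=params.release_discard_h
        )
        start = max(start, release_cut)
    df = track.fixes.copy()
    raw = df["status"].isin(_RETAINED)
    keep = raw & (df["timestamp"] >= start) & (df["timestamp"] < end)
    df.loc[raw & ~keep, "status"] = STATUS_REMOVED_WINDOW
    n_removed = int((raw & ~keep).sum())
    if keep.sum() == 0:
        import warnings

        warnings.warn(f"track {track.animal_id}: no fixes in analysis window")
    return track.with_fixes(df, n_removed_window=n_removed,
                            window=(str(start), str(end)))


def _speed_scan(df: pd.DataFrame, retained_idx: list[int],
                gallop: float, trot: float, use_gallop: bool,
                use_trot: bool) -> int | None:
    """Index (into retained_idx) of the first fix violating a speed rule."""
    sub = df.iloc[retained_idx]
    v = _speeds_kmh(sub)
    n = len(retained_idx)
    for i in range(1, n):
        if use_gallop and v[i - 1] > gallop:
            return i
        if use_trot and i < n - 1 and v[i - 1] > trot and v[i] > trot:
            return i
    return None


def speed_filter(track: Track, params: ScreeningParams) -> Track:
    """Iteratively remove speed-impossible fixes.

    Default joint rule: on each sweep, remove the earliest fix whose
    approach speed exceeds the gallop ceiling or that is both approached
    and left above the trot ceiling, then recompute; repeat to a fixed
    point. ``sequential_speed_rules`` runs a gallop-only pass to fixpoint
    followed by a trot pass instead.
    """
    df = track.fixes.copy()
    retained = [int(i) for i in np.flatnonzero(df["status"].isin(_RETAINED))]
    n_removed = 0

    def run(use_gallop: bool, use_trot: bool) -> None:
        nonlocal n_removed
        while len(retained) >= 2:
            hit = _speed_scan(df, retained, params.gallop_kmh,
                              params.trot_kmh, use_gallop, use_trot)
            if hit is None:
                break
            df.iloc[retained[hit], df.columns.get_loc("status")] = STATUS_REMOVED_SPEED
            del retained[hit]
            n_removed += 1

    if params.sequential_speed_rules:
        run(True, False)
        run(False, True)
    else:
        run(True, True)
    return track.with_fixes(df, n_removed_speed=n_removed)


def elevation_filter(track: Track, ref_elev: float,
                     params: ScreeningParams) -> Track:
    """Drop fixes whose elevation is more than the tolerance from the site
    reference elevation; fixes with missing elevation are retained and
    counted."""
    if not np.isfinite(ref_elev):
        raise ValueError("reference elevation must be finite")
    df = track.fixes.copy()
    raw = df["status"].isin(_RETAINED)
    elev = df["elevation"].astype(float)
    bad = raw & elev.notna() & (
        (elev - ref_elev).abs() > params.elev_tolerance_m
    )
    df.loc[bad, "status"] = STATUS_REMOVED_ELEV
    n_missing = int((raw & elev.isna()).sum())
    return track.with_fixes(df, n_removed_elev=int(bad.sum()),
                            n_missing_elev=n_missing)


def classify_movement(track: Track, params: ScreeningParams) -> Track:
    """Label each retained fix moving/resting by displacement from the
    preceding retained fix (strict ``>`` on the species threshold).

    The first retained fix has no predecessor and is labelled resting.
    Resting fixes are excluded from downstream step-selection.
    """
    df = track.fixes.copy()
    idx = np.flatnonzero(df["status"].isin(_RETAINED))
    if len(idx) <= 1:
        import warnings

        warnings.warn(
            f"track {track.animal_id}: <2 retained fixes, nothing to classify"
        )
        if len(idx) == 1:
            df.iloc[idx[0], df.columns.get_loc("status")] = STATUS_RESTING
        return track.with_fixes(df, prop_moving=np.nan)
    sub = df.iloc[idx]
    disp = np.hypot(np.diff(sub["x"].to_numpy()), np.diff(sub["y"].to_numpy()))
    moving = np.concatenate(([False], disp > params.move_threshold_m))
    col = df.columns.get_loc("status")
    df.iloc[idx[moving], col] = STATUS_MOVING
    df.iloc[idx[~moving], col] = STATUS_RESTING
    prop = float(moving[1:].mean()) if len(moving) > 1 else np.nan
    return track.with_fixes(df, prop_moving=prop)


def screen_track(track: Track, params: ScreeningParams,
                 ref_elev: float | None = None) -> Track:
    """Full screen in the canonical order: window, speed, elevation,
    movement. ``ref_elev=None`` skips the elevation filter."""
    out = track
    if params.window_end is not None:
        out = clip_window(out, params)
    out = speed_filter(out, params)
    if ref_elev is not None:
        out = elevation_filter(out, ref_elev, params)
    out = classify_movement(out, params)
    return out


@dataclass(frozen=True)
class Step:
    """One movement step between consecutive moving fixes on schedule."""

    animal_id: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    x0: float
    y0: float
    x1: float
    y1: float
    length_m: float
    bearing_rad: float  # absolute bearing of this step (math convention)
    turn_rad: float | None  # relative to previous step; None at burst start


def build_steps(track: Track, *, interval_tol_h: float = 0.25) -> list[Step]:
    """Steps between consecutive *moving* fixes one nominal interval apart.

    Consecutive moving fixes whose time difference is within ``interval_tol_h``
    of the nominal fix interval form a step; gaps (missed fixes, removed or
    resting fixes in between) break the sequence so no step spans them.
    Turning angles are defined only where the preceding step exists and ended
    where this one starts; they are wrapped to (-pi, pi].
    """
    mv = track.moving
    steps: list[Step] = []
    if len(mv) < 2:
        return steps
    t = mv["timestamp"].to_numpy()
    x = mv["x"].to_numpy(dtype=float)
    y = mv["y"].to_numpy(dtype=float)
    nominal = track.fix_interval_h
    dt_h = np.diff(t.astype("datetime64[s]").astype(float)) / 3600.0
    on_schedule = np.abs(dt_h - nominal) <= interval_tol_h
    prev_bearing: float | None = None
    prev_end: int | None = None
    for i, ok in enumerate(on_schedule):
        if not ok:
            prev_bearing = None
            prev_end = None
            continue
        dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
        bearing = float(np.arctan2(dy, dx))
        if prev_bearing is not None and prev_end == i:
            turn = (bearing - prev_bearing + np.pi) % (2 * np.pi) - np.pi
            if turn == -np.pi:
                turn = np.pi
            turn = float(turn)
        else:
            turn = None
        steps.append(
            Step(
                animal_id=track.animal_id,
                start_time=pd.Timestamp(t[i]),
                end_time=pd.Timestamp(t[i + 1]),
                x0=float(x[i]), y0=float(y[i]),
                x1=float(x[i + 1]), y1=float(y[i + 1]),
                length_m=float(np.hypot(dx, dy)),
                bearing_rad=bearing,
                turn_rad=turn,
            )
        )
        prev_bearing = bearing
        prev_end = i + 1
    return steps


def screening_report(tracks: list[Track]) -> pd.DataFrame:
    """Per-animal counts by removal reason and proportion moving."""
    rows = []
    for tr in tracks:
        status = tr.fixes["status"]
        rows.append(
            {
                "animal_id": tr.animal_id,
                "species": tr.species,
                "n_fixes": len(tr.fixes),
                "n_removed_window": int((status == STATUS_REMOVED_WINDOW).sum()),
                "n_removed_speed": int((status == STATUS_REMOVED_SPEED).sum()),
                "n_removed_elev": int((status == STATUS_REMOVED_ELEV).sum()),
                "n_resting": int((status == STATUS_RESTING).sum()),
                "n_moving": int((status == STATUS_MOVING).sum()),
                "prop_moving": tr.log.get("prop_moving", np.nan),
            }
        )
    return pd.DataFrame(rows)
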