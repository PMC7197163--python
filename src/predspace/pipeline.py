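"""Staged pipeline over the library: simulate -> screen -> homerange ->
broadscale -> ssf -> autocorr -> report.

Each stage reads the artifacts of the previous stage from the run
directory and writes CSV/GeoJSON/ASCII-grid/JSON outputs plus a log line;
the resolved configuration is written beside the outputs so every run is
self-describing. The defaults reproduce the full synthetic study at a
size that runs end to end in minutes on one CPU.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .autocorr import deviance_residuals, residual_acf, select_lag, thin_and_refit
from .broadscale import availability_region, fit_weighted_rsf, sample_circle_hrs
from .finescale import (
    DESIGN_TERMS,
    build_choice_sets,
    empirical_move_dists,
    estimable_terms,
    feature_correlations,
    fit_clogit,
)
from .homerange import isopleth, kde_ud, reference_bandwidth
from .landscape import LandscapeMap, region_composition
from .raster import AsciiGrid
from .screening import ScreeningParams, build_steps, screen_track, screening_report
from .species import get_preset
from .synthetic import (
    SimAnimalConfig,
    SimLandscapeConfig,
    simulate_landscape,
    simulate_population,
)

log = logging.getLogger("predspace")

STAGES = ["simulate", "screen", "homerange", "broadscale", "ssf",
          "autocorr", "report"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "landscape": {},  # SimLandscapeConfig overrides
    "population": {
        "dingo": {"n_animals": 5, "n_steps": 250},
        "cat": {"n_animals": 6, "n_steps": 250},
    },
    "screening": {"ref_elev_m": 500.0},
    "homerange": {"levels": [0.95, 0.5], "cell_factor": 4.0},
    "broadscale": {"n_available": 1000},
    "ssf": {"n_controls": 20},
    "autocorr": {"max_lag": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def resolve_config(overrides: dict | None = None) -> dict:
    return _merge(DEFAULT_CONFIG, overrides or {})


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing artifact {path}; "
            "run the earlier stages first"
        )
    return path


def _load_landscape(outdir: Path) -> LandscapeMap:
    d = outdir / "landscape"
    roads, _ = pio.read_geojson(_require(d / "roads.geojson", "load"))
    hydro, _ = pio.read_geojson(d / "hydro.geojson")
    grass, _ = pio.read_geojson(d / "grassland.geojson")
    extent, _ = pio.read_geojson(d / "extent.geojson")
    cover = AsciiGrid.read(d / "cover.asc")
    with open(d / "cover_breaks.json") as fh:
        breaks = json.load(fh)["breaks"]
    import shapely

    return LandscapeMap(
        road_zones=shapely.unary_union(roads),
        hydro_zones=shapely.unary_union(hydro),
        grassland=shapely.unary_union(grass),
        study_extent=extent[0],
        cover_raster=cover,
        cover_breaks=tuple(breaks),
    )


def stage_simulate(config: dict, outdir: Path) -> None:
    seed = int(config["seed"])
    lcfg = SimLandscapeConfig(**config["landscape"], seed=seed)
    lmap = simulate_landscape(lcfg)
    d = outdir / "landscape"
    d.mkdir(parents=True, exist_ok=True)
    pio.write_geojson(lmap.road_zones, d / "roads.geojson")
    pio.write_geojson(lmap.hydro_zones, d / "hydro.geojson")
    pio.write_geojson(lmap.grassland, d / "grassland.geojson")
    pio.write_geojson(lmap.study_extent, d / "extent.geojson")
    lmap.cover_raster.write(d / "cover.asc")
    with open(d / "cover_breaks.json", "w") as fh:
        json.dump({"breaks": list(lmap.cover_breaks)}, fh)
    comp = region_composition(lmap, lmap.study_extent)
    comp_row = {
        **comp,
        "road_fraction": lmap.road_zones.area / lmap.study_extent.area,
        "hydro_fraction": lmap.hydro_zones.area / lmap.study_extent.area,
        **{f"cover_{k}": v
           for k, v in lmap.cover_report["proportions"].items()},
    }
    pd.DataFrame([comp_row]).to_csv(d / "composition.csv", index=False)

    tracks, truth = [], {"species": {}}
    for i, (species, pcfg) in enumerate(config["population"].items()):
        acfg = SimAnimalConfig.for_species(
            species, n_steps=int(pcfg.get("n_steps", 250))
        )
        trs, rec = simulate_population(
            lmap, species, int(pcfg["n_animals"]), acfg,
            slope_sd=float(pcfg.get("slope_sd", 0.0)),
            seed=seed + 101 * (i + 1),
        )
        tracks.extend(trs)
        truth["species"][species] = rec
    pio.write_fixes_csv(tracks, outdir / "fixes_raw.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    log.info("simulate: %d tracks on a %s landscape", len(tracks),
             lcfg.extent_m)


def stage_screen(config: dict, outdir: Path) -> None:
    tracks = pio.read_fixes_csv(_require(outdir / "fixes_raw.csv", "screen"))
    ref_elev = float(config["screening"].get("ref_elev_m", 500.0))
    screened = []
    for tr in tracks:
        params = ScreeningParams.for_species(tr.species)
        screened.append(screen_track(tr, params, ref_elev=ref_elev))
    pio.write_fixes_csv(screened, outdir / "fixes_screened.csv")
    report = screening_report(screened)
    report.to_csv(outdir / "screening_report.csv", index=False)
    log.info("screen: removed %d speed, %d elevation fixes",
             report["n_removed_speed"].sum(), report["n_removed_elev"].sum())


def _screened_tracks(outdir: Path, stage: str):
    path = _require(outdir / "fixes_screened.csv", stage)
    return pio.read_fixes_csv(path)


def stage_homerange(config: dict, outdir: Path) -> None:
    tracks = _screened_tracks(outdir, "homerange")
    levels = config["homerange"]["levels"]
    cell_factor = float(config["homerange"]["cell_factor"])
    rows = []
    d = outdir / "homerange"
    d.mkdir(exist_ok=True)
    for tr in tracks:
        pts = tr.retained[["x", "y"]].to_numpy()
        if len(pts) < 5:
            continue
        h = reference_bandwidth(pts)
        ud = kde_ud(pts, h, h / cell_factor)
        for level in levels:
            hr = isopleth(ud, float(level), tr.animal_id)
            rows.append(
                {
                    "animal_id": tr.animal_id,
                    "species": tr.species,
                    "sex": tr.sex,
                    "level": level,
                    "area_ha": hr.area_ha,
                    "bandwidth_m": h,
                    "n_fixes": len(pts),
                }
            )
    pd.DataFrame(rows).to_csv(d / "areas.csv", index=False)
    log.info("homerange: %d isopleths", len(rows))


def stage_broadscale(config: dict, outdir: Path) -> None:
    tracks = _screened_tracks(outdir, "broadscale")
    areas = pd.read_csv(
        _require(outdir / "homerange" / "areas.csv", "broadscale")
    )
    lmap = _load_landscape(outdir)
    n_avail = int(config["broadscale"]["n_available"])
    seed = int(config["seed"])
    d = outdir / "broadscale"
    d.mkdir(exist_ok=True)
    rows = []
    for species in areas["species"].unique():
        preset = get_preset(species)
        sp_tracks = [t for t in tracks if t.species == species]
        fixes = np.vstack(
            [t.retained[["x", "y"]].to_numpy() for t in sp_tracks]
        )
        med = float(
            areas.query("species == @species and level == 0.95")[
                "area_ha"].median()
        )
        region = availability_region(fixes, med, species)
        pio.write_geojson(region.polygon, d / f"region_{species}.geojson")
        avail = sample_circle_hrs(region, lmap, preset.focal_class,
                                  n=n_avail, seed=seed + 7)
        used_rows = []
        for t in sp_tracks:
            pts = t.retained[["x", "y"]].to_numpy()
            if len(pts) < 5:
                continue
            h = reference_bandwidth(pts)
            hr = isopleth(kde_ud(pts, h, h / 4), 0.95, t.animal_id)
            comp = region_composition(lmap, hr.polygons)[preset.focal_class]
            used_rows.append({"composition": comp, "used": True})
        used = pd.DataFrame(used_rows)
        fit = fit_weighted_rsf(used, avail)
        rows.append({"species": species, "focal_class": preset.focal_class,
                     "median_hr_ha": med, "r_median_m": region.r_median_m,
                     **{k: v for k, v in fit.items()}, "seed": seed + 7})
    pd.DataFrame(rows).to_csv(d / "rsf.csv", index=False)
    log.info("broadscale: fitted RSFs for %d species", len(rows))


def stage_ssf(config: dict, outdir: Path) -> None:
    tracks = _screened_tracks(outdir, "ssf")
    lmap = _load_landscape(outdir)
    K = int(config["ssf"]["n_controls"])
    seed = int(config["seed"])
    d = outdir / "ssf"
    d.mkdir(exist_ok=True)
    for species in sorted({t.species for t in tracks}):
        sp_tracks = [t for t in tracks if t.species == species]
        steps = []
        for t in sp_tracks:
            steps.extend(build_steps(t))
        dists = empirical_move_dists(steps, species)
        choices = build_choice_sets(steps, dists, lmap, K=K, seed=seed + 13)
        choices.to_csv(d / f"choices_{species}.csv", index=False)
        corr = feature_correlations(choices)
        corr["matrix"].to_csv(d / f"correlations_{species}.csv")
        terms = estimable_terms(choices, DESIGN_TERMS)
        dropped = sorted(set(DESIGN_TERMS) - set(terms))
        if dropped:
            log.warning("ssf[%s]: dropping terms with no within-stratum "
                        "variation at this run size: %s", species, dropped)
        fit = fit_clogit(choices, terms)
        summary = fit.summary()
        summary.to_csv(d / f"fit_{species}.csv")
        with open(d / f"fit_{species}.txt", "w") as fh:
            fh.write(f"Step-selection fit: {species}\n")
            fh.write(f"n_strata = {fit.n_strata}, "
                     f"loglik = {fit.loglik:.3f}\n\n")
            fh.write(summary.to_string(float_format=lambda v: f"{v:8.4f}"))
            fh.write("\n")
        log.info("ssf[%s]: %d strata", species, fit.n_strata)


def stage_autocorr(config: dict, outdir: Path) -> None:
    d = outdir / "ssf"
    out = outdir / "autocorr"
    out.mkdir(exist_ok=True)
    max_lag = int(config["autocorr"]["max_lag"])
    for path in sorted(d.glob("choices_*.csv")):
        species = path.stem.split("_", 1)[1]
        choices = pd.read_csv(path, parse_dates=["timestamp"])
        fit = fit_clogit(choices, estimable_terms(choices, DESIGN_TERMS))
        interval = get_preset(species).fix_interval_h
        series = deviance_residuals(fit, choices, interval)
        acf = residual_acf(series, max_lag=max_lag)
        lag = select_lag(acf, interval)
        L = lag["lag"] if lag["lag"] else max_lag
        sens = thin_and_refit(choices, L, fit)
        sens["table"].to_csv(out / f"sensitivity_{species}.csv", index=False)
        with open(out / f"lag_{species}.json", "w") as fh:
            json.dump({"lag": lag["lag"], "hours": lag["hours"],
                       "censored": lag["censored"],
                       "acf": list(map(float, acf["acf"])),
                       "bound": acf["bound"]}, fh, indent=1)
        log.info("autocorr[%s]: lag=%s (%s h)", species, lag["lag"],
                 lag["hours"])


def stage_report(config: dict, outdir: Path) -> None:
    areas = pd.read_csv(
        _require(outdir / "homerange" / "areas.csv", "report")
    )
    summary = (
        areas.groupby(["species", "level"])["area_ha"]
        .agg(["count", "median", "min", "max"])
        .reset_index()
    )
    d = outdir / "report"
    d.mkdir(exist_ok=True)
    summary.to_csv(d / "area_summary.csv", index=False)
    coef_frames = []
    for path in sorted((outdir / "ssf").glob("fit_*.csv")):
        species = path.stem.split("_", 1)[1]
        df = pd.read_csv(path, index_col=0)
        df.insert(0, "species", species)
        coef_frames.append(df)
    if coef_frames:
        pd.concat(coef_frames).to_csv(d / "coefficients.csv")
    log.info("report: wrote area summary and coefficient table")


_STAGE_FN = {
    "simulate": stage_simulate,
    "screen": stage_screen,
    "homerange": stage_homerange,
    "broadscale": stage_broadscale,
    "ssf": stage_ssf,
    "autocorr": stage_autocorr,
    "report": stage_report,
}


def run_stage(stage: str, config: dict, outdir: str | Path) -> None:
    """Run one named stage; raises on a missing upstream artifact."""
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = resolve_config(config)
    with open(outdir / "resolved_config.json", "w") as fh:
        json.dump(config, fh, indent=1)
    _STAGE_FN[stage](config, outdir)


def run_all(config: dict | None, outdir: str | Path) -> None:
    for stage in STAGES:
        run_stage(stage, config or {}, outdir)
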