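"""End-to-end demo pipeline: synth → NDVI → calibrate → map → plan → evaluate."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import fit_exponential, predict_biomass
from .config import config_hash, growth_params_from_config, load_config
from .evaluation import PairedSeries, agreement
from .growth import GrowthState, simulate_regrowth
from .ndvi import compute_ndvi, zonal_mean
from .paddocks import write_geojson
from .planner import PaddockState, build_wedge
from .raster import Raster, write_geotiff
from .scene import SceneSpec, generate_grazing_schedule, generate_scene
from .weather import generate_weather


def sample_calibration_plots(ndvi_raster: Raster, truth: Raster, n_plots: int, seed: int):
    """Draw plot-scale calibration pairs (NDVI, true biomass) at random pixels."""
    rng = np.random.default_rng(seed)
    grid = ndvi_raster.data[0]
    mask = ndvi_raster.mask(0)
    rows, cols = np.where(~mask)
    if len(rows) < n_plots:
        raise ValueError("not enough valid pixels for the requested number of plots")
    pick = rng.choice(len(rows), size=n_plots, replace=False)
    return grid[rows[pick], cols[pick]], truth.data[0][rows[pick], cols[pick]]


def classify_biomass(biomass: Raster, edges) -> Raster:
    """Class raster from biomass band edges (e.g. <500 / 500-1700 / 1700-2800 / >2800)."""
    classes = np.digitize(biomass.data[0], bins=list(edges)).astype(float)
    classes[biomass.mask(0)] = np.nan
    return Raster(
        data=classes[None],
        transform=biomass.transform,
        crs=biomass.crs,
        band_names=("biomass_class",),
        meta={"class_edges_kg_ha": list(edges)},
    )


def run_demo(out_dir, seed: int = 0, config_path=None, overrides=None) -> dict:
    """Run the full pipeline on a synthetic platform; returns the manifest.

    Writes: paddocks.geojson, ndvi.tif, biomass.tif, biomass_classes.tif,
    plan.csv, evaluation.json, manifest.json under ``out_dir``.
    """
    cfg = load_config(config_path, overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = cfg["scene"]
    spec = SceneSpec(
        n_paddocks=int(sc["n_paddocks"]),
        paddock_dims=tuple(sc["paddock_dims"]),
        pixel_size=float(sc["pixel_size"]),
        biomass_field=(float(sc["biomass_mean"]), float(sc["correlation_length"]), float(sc["biomass_cv"])),
        true_calibration=(float(sc["true_alpha"]), float(sc["true_beta"])),
        noise_cv=float(sc["noise_cv"]),
        seed=seed,
    )
    scene, pmap, truth = generate_scene(spec)
    ndvi = compute_ndvi(scene)

    ndvi_cal, biomass_cal = sample_calibration_plots(ndvi, truth, n_plots=72, seed=seed + 1)
    cal = fit_exponential(ndvi_cal, biomass_cal)

    pred, _ = predict_biomass(cal, ndvi.data[0], saturation_threshold=cfg["ndvi_saturation"])
    biomass_map = ndvi.with_data(pred[None], band_names=("biomass_kg_ha",))
    class_map = classify_biomass(biomass_map, cfg["map_bands"])

    uav = zonal_mean(biomass_map, pmap)
    true_means = zonal_mean(truth, pmap)
    report = agreement(
        PairedSeries(
            reference=true_means["mean"].to_numpy(),
            estimate=uav["mean"].to_numpy(),
            ids=list(uav["paddock_id"]),
        )
    )

    weather = generate_weather(30, "summer", seed=seed + 2)
    params = growth_params_from_config(cfg)
    mean_state = GrowthState(date=None, biomass=float(uav["mean"].mean()), lai=1.5)
    traj = simulate_regrowth(mean_state, weather, params, n_days=14)
    growth_rate = traj.mean_rate

    schedule = generate_grazing_schedule(pmap, seed=seed + 3)
    sched = schedule.set_index("paddock_id")["days_of_regrowth"]
    states = [
        PaddockState(
            paddock_id=r["paddock_id"],
            uav_biomass=float(r["mean"]),
            days_of_regrowth=float(sched[r["paddock_id"]]),
            species=r["species"],
            area_ha=float(r["area_ha"]),
        )
        for _, r in uav.iterrows()
    ]
    plan = build_wedge(
        states,
        growth_rate,
        target=cfg["planner"]["pre_grazing_target"],
        post_target=cfg["planner"]["post_grazing_target"],
    )

    write_geojson(out / "paddocks.geojson", pmap)
    write_geotiff(out / "ndvi.tif", ndvi)
    write_geotiff(out / "biomass.tif", biomass_map)
    write_geotiff(out / "biomass_classes.tif", class_map)
    plan.to_csv(out / "plan.csv", index=False)
    eval_doc = {
        "paddock_agreement": report.to_dict(),
        "calibration": {"alpha": cal.alpha, "beta": cal.beta, "r2": cal.r2, "n": cal.n},
        "growth_rate_kg_ha_d": growth_rate,
        "recommended_extension_days": plan.attrs["recommended_extension_days"],
        "mean_cover_kg_ha": plan.attrs["mean_cover"],
        "low_cover_warning": plan.attrs["low_cover_warning"],
    }
    with open(out / "evaluation.json", "w") as fh:
        json.dump(eval_doc, fh, indent=1)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "artifacts": [
            "paddocks.geojson",
            "ndvi.tif",
            "biomass.tif",
            "biomass_classes.tif",
            "plan.csv",
            "evaluation.json",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {**manifest, "evaluation": eval_doc}
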