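"""End-to-end pipeline: simulate -> NDVI -> segment -> fuse -> krige -> advise -> route.

Configuration is a single schema-validated document
(:class:`PipelineConfig`); unknown keys are rejected.  A single global
seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])``, so rerunning
any stage in isolation reproduces the full run.  The run manifest
records config, per-stage seeds, outputs and SHA-256 checksums and
contains nothing time-dependent, so identical configs produce
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import advisor, fusion, kriging, segmentation, simulate
from .ndvi import ndvi as compute_ndvi
from .errors import ConfigError
from .geodata import write_ndvi_map, write_raster, write_sensor_table

STAGES = ("simulate", "ndvi", "segment", "fuse", "krige", "advise", "route")


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    field_width_m: float = 60.0
    field_height_m: float = 40.0
    row_spacing_m: float = 2.0
    canopy_width_m: float = 1.0
    row_azimuth_deg: float = 0.0
    vigour_base: float = 0.7
    vigour_gradient: tuple[float, float] = (0.002, 0.001)
    soil_ndvi_mean: float = 0.15
    moisture_mean: float = 0.30
    moisture_sd: float = 0.06
    moisture_range_m: float = 30.0
    noise_sd: float = 0.01
    ground_res_m: float = 0.05
    uav_gsd_m: float = 0.05
    satellite_gsd_m: float = 10.0
    n_sensors: int = 6
    sensor_noise_sd: float = 0.01
    n_covariate_points: int = 60


class SegmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    method: Literal["otsu", "fixed"] = "otsu"
    threshold: float | None = None


class FuseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    which: list[Literal["all", "vin", "int"]] = ["all", "vin", "int"]
    denominator: Literal["restricted", "printed"] = "restricted"
    min_coverage: float = 0.95


class KrigeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: Literal["exponential", "spherical", "gaussian"] = "exponential"
    nugget_grid: list[float] = [0.0, 1e-4]
    sill_grid: list[float] = [2e-3, 4e-3]
    range_grid_m: list[float] = [15.0, 30.0, 60.0]
    raw_coeff_grid: list[float] = [0.8, 1.0, 1.2]
    ndvi_coeff_grid: list[float] = [0.0]
    intercept_grid: list[float] = [0.0]


class AdviseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    moisture_min: float = 0.25
    ndvi_min: float = 0.45


class RouteConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pop_size: int = 100
    generations: int = 300
    crossover_rate: float = 0.9
    mutation_rate: float = 0.8
    w_dist: float = 1.0
    w_priority: float = 0.0
    depot: tuple[float, float] | None = None  # default: scene NW corner


class PipelineConfig(BaseModel):
    """Schema-validated configuration for the full pipeline."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    output_dir: str = "agrifuse_run"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    segment: SegmentConfig = Field(default_factory=SegmentConfig)
    fuse: FuseConfig = Field(default_factory=FuseConfig)
    krige: KrigeConfig = Field(default_factory=KrigeConfig)
    advise: AdviseConfig = Field(default_factory=AdviseConfig)
    route: RouteConfig = Field(default_factory=RouteConfig)

    @model_validator(mode="after")
    def _check_dependencies(self):
        needs_mask = any(w in ("vin", "int") for w in self.fuse.which)
        if needs_mask and not self.segment.enabled:
            raise ConfigError(
                "fuse.which includes 'vin'/'int' but segmentation is disabled"
            )
        return self


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk).

    On a stage failure the manifest is still written, recording the
    completed stages and the failing stage with its error.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, files: dict[str, str]) -> None:
        manifest["stages"][stage] = "complete"
        for key, path in files.items():
            manifest["outputs"][key] = {
                "path": os.path.relpath(path, out),
                "sha256": _sha256(path),
            }

    try:
        state = _run_stages(config, out, manifest, record)
    except Exception as exc:  # record partial completion, then re-raise
        failing = next((s for s in STAGES if s not in manifest["stages"]), "unknown")
        manifest["stages"][failing] = f"failed: {type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: str) -> None:
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _run_stages(config: PipelineConfig, out: str, manifest: dict, record) -> dict:
    sc = config.simulate

    # -- simulate -----------------------------------------------------------
    sim_cfg = simulate.SimConfig(
        field_width_m=sc.field_width_m,
        field_height_m=sc.field_height_m,
        row_spacing_m=sc.row_spacing_m,
        canopy_width_m=sc.canopy_width_m,
        row_azimuth_deg=sc.row_azimuth_deg,
        vigour_base=sc.vigour_base,
        vigour_gradient=tuple(sc.vigour_gradient),
        soil_ndvi_mean=sc.soil_ndvi_mean,
        moisture_mean=sc.moisture_mean,
        moisture_sd=sc.moisture_sd,
        moisture_range_m=sc.moisture_range_m,
        noise_sd=sc.noise_sd,
        ground_res_m=sc.ground_res_m,
        seed=stage_seed(config.seed, "simulate"),
    )
    scene = simulate.simulate_scene(sim_cfg)
    uav = simulate.render_uav(scene, sc.uav_gsd_m)
    sat = simulate.render_satellite(scene, sc.satellite_gsd_m)
    sensor_locs = simulate.random_locations_in_scene(
        scene, sc.n_sensors, seed=stage_seed(config.seed, "simulate") + 1
    )
    sensors = simulate.sample_sensors(
        scene, sensor_locs, noise_sd=sc.sensor_noise_sd,
        seed=stage_seed(config.seed, "simulate") + 2,
    )
    uav_path = os.path.join(out, "uav.tif")
    sat_path = os.path.join(out, "satellite.tif")
    sensors_path = os.path.join(out, "sensors.csv")
    write_raster(uav, uav_path)
    write_raster(sat, sat_path)
    write_sensor_table(sensors, sensors_path)
    record("simulate", {"uav": uav_path, "satellite": sat_path, "sensors": sensors_path})

    # -- ndvi ---------------------------------------------------------------
    uav_ndvi = compute_ndvi(uav)
    sat_ndvi = fusion.ndvi_sat(sat)
    p_uav = os.path.join(out, "ndvi_uav_native.tif")
    p_sat = os.path.join(out, "ndvi_sat.tif")
    write_ndvi_map(uav_ndvi, p_uav)
    write_ndvi_map(sat_ndvi, p_sat)
    record("ndvi", {"ndvi_uav_native": p_uav, "ndvi_sat": p_sat})

    # -- segment ------------------------------------------------------------
    partition = None
    if config.segment.enabled:
        partition = segmentation.segment_canopy(
            uav_ndvi, method=config.segment.method, threshold=config.segment.threshold
        )
        mask_path = os.path.join(out, "canopy_mask.tif")
        from .geodata import MultispectralRaster  # local import to avoid cycle noise

        mask_raster = MultispectralRaster(
            grid=partition.grid,
            bands={"vin": partition.vin_mask.astype(float)},
            radiometry="dn",
        )
        write_raster(mask_raster, mask_path)
        record("segment", {"canopy_mask": mask_path})
    else:
        manifest["stages"]["segment"] = "skipped"

    # -- fuse ---------------------------------------------------------------
    corr = fusion.match_footprints(sat.grid, uav.grid)
    fused = {}
    files = {}
    for which in config.fuse.which:
        agg = fusion.aggregate_ndvi(
            uav, corr, mask=partition, which=which,
            denominator=config.fuse.denominator,
            min_coverage=config.fuse.min_coverage,
        )
        fused[which] = agg
        path = os.path.join(out, f"ndvi_{'uav' if which == 'all' else which}.tif")
        write_ndvi_map(agg, path)
        files[f"ndvi_{which}"] = path
    stats = {
        which: fusion.compare_maps(sat_ndvi, agg) for which, agg in fused.items()
    }
    stats_path = os.path.join(out, "fusion_stats.json")
    with open(stats_path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["fusion_stats"] = stats_path
    record("fuse", files)

    # -- krige --------------------------------------------------------------
    kc = config.krige
    kseed = stage_seed(config.seed, "krige")
    cov_locs = simulate.random_locations_in_scene(scene, sc.n_covariate_points, seed=kseed)
    rng = np.random.default_rng(kseed + 1)
    g = scene.grid
    cov_values = []
    for lat, lon in cov_locs:
        u = min(int((g.lat_origin - lat) / g.pixel_height), g.n_rows - 1)
        v = min(int((lon - g.lon_origin) / g.pixel_width), g.n_cols - 1)
        cov_values.append(
            {
                # a raw capacitance-style survey reading: true moisture + noise
                "moisture_raw": float(
                    np.clip(scene.moisture_field[u, v] + rng.normal(0, sc.sensor_noise_sd),
                            0, 0.57)
                ),
                "ndvi": float(uav_ndvi.values[
                    min(int(u * g.pixel_height / uav.grid.pixel_height), uav.grid.n_rows - 1),
                    min(int(v * g.pixel_width / uav.grid.pixel_width), uav.grid.n_cols - 1),
                ]),
            }
        )
    vgm_grid = [
        kriging.VariogramModel(kc.family, n, s, r)
        for n in kc.nugget_grid
        for s in kc.sill_grid
        for r in kc.range_grid_m
    ]
    coeff_grid = [
        {"moisture_raw": c_raw, "ndvi": c_ndvi}
        for c_raw in kc.raw_coeff_grid
        for c_ndvi in kc.ndvi_coeff_grid
    ]
    calib = kriging.calibrate_against_sensors(
        cov_locs, cov_values, sensors, vgm_grid, coeff_grid, kc.intercept_grid
    )
    samples = kriging.estimate_moisture_at_points(
        cov_locs, cov_values, calib.coefficients, calib.intercept
    )
    sat_lats, sat_lons = sat.grid.center_arrays()
    targets = [(la, lo) for la in sat_lats for lo in sat_lons]
    preds = kriging.krige(samples, calib.variogram, targets)
    moisture_plane = np.array([e for e, _ in preds]).reshape(sat.grid.shape)
    variance_plane = np.array([v for _, v in preds]).reshape(sat.grid.shape)
    from .geodata import MultispectralRaster

    moist_path = os.path.join(out, "moisture.tif")
    write_raster(
        MultispectralRaster(
            grid=sat.grid,
            bands={"vwc": moisture_plane, "variance": variance_plane},
            radiometry="dn",
        ),
        moist_path,
    )
    calib_path = os.path.join(out, "calibration.json")
    with open(calib_path, "w") as fh:
        json.dump(
            {
                "variogram": {
                    "family": calib.variogram.family,
                    "nugget": calib.variogram.nugget,
                    "sill": calib.variogram.sill,
                    "range_m": calib.variogram.range_m,
                },
                "coefficients": calib.coefficients,
                "intercept": calib.intercept,
                "mae": calib.mae,
                "residuals": calib.residuals.tolist(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    record("krige", {"moisture": moist_path, "calibration": calib_path})

    # -- advise -------------------------------------------------------------
    vin_map = fused.get("vin", fused.get("all"))
    rules = advisor.AlertRules(
        moisture_min=config.advise.moisture_min, ndvi_min=config.advise.ndvi_min
    )
    points = advisor.detect_attention_points(vin_map, moisture_plane, rules)
    ap_path = os.path.join(out, "attention_points.geojson")
    with open(ap_path, "w") as fh:
        json.dump(advisor.attention_points_geojson(points), fh, indent=2, sort_keys=True)
        fh.write("\n")
    alerts_path = os.path.join(out, "alerts.jsonl")
    with open(alerts_path, "w") as fh:
        for p in points:
            for reason in sorted(p.reasons):
                fh.write(
                    json.dumps(
                        {"reason": reason, "cell": list(p.cell), "severity": p.severity},
                        sort_keys=True,
                    )
                    + "\n"
                )
    record("advise", {"attention_points": ap_path, "alerts": alerts_path})

    # -- route --------------------------------------------------------------
    rc = config.route
    depot = rc.depot or (scene.grid.lat_origin, scene.grid.lon_origin)
    ga = advisor.GAConfig(
        pop_size=rc.pop_size,
        generations=rc.generations,
        crossover_rate=rc.crossover_rate,
        mutation_rate=rc.mutation_rate,
        seed=stage_seed(config.seed, "route"),
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        plan = advisor.plan_route(points, depot, ga, weights=(rc.w_dist, rc.w_priority))
    route_path = os.path.join(out, "route.geojson")
    with open(route_path, "w") as fh:
        json.dump(advisor.route_geojson(plan), fh, indent=2, sort_keys=True)
        fh.write("\n")
    record("route", {"route": route_path})

    return {"scene": scene, "plan": plan}
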