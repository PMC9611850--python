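"""Synthetic vineyard scene generator.

Emulates the study geometry of a south-Italian hillside vineyard: vine
rows 2 m apart with a ~1 m wide canopy strip, imaged at centimetric UAV
resolution (5 cm GSD) and decametric satellite resolution (10 m GSD).
The simulator produces a ground-truth scene — canopy mask, vigour field
in [0, 1], volumetric soil-moisture field — and renders it to
multispectral rasters at arbitrary coarser GSDs by area-weighted
averaging of reflectance, which is exactly the sub-pixel mixing process
that biases decametric NDVI in row crops.

Reflectance model (linear in vigour):

    canopy:  red = 0.18 - 0.12 * vigour     nir = 0.25 + 0.55 * vigour
    soil:    nir = 0.30, red chosen so soil NDVI equals ``soil_ndvi_mean``

so canopy NDVI spans roughly 0.3-0.86 over vigour in [0, 1] and soil
sits near 0.15 — the vine/soil contrast a threshold segmentation relies
on.  The mapping vigour -> canopy NDVI is strictly increasing.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import BoundsError, ConfigError, ResolutionError
from .geodata import (
    GeoGrid,
    MultispectralRaster,
    SensorReading,
    VWC_MAX,
    meters_per_degree,
)

CANOPY_RED_0, CANOPY_RED_SLOPE = 0.18, -0.12
CANOPY_NIR_0, CANOPY_NIR_SLOPE = 0.25, 0.55
SOIL_NIR = 0.30


def canopy_reflectance(vigour: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(red, nir) reflectance of canopy at the given vigour."""
    v = np.asarray(vigour, dtype=float)
    return CANOPY_RED_0 + CANOPY_RED_SLOPE * v, CANOPY_NIR_0 + CANOPY_NIR_SLOPE * v


def soil_reflectance(soil_ndvi: float) -> tuple[float, float]:
    """(red, nir) of bare/grassed inter-row soil yielding the given NDVI."""
    red = SOIL_NIR * (1.0 - soil_ndvi) / (1.0 + soil_ndvi)
    return red, SOIL_NIR


def vigour_for_canopy_ndvi(ndvi: float) -> float:
    """Invert the canopy reflectance model: vigour giving a target canopy NDVI."""
    # (nir - red)/(nir + red) = ndvi, both linear in vigour
    a = CANOPY_NIR_0 - CANOPY_RED_0 - ndvi * (CANOPY_NIR_0 + CANOPY_RED_0)
    b = CANOPY_NIR_SLOPE - CANOPY_RED_SLOPE - ndvi * (CANOPY_NIR_SLOPE + CANOPY_RED_SLOPE)
    return -a / b


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters; defaults reproduce the study-site geometry."""

    field_width_m: float = 100.0
    field_height_m: float = 80.0
    row_spacing_m: float = 2.0
    canopy_width_m: float = 1.0
    row_azimuth_deg: float = 0.0
    vigour_base: float = 0.7
    vigour_gradient: tuple[float, float] = (0.0, 0.0)  # per metre (east, north)
    soil_ndvi_mean: float = 0.15
    moisture_mean: float = 0.30
    moisture_sd: float = 0.06
    moisture_range_m: float = 30.0
    noise_sd: float = 0.0
    ground_res_m: float = 0.05
    lat_origin: float = 37.93
    lon_origin: float = 15.93
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.canopy_width_m < self.row_spacing_m):
            raise ConfigError(
                "canopy width must be positive and narrower than the row spacing"
            )
        if not (0 < self.vigour_base <= 1):
            raise ConfigError("vigour_base must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.ground_res_m <= 0:
            raise ConfigError("ground resolution must be positive")


@dataclass
class VineyardScene:
    """Ground truth at the simulator's native (sub-UAV) resolution."""

    config: SimConfig
    grid: GeoGrid
    canopy_mask: np.ndarray
    vigour_field: np.ndarray
    moisture_field: np.ndarray
    red: np.ndarray
    nir: np.ndarray

    @property
    def ground_res_m(self) -> float:
        return self.config.ground_res_m

    def true_canopy_ndvi(self) -> np.ndarray:
        red, nir = canopy_reflectance(self.vigour_field)
        return (nir - red) / (nir + red)


def _smooth_field(shape, rng, correlation_px: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    white = rng.standard_normal(shape)
    if correlation_px <= 0:
        return white
    f = ndimage.gaussian_filter(white, sigma=correlation_px, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_scene(config: SimConfig) -> VineyardScene:
    """Generate a deterministic synthetic vineyard scene.

    Canopy strips of ``canopy_width_m`` run along ``row_azimuth_deg``
    (degrees clockwise from north) every ``row_spacing_m``; vigour is
    ``vigour_base`` plus a linear trend and smooth noise, clipped to
    [0, 1]; moisture is a smoothed Gaussian random field with the
    configured correlation length, clipped to the sensor's [0, 0.57]
    VWC calibration range.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    res = c.ground_res_m
    n_rows = max(1, round(c.field_height_m / res))
    n_cols = max(1, round(c.field_width_m / res))

    # local metric coordinates of pixel centres: x east, y north (m)
    x = (np.arange(n_cols) + 0.5) * res
    y_from_top = (np.arange(n_rows) + 0.5) * res
    y = c.field_height_m - y_from_top  # northing increases upward
    xx, yy = np.meshgrid(x, y)

    # signed distance across rows: coordinate along the row normal
    theta = math.radians(c.row_azimuth_deg)
    s = xx * math.cos(theta) - yy * math.sin(theta)
    phase = np.mod(s, c.row_spacing_m)
    canopy = phase < c.canopy_width_m

    vigour = (
        c.vigour_base
        + c.vigour_gradient[0] * xx
        + c.vigour_gradient[1] * yy
    )
    if c.noise_sd > 0:
        vigour = vigour + c.noise_sd * _smooth_field(
            (n_rows, n_cols), rng, correlation_px=1.0 / res * 0.5
        )
    vigour = np.clip(vigour, 0.0, 1.0)

    corr_px = c.moisture_range_m / res
    moisture = c.moisture_mean + c.moisture_sd * _smooth_field(
        (n_rows, n_cols), rng, corr_px
    )
    moisture = np.clip(moisture, 0.0, VWC_MAX)

    red_can, nir_can = canopy_reflectance(vigour)
    red_soil, nir_soil = soil_reflectance(c.soil_ndvi_mean)
    red = np.where(canopy, red_can, red_soil)
    nir = np.where(canopy, nir_can, nir_soil)
    if c.noise_sd > 0:
        red = np.clip(red + rng.normal(0.0, c.noise_sd, red.shape), 0.0, 1.0)
        nir = np.clip(nir + rng.normal(0.0, c.noise_sd, nir.shape), 0.0, 1.0)

    m_lat, m_lon = meters_per_degree(c.lat_origin)
    grid = GeoGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        lat_origin=c.lat_origin,
        lon_origin=c.lon_origin,
        pixel_height=res / m_lat,
        pixel_width=res / m_lon,
    )
    return VineyardScene(
        config=c,
        grid=grid,
        canopy_mask=canopy,
        vigour_field=vigour,
        moisture_field=moisture,
        red=red,
        nir=nir,
    )


def _block_reduce_mean(plane: np.ndarray, factor: int) -> np.ndarray:
    """Mean over factor x factor blocks; partial edge blocks average what they cover."""
    n, m = plane.shape
    out_n = -(-n // factor)
    out_m = -(-m // factor)
    row_idx = np.arange(0, n, factor)
    col_idx = np.arange(0, m, factor)
    summed = np.add.reduceat(np.add.reduceat(plane, row_idx, axis=0), col_idx, axis=1)
    rows_per = np.minimum(factor, n - row_idx)
    cols_per = np.minimum(factor, m - col_idx)
    counts = rows_per[:, None] * cols_per[None, :]
    assert summed.shape == (out_n, out_m)
    return summed / counts


def _render(scene: VineyardScene, gsd_m: float) -> MultispectralRaster:
    res = scene.ground_res_m
    if gsd_m < res - 1e-12:
        raise ResolutionError(
            f"requested GSD {gsd_m} m finer than ground truth {res} m"
        )
    factor_f = gsd_m / res
    factor = round(factor_f)
    if abs(factor_f - factor) > 1e-6:
        raise ResolutionError(
            f"GSD {gsd_m} m must be an integer multiple of the ground resolution {res} m"
        )
    red = _block_reduce_mean(scene.red, factor)
    nir = _block_reduce_mean(scene.nir, factor)
    g = scene.grid
    grid = GeoGrid(
        n_rows=red.shape[0],
        n_cols=red.shape[1],
        lat_origin=g.lat_origin,
        lon_origin=g.lon_origin,
        pixel_height=g.pixel_height * factor,
        pixel_width=g.pixel_width * factor,
    )
    return MultispectralRaster(grid=grid, bands={"red": red, "nir": nir})


def render_uav(scene: VineyardScene, gsd_m: float = 0.05) -> MultispectralRaster:
    """Render the scene at centimetric UAV resolution (default 5 cm GSD)."""
    return _render(scene, gsd_m)


def render_satellite(scene: VineyardScene, gsd_m: float = 10.0) -> MultispectralRaster:
    """Render at decametric satellite resolution (default 10 m GSD).

    Each output pixel is the area-weighted mean *reflectance* of the
    canopy and soil it covers; its NDVI is therefore the index of mixed
    reflectances, not the mean of sub-pixel NDVIs — the decametric
    mixing artefact the UAV decomposition corrects.
    """
    return _render(scene, gsd_m)


def render_ground_truth_masks(scene: VineyardScene, gsd_m: float) -> np.ndarray:
    """Canopy fraction per output pixel at the requested GSD (for oracle tests)."""
    res = scene.ground_res_m
    factor = round(gsd_m / res)
    return _block_reduce_mean(scene.canopy_mask.astype(float), factor)


def sample_sensors(
    scene: VineyardScene,
    locations: list[tuple[float, float]],
    noise_sd: float = 0.0,
    seed: int | None = None,
    timestamp: str = "2021-07-28T09:40:00Z",
) -> list[SensorReading]:
    """Simulate soil-moisture probes at (lat, lon) locations.

    The reading is the moisture field at the nearest ground-truth pixel
    plus Gaussian noise, clipped to the probe's [0, 0.57] VWC range.
    """
    rng = np.random.default_rng(seed)
    g = scene.grid
    lat_min, lat_max, lon_min, lon_max = g.extent
    out = []
    for lat, lon in locations:
        if not (lat_min <= lat <= lat_max and lon_min <= lon <= lon_max):
            raise BoundsError(f"sensor location ({lat}, {lon}) outside scene extent")
        u = min(int((g.lat_origin - lat) / g.pixel_height), g.n_rows - 1)
        v = min(int((lon - g.lon_origin) / g.pixel_width), g.n_cols - 1)
        value = float(scene.moisture_field[u, v])
        if noise_sd > 0:
            value += float(rng.normal(0.0, noise_sd))
        value = float(np.clip(value, 0.0, VWC_MAX))
        out.append(
            SensorReading(
                lat=lat, lon=lon, timestamp=timestamp, kind="soil_moisture_vwc", value=value
            )
        )
    return out


def random_locations_in_scene(
    scene: VineyardScene, n: int, seed: int | None = None, margin_frac: float = 0.05
) -> list[tuple[float, float]]:
    """n uniform random (lat, lon) points inside the scene, away from the edge."""
    rng = np.random.default_rng(seed)
    lat_min, lat_max, lon_min, lon_max = scene.grid.extent
    dlat = (lat_max - lat_min) * margin_frac
    dlon = (lon_max - lon_min) * margin_frac
    lats = rng.uniform(lat_min + dlat, lat_max - dlat, n)
    lons = rng.uniform(lon_min + dlon, lon_max - dlon, n)
    return list(zip(lats.tolist(), lons.tolist()))
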