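"""Georeferenced raster and point-sensor data model with GeoTIFF/CSV I/O.

All coordinates are geographic WGS84 degrees.  Rasters are regular
north-up grids addressed 0-based, row-major, origin at the upper-left
corner: latitude decreases with row index, longitude increases with
column index.  Nodata is NaN in memory and a declared fill value on
disk.

GeoTIFF files are read and written through :mod:`tifffile`, carrying the
standard georeferencing tags (ModelPixelScale, ModelTiepoint and a
GeoKeyDirectory declaring EPSG:4326).  Band names, radiometry and the
nodata fill value travel in the ImageDescription tag as JSON; an
optional sidecar ``<path>.bands.json`` may override the band map.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    BandMissingError,
    RadiometryError,
    SensorKindError,
    SensorRangeError,
    UnsupportedCRSError,
)

# physical ranges enforced on sensor readings
VWC_MAX = 0.57  # capacitance probe calibration tops out at 57% VWC
SENSOR_KINDS = frozenset(
    {"soil_moisture_vwc", "temperature", "humidity", "pressure", "leaf_wetness", "ph"}
)

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
# GeoKey ids
_KEY_MODEL_TYPE = 1024  # 2 = geographic
_KEY_RASTER_TYPE = 1025  # 1 = PixelIsArea
_KEY_GEOGRAPHIC_TYPE = 2048  # 4326 = WGS84

EARTH_RADIUS_M = 6_371_008.8


def meters_per_degree(lat_deg: float) -> tuple[float, float]:
    """(metres per degree latitude, metres per degree longitude) at ``lat_deg``."""
    m_per_deg_lat = math.pi * EARTH_RADIUS_M / 180.0
    return m_per_deg_lat, m_per_deg_lat * math.cos(math.radians(lat_deg))


@dataclass(frozen=True)
class GeoGrid:
    """Regular north-up WGS84 grid.

    ``lat_origin``/``lon_origin`` locate the upper-left *corner* of pixel
    (0, 0); ``pixel_height``/``pixel_width`` are positive degree
    magnitudes (latitude decreases going down rows).
    """

    n_rows: int
    n_cols: int
    lat_origin: float
    lon_origin: float
    pixel_height: float
    pixel_width: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.pixel_height <= 0 or self.pixel_width <= 0:
            raise ValueError("pixel sizes must be positive degree magnitudes")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_corner(self, u: int, v: int) -> tuple[float, float]:
        """(lat, lon) of the upper-left corner of pixel (u, v).

        Valid for 0 <= u <= n_rows, 0 <= v <= n_cols so the exclusive
        bottom/right grid edges are addressable.
        """
        if not (0 <= u <= self.n_rows and 0 <= v <= self.n_cols):
            raise IndexError(f"corner index ({u}, {v}) outside grid {self.shape}")
        return (
            self.lat_origin - u * self.pixel_height,
            self.lon_origin + v * self.pixel_width,
        )

    def pixel_center(self, u: int, v: int) -> tuple[float, float]:
        """(lat, lon) of the centre of pixel (u, v)."""
        if not (0 <= u < self.n_rows and 0 <= v < self.n_cols):
            raise IndexError(f"pixel index ({u}, {v}) outside grid {self.shape}")
        return (
            self.lat_origin - (u + 0.5) * self.pixel_height,
            self.lon_origin + (v + 0.5) * self.pixel_width,
        )

    def center_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectors of row-centre latitudes (n_rows,) and column-centre longitudes (n_cols,)."""
        lats = self.lat_origin - (np.arange(self.n_rows) + 0.5) * self.pixel_height
        lons = self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.pixel_width
        return lats, lons

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) of the grid bounding box."""
        return (
            self.lat_origin - self.n_rows * self.pixel_height,
            self.lat_origin,
            self.lon_origin,
            self.lon_origin + self.n_cols * self.pixel_width,
        )

    def index_of(self, lat: float | np.ndarray, lon: float | np.ndarray):
        """Row/col indices of the pixel whose half-open footprint contains (lat, lon).

        The footprint convention is [lon_left, lon_right) in longitude and
        (lat_bottom, lat_top] in latitude, so footprints tile the plane.
        Returned indices may fall outside the grid; callers bound-check.
        """
        u = np.floor((self.lat_origin - np.asarray(lat)) / self.pixel_height).astype(int)
        v = np.floor((np.asarray(lon) - self.lon_origin) / self.pixel_width).astype(int)
        return u, v

    def same_geometry(self, other: "GeoGrid", tol: float = 1e-12) -> bool:
        return (
            self.shape == other.shape
            and abs(self.lat_origin - other.lat_origin) <= tol
            and abs(self.lon_origin - other.lon_origin) <= tol
            and abs(self.pixel_height - other.pixel_height) <= tol
            and abs(self.pixel_width - other.pixel_width) <= tol
        )


@dataclass
class MultispectralRaster:
    """Georeferenced band stack.

    ``bands`` maps band name -> 2-D float plane; planes share the grid
    shape.  ``radiometry`` is ``"reflectance"`` (values in [0, 1]) or
    ``"dn"`` (non-negative digital numbers).  ``nodata_mask`` is True
    where a pixel is invalid in any band.
    """

    grid: GeoGrid
    bands: dict[str, np.ndarray]
    radiometry: str = "reflectance"
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.radiometry not in ("reflectance", "dn"):
            raise RadiometryError(f"unknown radiometry tag {self.radiometry!r}")
        for name, plane in self.bands.items():
            plane = np.asarray(plane, dtype=float)
            if plane.shape != self.grid.shape:
                raise ValueError(
                    f"band {name!r} shape {plane.shape} != grid {self.grid.shape}"
                )
            self.bands[name] = plane
        if self.nodata_mask is None:
            mask = np.zeros(self.grid.shape, dtype=bool)
            for plane in self.bands.values():
                mask |= ~np.isfinite(plane)
            self.nodata_mask = mask
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise ValueError("nodata mask shape does not match grid")

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise BandMissingError(f"raster lacks required band {name!r}") from None

    def require_bands(self, *names: str) -> None:
        missing = [n for n in names if n not in self.bands]
        if missing:
            raise BandMissingError(f"raster lacks required band(s): {missing}")


@dataclass
class NDVIMap:
    """Single-band NDVI raster in [-1, 1] with nodata mask.

    ``provenance`` records which decomposition produced it: ``sat``
    (satellite pixels), ``uav`` (all UAV pixels per cell), ``vin``
    (canopy-only) or ``int`` (inter-row-only).
    """

    grid: GeoGrid
    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    provenance: str = "uav"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool) | ~np.isfinite(
                self.values
            )
        valid = self.values[~self.nodata_mask]
        if valid.size and (valid.min() < -1 - 1e-9 or valid.max() > 1 + 1e-9):
            raise ValueError("NDVI values outside [-1, 1]")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def masked(self) -> np.ndarray:
        """Values with nodata as NaN."""
        out = self.values.astype(float).copy()
        out[self.nodata_mask] = np.nan
        return out


@dataclass(frozen=True)
class SensorReading:
    lat: float
    lon: float
    timestamp: str
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in SENSOR_KINDS:
            raise SensorKindError(
                f"unknown sensor kind {self.kind!r}; expected one of {sorted(SENSOR_KINDS)}"
            )
        if self.kind == "soil_moisture_vwc" and not (0.0 <= self.value <= VWC_MAX):
            raise SensorRangeError(
                f"soil moisture {self.value} outside calibrated range [0, {VWC_MAX}] VWC"
            )
        if self.kind == "ph" and not (0.0 <= self.value <= 14.0):
            raise SensorRangeError(f"pH {self.value} outside [0, 14]")


# ---------------------------------------------------------------------------
# raster I/O


def _geokeys_wgs84() -> tuple[int, ...]:
    # GeoKeyDirectory: version 1.1.0, 3 keys: geographic model, pixel-is-area, WGS84
    return (
        1, 1, 0, 3,
        _KEY_MODEL_TYPE, 0, 1, 2,
        _KEY_RASTER_TYPE, 0, 1, 1,
        _KEY_GEOGRAPHIC_TYPE, 0, 1, 4326,
    )


def write_raster(
    raster: MultispectralRaster,
    path: str | os.PathLike,
    *,
    overwrite: bool = True,
    fill_value: float = -9999.0,
) -> None:
    """Write a raster as a multiband GeoTIFF (float32, WGS84 geographic).

    Band order on disk follows ``raster.bands`` insertion order; the
    name -> index map, radiometry and fill value are stored as JSON in
    the ImageDescription tag.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    g = raster.grid
    names = list(raster.bands)
    stack = np.stack([raster.bands[n] for n in names]).astype(np.float32)
    stack[:, raster.nodata_mask] = fill_value
    stack[~np.isfinite(stack)] = fill_value
    meta = {
        "bands": {n: i for i, n in enumerate(names)},
        "radiometry": raster.radiometry,
        "nodata": fill_value,
        "crs": "EPSG:4326",
    }
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.pixel_width, g.pixel_height, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.lon_origin, g.lat_origin, 0.0)),
        (_TAG_GEO_KEYS, "H", 16, _geokeys_wgs84()),
    ]
    kwargs = {}
    if stack.shape[0] > 1:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(
        path,
        stack[0] if stack.shape[0] == 1 else stack,
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=extratags,
        **kwargs,
    )


def read_raster(path: str | os.PathLike) -> MultispectralRaster:
    """Read a multiband GeoTIFF written by :func:`write_raster` (or compatible).

    Requires geographic WGS84 georeferencing (GeoKey 2048 = 4326 or no
    geokeys at all, in which case degrees are assumed).  Band names come
    from the ImageDescription JSON or a ``<path>.bands.json`` sidecar.
    """
    path = os.fspath(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        data = tif.asarray()
        if _TAG_GEO_KEYS in tags:
            keys = tuple(tags[_TAG_GEO_KEYS].value)
            kv = {keys[i]: keys[i + 3] for i in range(4, len(keys), 4)}
            if kv.get(_KEY_MODEL_TYPE, 2) != 2 or kv.get(_KEY_GEOGRAPHIC_TYPE, 4326) != 4326:
                raise UnsupportedCRSError(
                    f"{path}: raster CRS is not geographic WGS84 and no "
                    "reprojection support is available"
                )
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise UnsupportedCRSError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        lon0, lat0 = tie[3] - tie[0] * sx, tie[4] + tie[1] * sy
        desc = tags.get("ImageDescription")
        meta: dict = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    sidecar = path + ".bands.json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta["bands"] = json.load(fh)

    if data.ndim == 2:
        data = data[None]
    n_bands = data.shape[0]
    band_map = meta.get("bands") or {f"band_{i}": i for i in range(n_bands)}
    fill = meta.get("nodata")
    grid = GeoGrid(
        n_rows=data.shape[1],
        n_cols=data.shape[2],
        lat_origin=float(lat0),
        lon_origin=float(lon0),
        pixel_height=float(sy),
        pixel_width=float(sx),
    )
    planes = {}
    mask = np.zeros(grid.shape, dtype=bool)
    for name, idx in band_map.items():
        plane = data[int(idx)].astype(float)
        if fill is not None:
            bad = plane == fill
            plane[bad] = np.nan
            mask |= bad
        mask |= ~np.isfinite(plane)
        planes[name] = plane
    return MultispectralRaster(
        grid=grid,
        bands=planes,
        radiometry=meta.get("radiometry", "reflectance"),
        nodata_mask=mask,
    )


def write_ndvi_map(ndvi: NDVIMap, path: str | os.PathLike, **kw) -> None:
    """Export an NDVI map as a single-band float GeoTIFF."""
    raster = MultispectralRaster(
        grid=ndvi.grid,
        bands={"ndvi": ndvi.masked()},
        radiometry="reflectance",
        nodata_mask=ndvi.nodata_mask,
    )
    write_raster(raster, path, **kw)


# ---------------------------------------------------------------------------
# sensor tables


def read_sensor_table(path: str | os.PathLike) -> list[SensorReading]:
    """Parse a CSV with columns lat,lon,timestamp,kind,value into readings.

    Per-kind physical invariants are enforced on construction: soil
    moisture must lie in the probe's calibrated [0, 0.57] VWC range and
    pH in [0, 14]; an unknown kind raises :class:`SensorKindError`.
    """
    df = pd.read_csv(path, dtype={"timestamp": str, "kind": str})
    required = {"lat", "lon", "timestamp", "kind", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensor table missing columns: {sorted(missing)}")
    return [
        SensorReading(
            lat=float(r.lat),
            lon=float(r.lon),
            timestamp=str(r.timestamp),
            kind=str(r.kind),
            value=float(r.value),
        )
        for r in df.itertuples(index=False)
    ]


def write_sensor_table(readings: list[SensorReading], path: str | os.PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in readings]).to_csv(path, index=False)
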