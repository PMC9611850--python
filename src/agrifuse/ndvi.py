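"""Per-pixel NDVI computation and three-class vigour mapping.

NDVI = (NIR - Red) / (NIR + Red), the standard proxy for crop vigour.
The ratio is scale-invariant, so it is computed on whichever radiometry
(reflectance or DN) the raster declares — but never across mixed
radiometries.  Pixels where NIR + Red = 0 have an undefined ratio and
map to nodata rather than to 0, which would masquerade as moderate
vigour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMapError
from .geodata import GeoGrid, MultispectralRaster, NDVIMap

LABEL_LOW, LABEL_MEDIUM, LABEL_HIGH, LABEL_NODATA = 0, 1, 2, 255
LABEL_NAMES = {LABEL_LOW: "low", LABEL_MEDIUM: "medium", LABEL_HIGH: "high"}


@dataclass
class VigourMap:
    """Classed NDVI raster: low / medium / high management zones.

    Rendering convention follows the usual vigour-map palette: red =
    low, yellow = medium, green = high NDVI.
    """

    grid: GeoGrid
    classes: np.ndarray  # uint8 labels, LABEL_NODATA where invalid
    thresholds: tuple[float, float]

    def __post_init__(self) -> None:
        t_low, t_high = self.thresholds
        if not t_low < t_high:
            raise ValueError("thresholds must satisfy t_low < t_high")
        if self.classes.shape != self.grid.shape:
            raise ValueError("class plane shape does not match grid")

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.classes == lab).sum()) for lab, name in LABEL_NAMES.items()
        }


def ndvi(raster: MultispectralRaster, provenance: str = "uav") -> NDVIMap:
    """Compute (nir - red)/(nir + red) per pixel.

    Nodata propagates; a zero denominator yields nodata.
    """
    red = raster.band("red")
    nir = raster.band("nir")
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (nir - red) / denom
    bad = raster.nodata_mask | (denom == 0) | ~np.isfinite(values)
    values = values.copy()
    values[bad] = np.nan
    return NDVIMap(grid=raster.grid, values=values, nodata_mask=bad, provenance=provenance)


def classify_vigour(
    ndvi_map: NDVIMap, thresholds: tuple[float, float] | str = "tertiles"
) -> VigourMap:
    """Three-class vigour map from an NDVI raster.

    With explicit ``(t_low, t_high)``: low iff value < t_low, medium iff
    t_low <= value < t_high, high iff value >= t_high (half-open bins,
    t_high inclusive for "high").  With ``"tertiles"`` the breaks are the
    33.3/66.7 empirical percentiles of the valid values.
    """
    valid = ndvi_map.valid
    if isinstance(thresholds, str):
        if thresholds != "tertiles":
            raise ValueError(f"unknown threshold mode {thresholds!r}")
        vals = ndvi_map.values[valid]
        if vals.size == 0:
            raise EmptyMapError("cannot take tertiles of an all-nodata map")
        t_low, t_high = np.percentile(vals, [100 / 3, 200 / 3])
        if not t_low < t_high:  # near-constant map: widen infinitesimally
            t_high = np.nextafter(t_low, np.inf)
        thresholds = (float(t_low), float(t_high))
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("thresholds must satisfy t_low < t_high")

    classes = np.full(ndvi_map.grid.shape, LABEL_NODATA, dtype=np.uint8)
    v = ndvi_map.values
    classes[valid & (v < t_low)] = LABEL_LOW
    classes[valid & (v >= t_low) & (v < t_high)] = LABEL_MEDIUM
    classes[valid & (v >= t_high)] = LABEL_HIGH
    return VigourMap(grid=ndvi_map.grid, classes=classes, thresholds=(t_low, t_high))
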