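"""Exception hierarchy shared by all agrifuse modules."""


class AgrifuseError(Exception):
    """Base class for all package-specific errors."""


class BandMissingError(AgrifuseError):
    """A required spectral band (red/nir) is absent from a raster."""


class UnsupportedCRSError(AgrifuseError):
    """Raster is not in geographic WGS84 and cannot be reprojected."""


class RadiometryError(AgrifuseError):
    """Bands with incompatible radiometry (reflectance vs DN) were combined."""


class GridMismatchError(AgrifuseError):
    """Two layers that must share a grid do not."""


class SensorRangeError(AgrifuseError, ValueError):
    """Sensor value outside the physically calibrated range."""


class SensorKindError(AgrifuseError, ValueError):
    """Unknown sensor kind tag."""


class ConfigError(AgrifuseError, ValueError):
    """Invalid configuration (invariant violation)."""


class ResolutionError(AgrifuseError, ValueError):
    """Requested GSD finer than the underlying data resolution."""


class BoundsError(AgrifuseError, ValueError):
    """Coordinate outside the scene/raster extent."""


class InsufficientDataError(AgrifuseError, ValueError):
    """Too few valid samples/cells for the requested statistic."""


class DegenerateHistogramError(AgrifuseError, ValueError):
    """Histogram has <2 distinct values; automatic thresholding undefined."""


class EmptyMapError(AgrifuseError, ValueError):
    """All-nodata map where valid values are required."""


class GeometryError(AgrifuseError, ValueError):
    """Degenerate spatial configuration (e.g. duplicate sample locations)."""


class MissingCovariateError(AgrifuseError, ValueError):
    """A covariate value is unavailable at a requested point."""


class NoRowsWarning(UserWarning):
    """Raster shows no periodic row structure; azimuth estimate undefined."""


class EmptyRouteWarning(UserWarning):
    """Route requested with no attention points; depot-only route returned."""


class NoOverlapWarning(UserWarning):
    """Satellite and UAV extents do not overlap; correspondence is empty."""
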