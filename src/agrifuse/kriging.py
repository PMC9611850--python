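"""Ordinary kriging of soil moisture with sensor-based calibration.

Soil moisture is first *estimated* at covariate sample points as a
linear combination of covariates (rainfall, NDVI, soil class, ...),
then interpolated by ordinary kriging — the best linear unbiased
predictor under an unknown constant mean, with weights constrained to
sum to one.  The free parameters (variogram nugget/sill/range and the
covariate coefficients) are calibrated by exhaustive search against
in-situ capacitance soil-moisture probes: the configuration minimising
the mean absolute error between the kriged estimate at each probe and
the probe reading wins.

Distances are computed on a local equirectangular metric projection
anchored at the sample centroid; degrees are anisotropic in metres, so
kriging in raw degrees would distort the variogram.

Variogram families use the *practical range* parameterisation, i.e.
the semivariance reaches ~95% of the sill at ``range_m``:

    exponential:  g(h) = nugget + sill * (1 - exp(-3h/a))
    gaussian:     g(h) = nugget + sill * (1 - exp(-3(h/a)^2))
    spherical:    g(h) = nugget + sill * (1.5 h/a - 0.5 (h/a)^3),  h < a
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .errors import (
    GeometryError,
    InsufficientDataError,
    MissingCovariateError,
    SensorKindError,
)
from .geodata import SensorReading, VWC_MAX, meters_per_degree

VARIOGRAM_FAMILIES = ("exponential", "spherical", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    family: str
    nugget: float
    sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.sill <= 0 or self.range_m <= 0:
            raise ValueError("require nugget >= 0, sill > 0, range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        """Semivariance at lag ``h`` metres; g(0) = 0, g(0+) = nugget."""
        h = np.asarray(h, dtype=float)
        a = self.range_m
        if self.family == "exponential":
            struct = 1.0 - np.exp(-3.0 * h / a)
        elif self.family == "gaussian":
            struct = 1.0 - np.exp(-3.0 * (h / a) ** 2)
        else:  # spherical
            hr = np.minimum(h / a, 1.0)
            struct = 1.5 * hr - 0.5 * hr**3
        g = self.nugget + self.sill * struct
        return np.where(h == 0, 0.0, g)


@dataclass
class CovariateSample:
    lat: float
    lon: float
    covariates: dict[str, float]
    moisture_estimate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.moisture_estimate <= VWC_MAX):
            raise ValueError(
                f"moisture estimate {self.moisture_estimate} outside [0, {VWC_MAX}] VWC"
            )


def local_xy(
    lats: np.ndarray, lons: np.ndarray, lat0: float, lon0: float
) -> np.ndarray:
    """(n, 2) local metric coordinates (x east, y north) of WGS84 points."""
    m_lat, m_lon = meters_per_degree(lat0)
    x = (np.asarray(lons, float) - lon0) * m_lon
    y = (np.asarray(lats, float) - lat0) * m_lat
    return np.column_stack([x, y])


def estimate_moisture_at_points(
    points: list[tuple[float, float]],
    covariate_values: list[dict[str, float]],
    coefficients: dict[str, float],
    intercept: float = 0.0,
) -> list[CovariateSample]:
    """Linear covariate model: clip(intercept + sum_k coeff_k * covariate_k, 0, 0.57).

    ``covariate_values[i]`` holds the covariates observed at
    ``points[i]``; every coefficient key must be present at every point.
    """
    out = []
    for (lat, lon), cov in zip(points, covariate_values):
        missing = [k for k in coefficients if k not in cov]
        if missing:
            raise MissingCovariateError(
                f"covariate(s) {missing} missing at point ({lat}, {lon})"
            )
        est = intercept + sum(c * cov[k] for k, c in coefficients.items())
        out.append(
            CovariateSample(
                lat=lat,
                lon=lon,
                covariates=dict(cov),
                moisture_estimate=float(np.clip(est, 0.0, VWC_MAX)),
            )
        )
    return out


class OrdinaryKriging:
    """Ordinary kriging solver over a fixed sample configuration.

    Solves the augmented semivariance system with a Lagrange multiplier
    enforcing unbiasedness (weights sum to 1); predictions and kriging
    variances come from a single factorisation reused across targets.
    """

    def __init__(
        self,
        lats: np.ndarray,
        lons: np.ndarray,
        values: np.ndarray,
        variogram: VariogramModel,
    ):
        self.lats = np.asarray(lats, float)
        self.lons = np.asarray(lons, float)
        self.values = np.asarray(values, float)
        self.variogram = variogram
        if self.lats.size < 1:
            raise InsufficientDataError("kriging needs at least one sample")
        self.lat0 = float(self.lats.mean())
        self.lon0 = float(self.lons.mean())
        self.xy = local_xy(self.lats, self.lons, self.lat0, self.lon0)
        d = cdist(self.xy, self.xy)
        if np.any(d[~np.eye(len(d), dtype=bool)] == 0):
            raise GeometryError("duplicate sample locations make the system singular")
        n = len(self.xy)
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = variogram(d)
        a[n, :n] = 1.0
        a[:n, n] = 1.0
        a[n, n] = 0.0
        self._a = a
        self._n = n

    def weights(self, targets_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Kriging weights (m, n) and Lagrange multipliers (m,) for metric targets."""
        g = self.variogram(cdist(np.atleast_2d(targets_xy), self.xy))
        b = np.column_stack([g, np.ones(len(g))])
        sol = np.linalg.solve(self._a, b.T).T
        return sol[:, : self._n], sol[:, self._n]

    def predict(self, targets: list[tuple[float, float]]) -> list[tuple[float, float]]:
        """(estimate, kriging variance) at each (lat, lon) target."""
        t = np.asarray(targets, float)
        txy = local_xy(t[:, 0], t[:, 1], self.lat0, self.lon0)
        w, mu = self.weights(txy)
        est = w @ self.values
        g = self.variogram(cdist(txy, self.xy))
        var = np.einsum("ij,ij->i", w, g) + mu
        var = np.maximum(var, 0.0)
        return list(zip(est.tolist(), var.tolist()))


def krige(
    samples: list[CovariateSample],
    vgm: VariogramModel,
    targets: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Ordinary kriging of sample moisture estimates at target locations."""
    ok = OrdinaryKriging(
        np.array([s.lat for s in samples]),
        np.array([s.lon for s in samples]),
        np.array([s.moisture_estimate for s in samples]),
        vgm,
    )
    return ok.predict(targets)


def empirical_variogram(
    xy: np.ndarray, values: np.ndarray, n_bins: int = 15
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram: (lag centres, semivariance, pair counts).

    Lags up to half the maximum pairwise distance, ``n_bins`` equal-width bins.
    """
    d = cdist(xy, xy)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    sv = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    h_max = h.max() / 2.0
    edges = np.linspace(0.0, h_max, n_bins + 1)
    idx = np.digitize(h, edges) - 1
    keep = (idx >= 0) & (idx < n_bins)
    gamma = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = keep & (idx == b)
        counts[b] = m.sum()
        if counts[b]:
            gamma[b] = sv[m].mean()
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres[counts > 0], gamma[counts > 0], counts[counts > 0]


def fit_variogram(
    samples: list[CovariateSample],
    family: str = "exponential",
    bounds: dict[str, tuple[float, float]] | None = None,
    n_bins: int = 15,
) -> VariogramModel:
    """Weighted-least-squares fit of a variogram family to the empirical variogram.

    Weights are N(h)/h^2 (pair count over squared lag), the common
    geostatistical default that privileges the short lags which carry
    the range information.  ``bounds`` maps nugget/sill/range_m to
    (lo, hi); defaults are wide and data-driven.
    """
    if len(samples) < 10:
        raise InsufficientDataError(
            f"variogram fitting needs >= 10 samples, got {len(samples)}"
        )
    lats = np.array([s.lat for s in samples])
    lons = np.array([s.lon for s in samples])
    vals = np.array([s.moisture_estimate for s in samples])
    xy = local_xy(lats, lons, float(lats.mean()), float(lons.mean()))
    h, gamma, counts = empirical_variogram(xy, vals, n_bins=n_bins)

    var = float(vals.var())
    h_max = float(h.max())
    default_bounds = {
        "nugget": (0.0, max(var, 1e-12)),
        "sill": (1e-12, max(4 * var, 1e-9)),
        "range_m": (h_max * 1e-3, 4 * h_max),
    }
    if bounds:
        default_bounds.update(bounds)
    lo = np.array([default_bounds[k][0] for k in ("nugget", "sill", "range_m")])
    hi = np.array([default_bounds[k][1] for k in ("nugget", "sill", "range_m")])
    w = np.sqrt(counts.astype(float)) / np.maximum(h, 1e-9)

    def residuals(p):
        vgm = VariogramModel(family, max(p[0], 0.0), max(p[1], 1e-12), max(p[2], 1e-9))
        return w * (vgm(h) - gamma)

    p0 = np.clip(
        np.array([0.1 * var + 1e-12, max(var, 1e-9), h_max / 4]), lo, hi
    )
    fit = least_squares(residuals, p0, bounds=(lo, hi))
    nugget, sill, rng = fit.x
    return VariogramModel(family, float(max(nugget, 0.0)), float(max(sill, 1e-12)), float(rng))


def nested_survey_xy(
    n: int, span_m: float, seed: int | None = None,
    offset_range_m: tuple[float, float] = (0.5, 6.0),
) -> np.ndarray:
    """Nested variogram-survey design: base stations plus short-offset satellites.

    Half the points are uniform over a ``span_m`` square; each remaining
    point sits at a random 0.5-6 m offset from a base station.  The
    short-offset pairs pin down nugget and range, which purely uniform
    designs resolve poorly.  Returns (n, 2) metric coordinates.
    """
    rng = np.random.default_rng(seed)
    m = n // 2
    bx = rng.uniform(0, span_m, m)
    by = rng.uniform(0, span_m, m)
    ang = rng.uniform(0, 2 * math.pi, n - m)
    r = rng.uniform(*offset_range_m, n - m)
    sx = np.clip(bx[: n - m] + r * np.cos(ang), 0, span_m)
    sy = np.clip(by[: n - m] + r * np.sin(ang), 0, span_m)
    return np.column_stack([np.r_[bx, sx], np.r_[by, sy]])


def sample_gaussian_process(
    xy: np.ndarray, vgm: VariogramModel, seed: int | None = None
) -> np.ndarray:
    """Draw one zero-mean Gaussian field realisation at metric points ``xy``.

    Covariance is the stationary counterpart of the variogram:
    sill * corr(h) + nugget on the diagonal.
    """
    rng = np.random.default_rng(seed)
    d = cdist(xy, xy)
    corr = 1.0 - (vgm(d) - np.where(d > 0, vgm.nugget, 0.0)) / vgm.sill
    cov = vgm.sill * corr + vgm.nugget * np.eye(len(xy))
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(xy)))
    return chol @ rng.standard_normal(len(xy))


@dataclass
class CalibrationResult:
    variogram: VariogramModel
    coefficients: dict[str, float]
    intercept: float
    residuals: np.ndarray  # per sensor, kriged - measured
    mae: float


def calibrate_against_sensors(
    points: list[tuple[float, float]],
    covariate_values: list[dict[str, float]],
    sensor_readings: list[SensorReading],
    variogram_grid: list[VariogramModel],
    coefficient_grid: list[dict[str, float]],
    intercept_grid: list[float] = (0.0,),
) -> CalibrationResult:
    """Exhaustive grid search over variogram x coefficient configurations.

    For every configuration, covariate-derived moisture estimates are
    kriged at the soil-moisture sensor locations and scored by mean
    absolute error against the sensor readings; the minimiser wins.
    Ties break towards smaller nugget, then smaller range.
    """
    sensors = [r for r in sensor_readings if r.kind == "soil_moisture_vwc"]
    if not sensors:
        raise SensorKindError("calibration requires soil_moisture_vwc readings")
    if not variogram_grid or not coefficient_grid:
        raise ValueError("parameter grids must be non-empty")
    targets = [(r.lat, r.lon) for r in sensors]
    measured = np.array([r.value for r in sensors])

    best: CalibrationResult | None = None
    best_key = None
    for coeffs, intercept, vgm in itertools.product(
        coefficient_grid, intercept_grid, variogram_grid
    ):
        samples = estimate_moisture_at_points(points, covariate_values, coeffs, intercept)
        preds = np.array([e for e, _ in krige(samples, vgm, targets)])
        resid = preds - measured
        mae = float(np.abs(resid).mean())
        key = (mae, vgm.nugget, vgm.range_m)
        if best is None or key < best_key:
            best = CalibrationResult(
                variogram=vgm,
                coefficients=dict(coeffs),
                intercept=float(intercept),
                residuals=resid,
                mae=mae,
            )
            best_key = key
    return best
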