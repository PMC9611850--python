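"""Satellite-footprint aggregation of centimetric UAV NDVI.

This is the heart of the workflow: each decametric satellite cell
s(i,j) is associated with the set of UAV pixels whose centres fall in
its half-open geographic footprint, and three aggregated NDVI maps on
the satellite grid are computed from the UAV data:

* NDVI_uav — mean per-pixel NDVI over the whole cell,
* NDVI_vin — over canopy pixels only,
* NDVI_int — over inter-row pixels only,

to be compared with NDVI_sat computed directly from the satellite
bands.  Because the satellite sensor averages *reflectance* before the
ratio while the aggregation averages per-pixel *ratios*, the two differ
on mixed pixels — and NDVI_vin is the one that tracks true canopy
vigour.

Denominator modes: the restricted mode (default) divides each sum by
the cardinality of the restricted pixel set, giving a true conditional
mean; the ``printed`` mode divides the canopy and inter-row sums by the
full cell cardinality |P(i,j)|, under which NDVI_uav = NDVI_vin +
NDVI_int holds exactly per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ndvi import ndvi as _compute_ndvi
from .errors import GridMismatchError, InsufficientDataError, NoOverlapWarning
from .geodata import GeoGrid, MultispectralRaster, NDVIMap
from .segmentation import PixelPartition


@dataclass
class CellCorrespondence:
    """Mapping from satellite cells to the UAV pixels they contain.

    ``cell_row``/``cell_col`` give, per UAV pixel, the satellite cell
    index containing its centre (-1 where the centre falls outside the
    satellite grid).  ``counts`` and ``coverage_fraction`` are on the
    satellite grid; coverage is |members| * (UAV pixel area) /
    (satellite pixel area) in degree^2.
    """

    sat_grid: GeoGrid
    uav_grid: GeoGrid
    cell_row: np.ndarray
    cell_col: np.ndarray
    counts: np.ndarray
    coverage_fraction: np.ndarray
    empty: bool = False

    @property
    def flat_cell(self) -> np.ndarray:
        """Flattened satellite-cell id per UAV pixel, -1 where unassigned."""
        inside = self.cell_row >= 0
        flat = np.where(
            inside, self.cell_row * self.sat_grid.n_cols + self.cell_col, -1
        )
        return flat

    def members(self, i: int, j: int) -> list[tuple[int, int]]:
        """UAV pixel indices (u, v) whose centres lie in satellite cell (i, j)."""
        uu, vv = np.nonzero((self.cell_row == i) & (self.cell_col == j))
        return list(zip(uu.tolist(), vv.tolist()))


def match_footprints(sat_grid: GeoGrid, uav_grid: GeoGrid) -> CellCorrespondence:
    """Assign every UAV pixel centre to the satellite footprint containing it.

    Footprints are half-open axis-aligned boxes — longitude
    [west, east), latitude (south, north] — so they tile the plane and
    no centre is ever assigned twice.  Non-overlapping extents return an
    empty correspondence carrying a warning flag.
    """
    lats, lons = uav_grid.center_arrays()
    # floor on the row/col offset realises the half-open convention directly:
    # a centre on a cell's north or west edge lands in that cell, a centre on
    # the south or east edge lands in the neighbour.
    i = np.floor((sat_grid.lat_origin - lats) / sat_grid.pixel_height).astype(int)
    j = np.floor((lons - sat_grid.lon_origin) / sat_grid.pixel_width).astype(int)

    ok_i = (i >= 0) & (i < sat_grid.n_rows)
    ok_j = (j >= 0) & (j < sat_grid.n_cols)
    cell_row = np.where(ok_i[:, None] & ok_j[None, :], i[:, None], -1)
    cell_col = np.where(ok_i[:, None] & ok_j[None, :], j[None, :], -1)
    cell_row = np.broadcast_to(cell_row, (uav_grid.n_rows, uav_grid.n_cols)).copy()
    cell_col = np.broadcast_to(cell_col, (uav_grid.n_rows, uav_grid.n_cols)).copy()

    flat = np.where(cell_row >= 0, cell_row * sat_grid.n_cols + cell_col, -1)
    counts = np.bincount(
        flat[flat >= 0].ravel(), minlength=sat_grid.n_rows * sat_grid.n_cols
    ).reshape(sat_grid.shape)

    area_ratio = (uav_grid.pixel_height * uav_grid.pixel_width) / (
        sat_grid.pixel_height * sat_grid.pixel_width
    )
    coverage = counts * area_ratio

    empty = counts.sum() == 0
    if empty:
        warnings.warn(
            "satellite and UAV extents do not overlap; correspondence is empty",
            NoOverlapWarning,
            stacklevel=2,
        )
    return CellCorrespondence(
        sat_grid=sat_grid,
        uav_grid=uav_grid,
        cell_row=cell_row,
        cell_col=cell_col,
        counts=counts,
        coverage_fraction=coverage,
        empty=bool(empty),
    )


def ndvi_sat(raster: MultispectralRaster) -> NDVIMap:
    """Per-pixel NDVI of the satellite raster (provenance tag ``sat``)."""
    return _compute_ndvi(raster, provenance="sat")


def aggregate_ndvi(
    uav: MultispectralRaster,
    corr: CellCorrespondence,
    mask: PixelPartition | None = None,
    which: str = "all",
    denominator: str = "restricted",
    min_coverage: float = 0.95,
) -> NDVIMap:
    """Aggregate per-pixel UAV NDVI onto the satellite grid.

    ``which`` selects the UAV pixel set per cell: ``all`` (the whole
    footprint), ``vin`` (canopy pixels, needs ``mask``) or ``int``
    (inter-row pixels).  ``denominator``: ``restricted`` divides by the
    selected-set cardinality; ``printed`` divides by the full footprint
    cardinality |P(i,j)|.  Cells with an empty selected set, or with
    footprint coverage below ``min_coverage``, are nodata.
    """
    if which not in ("all", "vin", "int"):
        raise ValueError(f"unknown selection {which!r}")
    if denominator not in ("restricted", "printed"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if which in ("vin", "int"):
        if mask is None:
            raise ValueError(f"which={which!r} requires a canopy/inter-row mask")
        if not mask.grid.same_geometry(corr.uav_grid):
            raise GridMismatchError("mask grid does not match the UAV grid")
    if not uav.grid.same_geometry(corr.uav_grid):
        raise GridMismatchError("UAV raster grid does not match the correspondence")

    uav_ndvi = _compute_ndvi(uav)
    values = uav_ndvi.values
    valid = uav_ndvi.valid

    if which == "all":
        selected = valid
    elif which == "vin":
        selected = valid & mask.vin_mask
    else:
        selected = valid & mask.int_mask

    n_cells = corr.sat_grid.n_rows * corr.sat_grid.n_cols
    flat = corr.flat_cell

    sel_flat = flat[selected]
    sel_flat = sel_flat[sel_flat >= 0]
    sel_vals = values[selected][flat[selected] >= 0]
    sums = np.bincount(sel_flat, weights=sel_vals, minlength=n_cells)
    n_selected = np.bincount(sel_flat, minlength=n_cells)

    all_flat = flat[valid]
    all_flat = all_flat[all_flat >= 0]
    n_total = np.bincount(all_flat, minlength=n_cells)

    denom = n_selected if denominator == "restricted" else n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        agg = sums / denom
    agg = agg.reshape(corr.sat_grid.shape)
    nodata = (
        (n_selected.reshape(corr.sat_grid.shape) == 0)
        | (denom.reshape(corr.sat_grid.shape) == 0)
        | (corr.coverage_fraction < min_coverage)
    )
    agg = agg.copy()
    agg[nodata] = np.nan
    provenance = {"all": "uav", "vin": "vin", "int": "int"}[which]
    return NDVIMap(
        grid=corr.sat_grid, values=agg, nodata_mask=nodata, provenance=provenance
    )


def compare_maps(a: NDVIMap, b: NDVIMap) -> dict[str, float]:
    """Bias, RMSE, Pearson correlation and n over jointly valid cells (b - a)."""
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError("maps to compare must share a grid")
    joint = a.valid & b.valid
    n = int(joint.sum())
    if n < 2:
        raise InsufficientDataError(f"only {n} jointly valid cells; need >= 2")
    da, db = a.values[joint], b.values[joint]
    diff = db - da
    bias = float(diff.mean())
    rmse = float(np.sqrt((diff**2).mean()))
    if np.std(da) == 0 or np.std(db) == 0:
        corr = 1.0 if rmse == 0 or np.allclose(diff, diff[0]) else float("nan")
    else:
        corr = float(np.corrcoef(da, db)[0, 1])
    return {"bias": bias, "rmse": rmse, "correlation": corr, "n": n}
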