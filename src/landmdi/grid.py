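"""Raster data model and I/O.

A :class:`Grid` is a 2-D lattice of values on an equal-area projected
plane, carried everywhere in the pipeline.  GeoTIFF serialization uses
the baseline geo-tags (pixel scale, tiepoint, geo-key directory and the
GDAL nodata tag) so files interoperate with standard GIS tooling.

Conventions: cell-center registration, row-major storage, top-left
origin, north-up (row index increases southward).  Area accounting is
pixel count times cell area; this is exact under an equal-area CRS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "GridTransform",
    "Grid",
    "LandMask",
    "ZonePartition",
    "read_raster",
    "write_raster",
    "align_to_template",
    "area_km2",
    "MASK_NODATA",
]

#: nodata sentinel for 8-bit {0,1} masks and small-integer class grids
MASK_NODATA = 255

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """Affine north-up transform: top-left corner and square cell size (m)."""

    x0: float
    y0: float
    cell_size: float

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell size must be positive, got {self.cell_size}")

    def cell_center(self, row, col):
        """Map (row, col) indices to projected cell-center coordinates."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def index_of(self, x, y):
        """Fractional (row, col) of projected coordinates (inverse of cell_center)."""
        col = (np.asarray(x) - self.x0) / self.cell_size - 0.5
        row = (self.y0 - np.asarray(y)) / self.cell_size - 0.5
        return row, col


@dataclass
class Grid:
    """A single-band raster: 2-D values plus georeferencing and a nodata sentinel."""

    values: np.ndarray
    transform: GridTransform
    crs_id: int = 3035
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"Grid values must be 2-D, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return self.transform.cell_size

    def valid(self) -> np.ndarray:
        """Boolean array, True where the pixel holds a valid value."""
        if self.nodata is None:
            v = np.ones(self.shape, dtype=bool)
        elif isinstance(self.nodata, float) and math.isnan(self.nodata):
            v = ~np.isnan(self.values)
        else:
            v = self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            v &= ~np.isnan(self.values)
        return v

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs_id == other.crs_id
        )

    def with_values(self, values: np.ndarray, nodata=...) -> "Grid":
        """New grid sharing this grid's geometry."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError("values shape does not match grid geometry")
        return Grid(
            values=values,
            transform=self.transform,
            crs_id=self.crs_id,
            nodata=self.nodata if nodata is ... else nodata,
        )


@dataclass
class LandMask:
    """Land-use code grid with the agricultural / arable code subsets."""

    codes: Grid
    agricultural_codes: frozenset[int]
    arable_codes: frozenset[int]

    def __post_init__(self) -> None:
        self.agricultural_codes = frozenset(self.agricultural_codes)
        self.arable_codes = frozenset(self.arable_codes)
        if not self.arable_codes <= self.agricultural_codes:
            raise ValueError("arable codes must be a subset of agricultural codes")

    def stratum_mask(self, stratum: str) -> np.ndarray:
        """Boolean membership array for 'agricultural' or 'arable'."""
        if stratum == "agricultural":
            codes = self.agricultural_codes
        elif stratum == "arable":
            codes = self.arable_codes
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        return np.isin(self.codes.values, sorted(codes)) & self.codes.valid()


@dataclass
class ZonePartition:
    """Integer zone (country) id grid with per-zone input-layer completeness."""

    zones: Grid
    completeness: dict[int, int] = field(default_factory=dict)
    #: per-zone list of process ids with no data (empty when complete)
    missing: dict[int, list[str]] = field(default_factory=dict)

    def zone_ids(self) -> list[int]:
        v = self.zones.values[self.zones.valid()]
        return sorted(int(z) for z in np.unique(v))

    def complete_zone_ids(self, n_layers: int = 12) -> list[int]:
        return [z for z in self.zone_ids() if self.completeness.get(z, n_layers) >= n_layers]


def _geokeys(crs_id: int) -> tuple[int, ...]:
    # Version 1.1.0; two keys: model type = projected, projected CRS code.
    return (1, 1, 0, 2, 1024, 0, 1, 1, 3072, 0, 1, int(crs_id))


def write_raster(path, grid_or_stack, *, compress: bool = False) -> None:
    """Write a Grid, or a list of geometry-sharing Grids, as a GeoTIFF.

    Multi-band stacks are stored band-major; georeferencing is recorded
    once and applies to every band.
    """
    if isinstance(grid_or_stack, Grid):
        grids = [grid_or_stack]
        data = grid_or_stack.values
    else:
        grids = list(grid_or_stack)
        if not grids:
            raise ValueError("empty stack")
        first = grids[0]
        for g in grids[1:]:
            if not g.same_geometry(first):
                raise ValueError("stack bands must share geometry")
            if g.nodata != first.nodata:
                raise ValueError("stack bands must share nodata")
        data = np.stack([g.values for g in grids])
    g0 = grids[0]
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g0.cell_size, g0.cell_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g0.transform.x0, g0.transform.y0, 0.0), True),
        (_TAG_GEOKEYS, "H", 12, _geokeys(g0.crs_id), True),
    ]
    if g0.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(g0.nodata), True))
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        extratags=extratags,
        compression="zlib" if compress else None,
    )


def _parse_nodata(text: str, dtype) -> float | int:
    value = float(text)
    if np.issubdtype(dtype, np.integer):
        return int(value)
    return value


def read_raster(path):
    """Read a GeoTIFF into a Grid (single band) or list of Grids (stack).

    Raises ``ValueError`` for files lacking georeferencing tags.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tiepoint = page.tags.get(_TAG_TIEPOINT)
        geokeys = page.tags.get(_TAG_GEOKEYS)
        if scale is None or tiepoint is None or geokeys is None:
            raise ValueError(f"ungeoreferenced raster: {path}")
        data = tif.asarray()
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        sx = float(scale.value[0])
        tp = tiepoint.value
        keys = geokeys.value
        nodata_text = nodata_tag.value if nodata_tag is not None else None

    transform = GridTransform(x0=float(tp[3]), y0=float(tp[4]), cell_size=sx)
    crs_id = 0
    for i in range(4, len(keys), 4):
        if keys[i] == 3072:
            crs_id = int(keys[i + 3])
    nodata = None
    if nodata_text is not None:
        nodata = _parse_nodata(nodata_text, data.dtype)

    def make(arr):
        return Grid(values=arr, transform=transform, crs_id=crs_id, nodata=nodata)

    if data.ndim == 2:
        return make(data)
    return [make(data[b]) for b in range(data.shape[0])]


def align_to_template(grid: Grid, template: Grid, method: str = "nearest") -> Grid:
    """Resample ``grid`` onto the geometry of ``template``.

    ``nearest`` is required for categorical layers; ``bilinear`` is for
    continuous fields and refuses integer-typed inputs.  Pixels falling
    outside the source footprint, and source nodata, map to nodata.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if grid.crs_id != template.crs_id:
        raise ValueError("cannot align grids with different CRS ids")
    if method == "bilinear" and np.issubdtype(grid.values.dtype, np.integer):
        raise ValueError("bilinear resampling is invalid for categorical (integer) layers")
    if grid.same_geometry(template):
        return replace(grid, values=grid.values.copy())

    rows, cols = template.shape
    x, _ = template.transform.cell_center(0, np.arange(cols))
    _, y = template.transform.cell_center(np.arange(rows), 0)
    src_row, src_col = grid.transform.index_of(x[None, :], y[:, None])
    src_row = np.broadcast_to(src_row, (rows, cols))
    src_col = np.broadcast_to(src_col, (rows, cols))

    nr, nc = grid.shape
    if method == "nearest":
        ri = np.rint(src_row).astype(np.int64)
        ci = np.rint(src_col).astype(np.int64)
        inside = (ri >= 0) & (ri < nr) & (ci >= 0) & (ci < nc)
        out = np.empty((rows, cols), dtype=grid.values.dtype)
        nodata = grid.nodata if grid.nodata is not None else 0
        out[:] = nodata
        out[inside] = grid.values[ri[inside], ci[inside]]
        return Grid(out, template.transform, template.crs_id, grid.nodata)

    src = grid.values.astype(np.float64)
    if grid.nodata is not None:
        src = np.where(grid.valid(), src, np.nan)
    # clamp to edge values inside the source footprint; genuinely outside
    # pixels (beyond the half-cell border) become nodata
    sampled = ndimage.map_coordinates(src, [src_row, src_col], order=1, mode="nearest")
    outside = (
        (src_row < -0.5) | (src_row > nr - 0.5) | (src_col < -0.5) | (src_col > nc - 0.5)
    )
    sampled = np.where(outside, np.nan, sampled)
    nodata = grid.nodata if grid.nodata is not None else np.nan
    out = np.where(np.isnan(sampled), nodata, sampled)
    return Grid(out, template.transform, template.crs_id, grid.nodata)


def area_km2(mask, cell_size_m: float | None = None) -> float:
    """Area of the 1-pixels of a binary mask, in km².

    Accepts a Grid (cell size taken from its transform) or an ndarray
    with an explicit ``cell_size_m``.  Non-binary valid values are an
    error: area accounting is defined on {0,1} masks only.
    """
    if isinstance(mask, Grid):
        values = mask.values
        valid = mask.valid()
        cell = mask.cell_size
    else:
        values = np.asarray(mask)
        valid = np.ones(values.shape, dtype=bool)
        if cell_size_m is None:
            raise ValueError("cell_size_m required for bare arrays")
        cell = cell_size_m
    if cell_size_m is not None:
        cell = cell_size_m
    if not cell > 0:
        raise ValueError("cell size must be positive")
    vals = values[valid]
    if vals.size and not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    return float(np.count_nonzero(vals == 1)) * (cell / 1000.0) ** 2
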