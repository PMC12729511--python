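"""Raster data model, file I/O and geometry.

All gridded quantities in the package — environmental layers, suitability
surfaces, kriged concentration maps, zoning maps — live in :class:`RasterGrid`,
a north-up matrix of cell values tied to a :class:`GridSpec` in geographic
WGS84 coordinates. Two on-disk dialects are supported: ESRI ASCII grid
(``.asc``, the lingua franca of the species-distribution-modelling ecosystem)
and minimal single-band GeoTIFF.

Cell membership is half-open, ``[edge, edge + d)``, so a point on a cell's
west/north edge belongs to that cell. Cell areas are spherical
(``dx*dy*(pi/180)^2 * R^2 * cos(lat)``, mean Earth radius R = 6371.0088 km),
accurate to well under 1% at the resolutions used here.

Nodata is represented internally as NaN; the ``nodata`` sentinel of the
GridSpec is only a serialization convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088
_DEG = math.pi / 180.0


class RasterFormatError(ValueError):
    """Malformed raster file (missing header key, ragged body, bad tags)."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid (EPSG:4326, north-up)."""

    n_rows: int
    n_cols: int
    x_min: float
    y_max: float
    dx: float
    dy: float
    nodata: float = -9999.0
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes dx, dy must be positive")
        if not (-180.0 <= self.x_min < 180.0):
            raise ValueError(f"x_min {self.x_min} outside [-180, 180)")
        if self.y_max - self.n_rows * self.dy < -90.0 - 1e-9:
            raise ValueError("grid extends south of -90 latitude")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.dx

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.dy

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.x_min + (col + 0.5) * self.dx,
                self.y_max - (row + 0.5) * self.dy)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectors of column-center longitudes and row-center latitudes."""
        lons = self.x_min + (np.arange(self.n_cols) + 0.5) * self.dx
        lats = self.y_max - (np.arange(self.n_rows) + 0.5) * self.dy
        return lons, lats

    def index_of(self, lon: float | np.ndarray, lat: float | np.ndarray):
        """Half-open nearest-cell lookup; returns (row, col) int arrays.

        Out-of-bounds points get index -1 in the offending axis.
        """
        col = np.floor((np.asarray(lon, dtype=float) - self.x_min) / self.dx)
        row = np.floor((self.y_max - np.asarray(lat, dtype=float)) / self.dy)
        # a point exactly on the north/west boundary belongs to row/col 0;
        # the south/east outer edge is outside (half-open convention)
        col = np.where((col >= 0) & (col < self.n_cols), col, -1)
        row = np.where((row >= 0) & (row < self.n_rows), row, -1)
        # y exactly == y_max gives row -0.0 -> 0 already; lat == y_min -> n_rows (out)
        return row.astype(int), col.astype(int)


@dataclass
class RasterGrid:
    """One georeferenced value surface. ``values[0]`` is the northernmost row."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.n_rows}, {self.spec.n_cols})")
        if np.isinf(self.values).any():
            raise ValueError("raster contains non-finite (inf) values")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.spec, np.asarray(values, dtype=float))


@dataclass
class RasterStack:
    """Ordered mapping of variable code -> RasterGrid on one shared GridSpec."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack must contain at least one layer")
        specs = {g.spec for g in self.layers.values()}
        if len(specs) > 1:
            raise ValueError("all layers in a stack must share one GridSpec")

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.layers.values())).spec

    @property
    def codes(self) -> list[str]:
        return list(self.layers)

    def valid_mask(self) -> np.ndarray:
        """Cells with data in every layer (nodata propagates across layers)."""
        m = np.ones((self.spec.n_rows, self.spec.n_cols), dtype=bool)
        for g in self.layers.values():
            m &= g.mask
        return m

    def as_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) array in layer order."""
        return np.stack([g.values for g in self.layers.values()])


def cell_geometry(spec: GridSpec, row: int, col: int) -> tuple[float, float, float]:
    """Center longitude, center latitude and spherical area (km^2) of a cell."""
    if not (0 <= row < spec.n_rows and 0 <= col < spec.n_cols):
        raise IndexError(f"cell ({row}, {col}) outside grid "
                         f"({spec.n_rows} x {spec.n_cols})")
    lon, lat = spec.cell_center(row, col)
    area = spec.dx * spec.dy * (_DEG * EARTH_RADIUS_KM) ** 2 * math.cos(lat * _DEG)
    return lon, lat, area


def cell_area_rows(spec: GridSpec) -> np.ndarray:
    """Per-row cell area vector (km^2); area varies only with latitude."""
    _, lats = spec.cell_centers()
    return spec.dx * spec.dy * (_DEG * EARTH_RADIUS_KM) ** 2 * np.cos(lats * _DEG)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance on the mean-radius sphere, in km. Vectorized."""
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) * _DEG
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_ASCII_KEYS = ("ncols", "nrows", "cellsize")


def _read_esri_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and not _is_number(parts[0]):
            header[parts[0].lower()] = float(parts[1])
        else:
            body_start = i
            break
    else:
        body_start = len(lines)
    for key in _ASCII_KEYS:
        if key not in header:
            raise RasterFormatError(f"ESRI ASCII header missing key '{key}'")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x_min = header["xllcorner"]
    elif "xllcenter" in header:
        x_min = header["xllcenter"] - cell / 2.0
    else:
        raise RasterFormatError("ESRI ASCII header missing key 'xllcorner'")
    if "yllcorner" in header:
        y_ll = header["yllcorner"]
    elif "yllcenter" in header:
        y_ll = header["yllcenter"] - cell / 2.0
    else:
        raise RasterFormatError("ESRI ASCII header missing key 'yllcorner'")
    nodata = header.get("nodata_value", -9999.0)

    rows = []
    for line in lines[body_start:]:
        parts = line.split()
        if parts:
            rows.append([float(p) for p in parts])
    flat = [v for r in rows for v in r]
    if len(flat) != n_rows * n_cols:
        raise RasterFormatError(
            f"body has {len(flat)} values, expected {n_rows * n_cols} "
            f"({n_rows} rows x {n_cols} cols)")
    values = np.asarray(flat, dtype=float).reshape(n_rows, n_cols)
    values[values == nodata] = np.nan
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, x_min=x_min,
                    y_max=y_ll + n_rows * cell, dx=cell, dy=cell, nodata=nodata)
    return RasterGrid(spec, values)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _write_esri_ascii(grid: RasterGrid, path: Path) -> None:
    spec = grid.spec
    if abs(spec.dx - spec.dy) > 1e-12:
        raise ValueError("ESRI ASCII requires square cells (dx == dy)")
    vals = np.where(grid.mask, grid.values, spec.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_min:.10g}\n")
        fh.write(f"yllcorner {spec.y_min:.10g}\n")
        fh.write(f"cellsize {spec.dx:.10g}\n")
        fh.write(f"NODATA_value {spec.nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Minimal single-band GeoTIFF I/O (ModelPixelScale/ModelTiepoint/GDAL_NODATA)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeyDirectory declaring geographic WGS84 (EPSG:4326)
_GEO_KEYS_4326 = (1, 1, 0, 3,
                  1024, 0, 1, 2,      # GTModelTypeGeoKey = geographic
                  1025, 0, 1, 1,      # GTRasterTypeGeoKey = PixelIsArea
                  2048, 0, 1, 4326)   # GeographicTypeGeoKey


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    import tifffile

    spec = grid.spec
    data = np.where(grid.mask, grid.values, spec.nodata).astype("<f8")
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.dx, spec.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x_min, spec.y_max, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS_4326), _GEO_KEYS_4326),
        (_TAG_GDAL_NODATA, "s", 0, f"{spec.nodata:.10g}"),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_geotiff(path: Path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise RasterFormatError(
                f"GeoTIFF missing georeferencing tag {exc}") from None
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    if data.ndim != 2:
        raise RasterFormatError("only single-band GeoTIFF rasters are supported")
    x_min = tie[3] - tie[0] * sx
    y_max = tie[4] + tie[1] * sy
    values = data.copy()
    values[values == nodata] = np.nan
    spec = GridSpec(n_rows=data.shape[0], n_cols=data.shape[1], x_min=x_min,
                    y_max=y_max, dx=float(sx), dy=float(sy), nodata=nodata)
    return RasterGrid(spec, values)


def read_raster(path: str | Path, format: str | None = None) -> RasterGrid:
    """Read a raster in ESRI ASCII (.asc) or single-band GeoTIFF dialect.

    ``format`` may be "esri_ascii" or "geotiff"; if None it is inferred from
    the file suffix.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "esri_ascii":
        return _read_esri_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_raster(grid: RasterGrid, path: str | Path,
                 format: str | None = None) -> Path:
    """Write a raster; nodata cells are serialized as the spec sentinel."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "esri_ascii":
        _write_esri_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt"}:
        return "esri_ascii"
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise ValueError(f"cannot infer raster format from suffix {suffix!r}")


# ---------------------------------------------------------------------------
# Point extraction

def extract_at_points(stack: RasterStack, lons, lats) -> pd.DataFrame:
    """Nearest-cell values of every layer at the given points.

    Returns a DataFrame with one row per point and one column per variable,
    plus ``row``/``col`` cell indices. Points outside the grid or on nodata
    cells yield NaN entries; the count of such points is available via the
    ``attrs['n_outside']`` / ``attrs['n_nodata']`` metadata on the result.
    Extraction is invariant under layer reordering (pure per-layer lookup).
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if not (np.isfinite(lons).all() and np.isfinite(lats).all()):
        raise ValueError("point coordinates must be finite")
    spec = stack.spec
    row, col = spec.index_of(lons, lats)
    inside = (row >= 0) & (col >= 0)
    out = pd.DataFrame({"lon": lons, "lat": lats, "row": row, "col": col})
    for code, grid in stack.layers.items():
        vals = np.full(len(lons), np.nan)
        vals[inside] = grid.values[row[inside], col[inside]]
        out[code] = vals
    value_cols = stack.codes
    n_nodata = int((inside & out[value_cols].isna().any(axis=1)).sum())
    out.attrs["n_outside"] = int((~inside).sum())
    out.attrs["n_nodata"] = n_nodata
    out.loc[~inside, ["row", "col"]] = -1
    return out
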