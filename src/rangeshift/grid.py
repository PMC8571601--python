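"""Raster data model: georeferenced grids, aligned layer stacks, file I/O,
and spheroid cell-area geometry.

Conventions
-----------
Grids are geographic (lon/lat degrees) with square cells. Row 0 is the
northernmost row; longitude increases with column. ``origin`` is the
(west, north) *corner* of the grid. Point-to-cell lookups use half-open
cell intervals ``[edge, edge + resolution)``.

Nodata is represented internally by a boolean mask, regardless of the
sentinel value used on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: WGS-84 authalic earth radius, km.
EARTH_RADIUS_KM = 6371.0088

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """A raster file failed to parse, naming the offending field."""


class AlignmentError(ValueError):
    """Grids with mismatching geometry were combined."""


@dataclass
class Grid:
    """One georeferenced raster layer.

    Parameters
    ----------
    values : (nrows, ncols) float array
        Cell values; content at masked cells is ignored.
    nodata_mask : (nrows, ncols) bool array
        True where the cell holds no data.
    origin : (float, float)
        (west longitude, north latitude) of the grid's NW corner, degrees.
    resolution : float
        Cell size in degrees (square cells).
    crs_label : str
        Informational tag; geographic lon/lat is assumed throughout.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    origin: tuple[float, float]
    resolution: float
    crs_label: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite values outside the nodata mask")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def west(self) -> float:
        return self.origin[0]

    @property
    def north(self) -> float:
        return self.origin[1]

    def geometry(self) -> tuple:
        return (self.shape, self.origin, self.resolution)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and math.isclose(self.resolution, other.resolution)
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (half-open intervals)."""
        col = int(math.floor((lon - self.west) / self.resolution))
        row = int(math.floor((self.north - lat) / self.resolution))
        # points exactly on the north/west edge belong to the first cell
        if lat == self.north:
            row = 0
        if row < 0 or row >= self.n_rows or col < 0 or col >= self.n_cols:
            raise IndexError(f"point ({lon}, {lat}) outside grid bounds")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.west + (col + 0.5) * self.resolution
        lat = self.north - (row + 0.5) * self.resolution
        return lon, lat

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        return Grid(
            values=np.asarray(values, dtype=float),
            nodata_mask=self.nodata_mask.copy() if mask is None else np.asarray(mask, bool),
            origin=self.origin,
            resolution=self.resolution,
            crs_label=self.crs_label,
        )


def cell_area_km2(row: int, grid: Grid) -> float:
    """Area in km² of any cell in the given grid row.

    Spherical-zone formula: ``R² · Δλ · (sin φ_top − sin φ_bottom)`` with
    R the authalic earth radius. Constant along a row; strictly decreasing
    with |latitude|.
    """
    if row < 0 or row >= grid.n_rows:
        raise IndexError(f"row {row} out of range for grid with {grid.n_rows} rows")
    res = grid.resolution
    phi_top = math.radians(grid.north - row * res)
    phi_bot = math.radians(grid.north - (row + 1) * res)
    dlam = math.radians(res)
    return EARTH_RADIUS_KM**2 * dlam * (math.sin(phi_top) - math.sin(phi_bot))


def row_areas_km2(grid: Grid) -> np.ndarray:
    """Vector of per-row cell areas (km²) for the whole grid."""
    res = grid.resolution
    rows = np.arange(grid.n_rows)
    phi_top = np.radians(grid.north - rows * res)
    phi_bot = np.radians(grid.north - (rows + 1) * res)
    return EARTH_RADIUS_KM**2 * math.radians(res) * (np.sin(phi_top) - np.sin(phi_bot))


@dataclass
class LayerStack:
    """Aligned, named grids forming a predictor space."""

    layers: dict[str, Grid]
    union_nodata: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        ref = next(iter(self.layers.values()))
        bad = [n for n, g in self.layers.items() if not ref.same_geometry(g)]
        if bad:
            raise AlignmentError(f"layers not aligned with first layer: {bad}")
        mask = np.zeros(ref.shape, dtype=bool)
        for g in self.layers.values():
            mask |= g.nodata_mask
        self.union_nodata = mask

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> Grid:
        return next(iter(self.layers.values()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.template.shape

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def valid_values(self, names: list[str] | None = None) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix of values at shared valid cells."""
        names = names or self.names
        ok = ~self.union_nodata
        return np.column_stack([self.layers[n].values[ok] for n in names])

    def values_at(self, lons: np.ndarray, lats: np.ndarray,
                  names: list[str] | None = None) -> np.ndarray:
        """Extract layer values at points; raises if any point is on nodata."""
        names = names or self.names
        tpl = self.template
        rows = np.empty(len(lons), dtype=int)
        cols = np.empty(len(lons), dtype=int)
        for i, (lo, la) in enumerate(zip(lons, lats)):
            rows[i], cols[i] = tpl.cell_of(lo, la)
        if np.any(self.union_nodata[rows, cols]):
            n_bad = int(self.union_nodata[rows, cols].sum())
            raise ValueError(f"{n_bad} point(s) fall on nodata cells")
        return np.column_stack([self.layers[n].values[rows, cols] for n in names]), rows, cols

    def subset(self, names: list[str]) -> "LayerStack":
        return LayerStack({n: self.layers[n] for n in names})


def align_stack(grids: dict[str, Grid]) -> LayerStack:
    """Assemble named grids into a stack, verifying shared geometry."""
    return LayerStack(dict(grids))


# -- ESRI ASCII grid I/O --------------------------------------------------

_ASCII_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}


def _read_ascii_grid(path: str) -> Grid:
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS | {"nodata_value", "dx", "dy"}:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"unparseable header value for '{parts[0]}'") from exc
        else:
            data_start = i
            break
    missing = _ASCII_HEADER_KEYS - header.keys()
    if missing:
        raise GridFormatError(f"missing ASCII grid header field(s): {sorted(missing)}")
    if "dx" in header or "dy" in header:
        raise GridFormatError("non-square cells (dx/dy headers) are not supported")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    try:
        values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise GridFormatError("unparseable data block") from exc
    if values.shape != (nrows, ncols):
        raise GridFormatError(
            f"data block shape {values.shape} does not match header "
            f"nrows/ncols ({nrows}, {ncols})"
        )
    mask = values == nodata
    res = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * res)
    vals = values.copy()
    vals[mask] = np.nan
    vals[mask] = 0.0
    return Grid(values=vals, nodata_mask=mask, origin=origin, resolution=res)


def _write_ascii_grid(grid: Grid, path: str, nodata: float = DEFAULT_NODATA) -> None:
    vals = grid.values.copy()
    vals[grid.nodata_mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.west!r}\n")
        fh.write(f"yllcorner {grid.north - grid.n_rows * grid.resolution!r}\n")
        fh.write(f"cellsize {grid.resolution!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, vals, fmt="%.17g")


# -- GeoTIFF I/O (tifffile + standard geo tags) ---------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: str) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags:
            raise GridFormatError("GeoTIFF missing ModelPixelScale tag")
        if _TAG_MODEL_TIEPOINT not in tags:
            raise GridFormatError("GeoTIFF missing ModelTiepoint tag")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
            except ValueError as exc:
                raise GridFormatError("unparseable GDAL_NODATA tag") from exc
    if values.ndim != 2:
        raise GridFormatError("only single-band GeoTIFFs are supported")
    sx, sy = float(scale[0]), float(scale[1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise GridFormatError(f"non-square pixels: ModelPixelScale x={sx} != y={sy}")
    if float(tie[0]) != 0.0 or float(tie[1]) != 0.0:
        raise GridFormatError("ModelTiepoint must anchor raster pixel (0, 0)")
    origin = (float(tie[3]), float(tie[4]))
    mask = (values == nodata) | ~np.isfinite(values)
    vals = values.copy()
    vals[mask] = 0.0
    return Grid(values=vals, nodata_mask=mask, origin=origin, resolution=sx)


def _write_geotiff(grid: Grid, path: str, nodata: float = DEFAULT_NODATA) -> None:
    import tifffile

    vals = grid.values.astype(np.float64).copy()
    vals[grid.nodata_mask] = nodata
    res = float(grid.resolution)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(grid.west), float(grid.north), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_grid(path, format: str | None = None) -> Grid:
    """Read a raster from GeoTIFF or ESRI ASCII grid.

    ``format`` is 'geotiff' or 'ascii_grid'; inferred from the extension
    when omitted (.tif/.tiff → geotiff, .asc/.txt → ascii_grid).
    """
    path = str(path)
    if format is None:
        format = "geotiff" if path.lower().endswith((".tif", ".tiff")) else "ascii_grid"
    if format == "geotiff":
        return _read_geotiff(path)
    if format == "ascii_grid":
        return _read_ascii_grid(path)
    raise ValueError(f"unknown raster format: {format!r}")


def write_grid(grid: Grid, path, format: str | None = None,
               nodata: float = DEFAULT_NODATA) -> None:
    """Write a raster as GeoTIFF or ESRI ASCII grid (see :func:`read_grid`)."""
    path = str(path)
    if format is None:
        format = "geotiff" if path.lower().endswith((".tif", ".tiff")) else "ascii_grid"
    if format == "geotiff":
        _write_geotiff(grid, path, nodata=nodata)
    elif format == "ascii_grid":
        _write_ascii_grid(grid, path, nodata=nodata)
    else:
        raise ValueError(f"unknown raster format: {format!r}")


def grid_info(path: str) -> dict:
    """Summary metadata for a raster file (CLI `grid info` backend)."""
    g = read_grid(path)
    ok = ~g.nodata_mask
    return {
        "path": path,
        "shape": list(g.shape),
        "origin_west": g.west,
        "origin_north": g.north,
        "resolution_deg": g.resolution,
        "crs": g.crs_label,
        "n_valid": int(ok.sum()),
        "n_nodata": int(g.nodata_mask.sum()),
        "min": float(g.values[ok].min()) if ok.any() else None,
        "max": float(g.values[ok].max()) if ok.any() else None,
    }
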