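"""Gridded environmental layers: ESRI ASCII I/O, alignment, point extraction,
and geodesic cell areas.

Conventions (inherited by every other module):

* row 0 is the northernmost row, matching the ESRI ASCII grid layout;
* grids are corner-registered (``xllcorner``/``yllcorner``); the
  ``xllcenter`` dialect is converted on read;
* cell intervals are half-open ``[west, east) x [south, north)`` with points
  on the outer north/east edge clamped into the last row/column;
* nodata cells are held as NaN in memory and written back as the declared
  sentinel token.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    AlignmentError,
    FormatError,
    OutOfBoundsError,
    ValidationError,
)

EARTH_RADIUS_KM = 6371.0088
ALIGN_TOL = 1e-9

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "Raster",
    "RasterStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "assemble_stack",
    "cell_of",
    "cell_center",
    "extract_at_points",
    "cell_area_km2",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid with square cells (degrees)."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self):
        if self.ncols < 1 or self.nrows < 1:
            raise ValidationError(
                f"grid must have at least one cell, got {self.nrows}x{self.ncols}"
            )
        if not self.cellsize > 0:
            raise ValidationError(f"cellsize must be positive, got {self.cellsize}")
        if (
            self.xllcorner < -180 - ALIGN_TOL
            or self.xllcorner + self.ncols * self.cellsize > 180 + 1e-6
            or self.yllcorner < -90 - ALIGN_TOL
            or self.yllcorner + self.nrows * self.cellsize > 90 + 1e-6
        ):
            raise ValidationError("grid extends outside [-180,180] x [-90,90]")

    @property
    def xmax(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    def aligned_with(self, other: "GridSpec", tol: float = ALIGN_TOL) -> bool:
        """True iff the five geometry fields agree within ``tol`` degrees."""
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def misaligned_field(self, other: "GridSpec", tol: float = ALIGN_TOL):
        """Name of the first differing geometry field, or None if aligned."""
        if self.ncols != other.ncols:
            return "ncols"
        if self.nrows != other.nrows:
            return "nrows"
        for name in ("xllcorner", "yllcorner", "cellsize"):
            if abs(getattr(self, name) - getattr(other, name)) > tol:
                return name
        return None


@dataclass
class Raster:
    """One environmental layer: a GridSpec plus an (nrows, ncols) value
    matrix with NaN marking nodata."""

    spec: GridSpec
    values: np.ndarray
    name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValidationError(
                f"layer {self.name!r}: values shape {self.values.shape} does not "
                f"match grid {self.spec.nrows}x{self.spec.ncols}"
            )
        if not self.name:
            raise ValidationError("raster name must be nonempty")
        if np.isinf(self.values).any():
            raise ValidationError(f"layer {self.name!r}: infinite cell values")

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Raster":
        return Raster(self.spec, values, name if name is not None else self.name)


@dataclass
class RasterStack:
    """Ordered collection of aligned layers with unique names, plus an
    optional boolean study-region mask."""

    layers: list[Raster]
    mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.layers:
            raise ValidationError("stack needs at least one layer")
        ref = self.layers[0].spec
        for lyr in self.layers[1:]:
            bad = ref.misaligned_field(lyr.spec)
            if bad is not None:
                raise AlignmentError(
                    f"layer {lyr.name!r} misaligned with {self.layers[0].name!r}: "
                    f"field {bad} differs"
                )
        names = [lyr.name for lyr in self.layers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate layer names: {dupes}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (ref.nrows, ref.ncols):
                raise AlignmentError("mask shape does not match the stack grid")

    @property
    def spec(self) -> GridSpec:
        return self.layers[0].spec

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def get(self, name: str) -> Raster:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def valid_mask(self) -> np.ndarray:
        """Cells finite in every layer and inside the mask (if any)."""
        ok = ~np.isnan(self.layers[0].values)
        for lyr in self.layers[1:]:
            ok &= ~np.isnan(lyr.values)
        if self.mask is not None:
            ok &= self.mask
        return ok

    def subset(self, names) -> "RasterStack":
        return RasterStack([self.get(n) for n in names], mask=self.mask)


_HEADER_KEYS = ("ncols", "nrows", "cellsize")


def read_ascii_grid(path, name: str | None = None) -> Raster:
    """Read an ESRI ASCII grid.

    Accepts both ``xllcorner`` and ``xllcenter`` registration (center is
    converted to corner by subtracting half a cell).  Nodata tokens become
    NaN.  ``name`` defaults to the file stem.
    """
    import os

    header: dict[str, float] = {}
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not tokens and key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
            ):
                if len(parts) != 2:
                    raise FormatError(f"{path}: malformed header line {line!r}")
                header[key] = float(parts[1])
            else:
                tokens.extend(parts)

    for key in _HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: header missing required key {key!r}")
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - header["cellsize"] / 2
    else:
        raise FormatError(f"{path}: header missing required key 'xllcorner'")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - header["cellsize"] / 2
    else:
        raise FormatError(f"{path}: header missing required key 'yllcorner'")

    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    if len(tokens) != nrows * ncols:
        raise FormatError(
            f"{path}: expected {nrows * ncols} value tokens, found {len(tokens)}"
        )
    try:
        values = np.array(tokens, dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value token ({exc})") from exc
    values[values == nodata] = np.nan
    spec = GridSpec(ncols, nrows, xll, yll, header["cellsize"], nodata)
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return Raster(spec, values, name)


def write_ascii_grid(raster: Raster, path) -> str:
    """Write an ESRI ASCII grid (corner registration, full float precision).

    NaN cells are emitted as the grid's nodata sentinel.
    """
    spec = raster.spec
    out = raster.values.copy()
    out[np.isnan(out)] = spec.nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {float(spec.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(spec.yllcorner)!r}\n")
        fh.write(f"cellsize {float(spec.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(spec.nodata_value)!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    return str(path)


def assemble_stack(rasters, mask: Raster | None = None) -> RasterStack:
    """Bundle aligned rasters into a stack; a mask raster (nonzero = inside)
    may be supplied."""
    rasters = list(rasters)
    if not rasters:
        raise ValidationError("cannot assemble an empty stack")
    mask_arr = None
    if mask is not None:
        bad = rasters[0].spec.misaligned_field(mask.spec)
        if bad is not None:
            raise AlignmentError(f"mask misaligned with stack: field {bad} differs")
        mask_arr = np.nan_to_num(mask.values, nan=0.0) != 0
    return RasterStack(rasters, mask=mask_arr)


def cell_of(lon: float, lat: float, spec: GridSpec) -> tuple[int, int]:
    """Map a point to its (row, col); row 0 is north.

    Cells are half-open; a point exactly on the outer north/east edge maps
    into the last row/column.
    """
    if not (
        spec.xllcorner <= lon <= spec.xmax and spec.yllcorner <= lat <= spec.ymax
    ):
        raise OutOfBoundsError(
            f"point ({lon}, {lat}) outside grid bounds "
            f"[{spec.xllcorner}, {spec.xmax}] x [{spec.yllcorner}, {spec.ymax}]",
            points=[(lon, lat)],
        )
    col = int(math.floor((lon - spec.xllcorner) / spec.cellsize))
    row_s = int(math.floor((lat - spec.yllcorner) / spec.cellsize))
    col = min(col, spec.ncols - 1)
    row_s = min(row_s, spec.nrows - 1)
    return spec.nrows - 1 - row_s, col


def cell_center(row: int, col: int, spec: GridSpec) -> tuple[float, float]:
    """(lon, lat) of the center of cell (row, col)."""
    lon = spec.xllcorner + (col + 0.5) * spec.cellsize
    lat = spec.yllcorner + (spec.nrows - row - 0.5) * spec.cellsize
    return lon, lat


def extract_at_points(stack: RasterStack, lons, lats):
    """Extract layer values at points.

    Returns a DataFrame with columns ``point_id, lon, lat, <layer names...>,
    has_nodata``.  Rows that hit nodata in any layer are flagged, never
    silently dropped.  Out-of-bounds points raise, listing the offending
    indices.
    """
    import pandas as pd

    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    spec = stack.spec
    oob = [
        i
        for i, (x, y) in enumerate(zip(lons, lats))
        if not (spec.xllcorner <= x <= spec.xmax and spec.yllcorner <= y <= spec.ymax)
    ]
    if oob:
        raise OutOfBoundsError(
            f"{len(oob)} point(s) outside grid bounds, indices {oob}", points=oob
        )
    rows = np.empty(len(lons), dtype=int)
    cols = np.empty(len(lons), dtype=int)
    for i, (x, y) in enumerate(zip(lons, lats)):
        rows[i], cols[i] = cell_of(x, y, spec)
    data = {"point_id": np.arange(len(lons)), "lon": lons, "lat": lats}
    for lyr in stack.layers:
        data[lyr.name] = lyr.values[rows, cols]
    df = pd.DataFrame(data)
    df["has_nodata"] = df[stack.names].isna().any(axis=1)
    if stack.mask is not None:
        df.loc[~stack.mask[rows, cols], "has_nodata"] = True
    return df


def cell_area_km2(spec: GridSpec, row: int) -> float:
    """Spherical area (km^2) of one cell in the given row.

    ``R^2 * dlambda * (sin(phi_n) - sin(phi_s))`` with the row's cell edges;
    strictly positive and decreasing toward the poles.
    """
    if not 0 <= row < spec.nrows:
        raise ValidationError(f"row {row} outside [0, {spec.nrows})")
    north = spec.yllcorner + (spec.nrows - row) * spec.cellsize
    south = north - spec.cellsize
    dlam = math.radians(spec.cellsize)
    return (
        EARTH_RADIUS_KM**2
        * dlam
        * (math.sin(math.radians(north)) - math.sin(math.radians(south)))
    )


def row_areas_km2(spec: GridSpec) -> np.ndarray:
    """Vector of per-cell areas by row (all cells in a row share an area)."""
    rows = np.arange(spec.nrows)
    north = spec.yllcorner + (spec.nrows - rows) * spec.cellsize
    south = north - spec.cellsize
    dlam = np.radians(spec.cellsize)
    return (
        EARTH_RADIUS_KM**2
        * dlam
        * (np.sin(np.radians(north)) - np.sin(np.radians(south)))
    )


def area_grid_km2(spec: GridSpec) -> np.ndarray:
    """(nrows, ncols) matrix of cell areas in km^2."""
    return np.repeat(row_areas_km2(spec)[:, None], spec.ncols, axis=1)
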