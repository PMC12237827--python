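"""Gridded containers shared across the pipeline.

All rasters live on a regular longitude-latitude lattice described by
:class:`Grid`. Cell areas use the spherical cosine formula with Earth radius
R = 6371 km, so range areas are comparable across latitudes.

Rasters are serialised as ESRI ASCII grids (plain text); a multi-layer
climate stack is a directory of one ``.asc`` per variable plus a JSON
sidecar naming the layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = 2.0 * np.pi * EARTH_RADIUS_KM / 360.0  # ~111.195 km per degree


class GridError(ValueError):
    """Raised when two rasters do not share a lattice."""


@dataclass(frozen=True)
class Grid:
    """Regular lon-lat lattice.

    Row 0 is the *northernmost* row (image convention). ``origin`` is the
    lower-left corner of the lattice in degrees.
    """

    n_rows: int
    n_cols: int
    cell_size: float  # degrees, square cells
    origin_lon: float = -180.0
    origin_lat: float = -90.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row centre, row 0 at the top."""
        top = self.origin_lat + self.n_rows * self.cell_size
        return top - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); -1 where off-grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        top = self.origin_lat + self.n_rows * self.cell_size
        row = np.floor((top - lat) / self.cell_size).astype(int)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        row = np.where(ok, row, -1)
        col = np.where(ok, col, -1)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        top = self.origin_lat + self.n_rows * self.cell_size
        lat = top - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row cell area, broadcast to the full lattice.

        area = (R dlon)(R dlat) cos(lat_centre), dlon/dlat in radians.
        """
        dlat = np.deg2rad(self.cell_size)
        dlon = np.deg2rad(self.cell_size)
        lat = np.deg2rad(self.lat_centers())
        row_area = (EARTH_RADIUS_KM * dlon) * (EARTH_RADIUS_KM * dlat) * np.cos(lat)
        return np.repeat(row_area[:, None], self.n_cols, axis=1)

    def same_lattice(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
        )


def _require_same_lattice(a: Grid, b: Grid) -> None:
    if not a.same_lattice(b):
        raise GridError(f"lattice mismatch: {a} vs {b}")


@dataclass
class ClimateStack:
    """Co-registered climate predictor rasters with a shared nodata mask."""

    grid: Grid
    layer_names: list[str]
    values: np.ndarray  # (V, n_rows, n_cols)
    nodata_mask: np.ndarray  # True where nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        v, r, c = self.values.shape
        if v != len(self.layer_names):
            raise ValueError("layer_names length must match values' first axis")
        if (r, c) != self.grid.shape or self.nodata_mask.shape != self.grid.shape:
            raise ValueError("values and nodata_mask must match the grid shape")
        if not np.isfinite(self.values[:, ~self.nodata_mask]).all():
            raise ValueError("non-finite values off the nodata mask")

    @property
    def n_vars(self) -> int:
        return len(self.layer_names)

    def env_table(self) -> np.ndarray:
        """(n_valid_cells, V) environment matrix over off-nodata cells."""
        valid = ~self.nodata_mask
        return self.values[:, valid].T

    def valid_cells(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(~self.nodata_mask)

    def env_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.values[:, rows, cols].T

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, name in enumerate(self.layer_names):
            layer = np.where(self.nodata_mask, np.nan, self.values[i])
            write_ascii_grid(path / f"{name}.asc", self.grid, layer)
        meta = {"layer_names": self.layer_names, "crs": "EPSG:4326"}
        (path / "stack.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ClimateStack":
        path = Path(path)
        meta = json.loads((path / "stack.json").read_text())
        names = meta["layer_names"]
        layers, grid = [], None
        for name in names:
            g, vals = read_ascii_grid(path / f"{name}.asc")
            if grid is None:
                grid = g
            elif not grid.same_lattice(g):
                raise GridError(f"layer {name} is on a different lattice")
            layers.append(vals)
        values = np.stack(layers)
        mask = ~np.isfinite(values).all(axis=0)
        values = np.where(mask, 0.0, values)
        return cls(grid=grid, layer_names=names, values=values, nodata_mask=mask)


@dataclass
class SuitabilityMap:
    """Continuous habitat suitability in [0, 1] on a lattice."""

    grid: Grid
    values: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        off = self.values[~self.nodata_mask]
        if off.size and (off.min() < -1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1] off-mask")

    def to_ascii(self, path: str | Path) -> None:
        write_ascii_grid(path, self.grid, np.where(self.nodata_mask, np.nan, self.values))


@dataclass
class RangeMask:
    """Binary potential-range raster with spherical area accounting."""

    grid: Grid
    values: np.ndarray  # boolean
    area_km2: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape must match the grid")
        self.area_km2 = float(self.grid.cell_areas_km2()[self.values].sum())

    @property
    def n_cells(self) -> int:
        return int(self.values.sum())

    def intersection(self, other: "RangeMask") -> "RangeMask":
        _require_same_lattice(self.grid, other.grid)
        return RangeMask(self.grid, self.values & other.values)

    def difference(self, other: "RangeMask") -> "RangeMask":
        _require_same_lattice(self.grid, other.grid)
        return RangeMask(self.grid, self.values & ~other.values)

    def centroid(self) -> tuple[float, float]:
        """Area-weighted (lon, lat) centroid of the true cells."""
        if not self.values.any():
            raise ValueError("empty range mask has no centroid")
        w = self.grid.cell_areas_km2() * self.values
        lon = self.grid.lon_centers()[None, :]
        lat = self.grid.lat_centers()[:, None]
        total = w.sum()
        return float((w * lon).sum() / total), float((w * lat).sum() / total)

    def to_ascii(self, path: str | Path) -> None:
        write_ascii_grid(path, self.grid, self.values.astype(float))


def great_circle_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Haversine distance on the R = 6371 km sphere."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


# --- ESRI ASCII grid text I/O -------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: Grid, values: np.ndarray) -> None:
    values = np.asarray(values, dtype=float)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    body = np.where(np.isfinite(values), values, _NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[Grid, np.ndarray]:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = Grid(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"],
    )
    values = np.atleast_2d(values)
    values = np.where(values == header["nodata_value"], np.nan, values)
    return grid, values
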