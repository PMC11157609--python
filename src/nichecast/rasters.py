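"""Geographic grid geometry and raster containers.

All rasters in this package live on a regular longitude/latitude grid
(WGS84 decimal degrees).  Arrays are stored row-major with row 0 at the
*northern* edge, matching the ESRI ASCII grid convention.  Cell membership
is half-open: a point belongs to cell (i, j) iff
``west + j*cs <= lon < west + (j+1)*cs`` and similarly in latitude,
anchored on the south-west corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Mean Earth radius in kilometres (IUGG R1).
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid: south-west corner, square cell size, shape."""

    west: float
    south: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    @property
    def north(self) -> float:
        return self.south + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        """Longitudes of column centers, west to east."""
        j = np.arange(self.n_cols)
        return self.west + (j + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south (row 0 first)."""
        i = np.arange(self.n_rows)
        return self.north - (i + 0.5) * self.cell_size

    def cell_index(self, lon, lat):
        """Map coordinates to (row, col); -1 where outside the grid.

        Half-open intervals anchored on the south-west corner; the north
        and east outer edges are outside.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.cell_size).astype(int)
        row_s = np.floor((lat - self.south) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_s
        inside = (col >= 0) & (col < self.n_cols) & (row_s >= 0) & (row_s < self.n_rows)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.west + (col + 0.5) * self.cell_size
        lat = self.north - (row + 0.5) * self.cell_size
        return lon, lat


def cell_areas_km2(grid: GridGeometry) -> np.ndarray:
    """Per-row spherical cell area in km^2.

    Each cell is a spherical quadrangle; its area is
    R^2 * dlon_rad * (sin(lat_north) - sin(lat_south)), which depends on
    latitude only, so a single column is returned (length n_rows, row 0
    northernmost).
    """
    i = np.arange(grid.n_rows)
    lat_n = np.deg2rad(grid.north - i * grid.cell_size)
    lat_s = np.deg2rad(grid.north - (i + 1) * grid.cell_size)
    dlon = np.deg2rad(grid.cell_size)
    return EARTH_RADIUS_KM**2 * dlon * (np.sin(lat_n) - np.sin(lat_s))


def cell_area_grid_km2(grid: GridGeometry) -> np.ndarray:
    """Full (n_rows, n_cols) grid of spherical cell areas in km^2."""
    return np.repeat(cell_areas_km2(grid)[:, None], grid.n_cols, axis=1)


def _infer_layer_kind(name: str) -> str:
    """Classify a layer as temperature / precipitation / other by name.

    Recognises the bioclim convention (bio01-bio11 temperature,
    bio12-bio19 precipitation) and the words 'temp' / 'prec'.
    """
    low = name.lower()
    if low.startswith("bio"):
        try:
            num = int(low[3:].lstrip("_"))
        except ValueError:
            num = None
        if num is not None:
            return "temperature" if num <= 11 else "precipitation"
    if "temp" in low or low.startswith("t"):
        return "temperature"
    if "prec" in low or "rain" in low:
        return "precipitation"
    return "other"


@dataclass
class ClimateStack:
    """Aligned multi-layer climate raster with a shared nodata mask.

    ``nodata_mask`` is True where a cell is invalid (e.g. sea).  Every
    layer shares the same grid and mask, and every valid cell holds a
    finite value in every layer.
    """

    grid: GridGeometry
    layers: dict[str, np.ndarray]
    nodata_mask: np.ndarray
    layer_kinds: dict[str, str] = field(default_factory=dict)
    crs_note: str = "WGS84 geographic (EPSG:4326)"

    def __post_init__(self) -> None:
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError("nodata_mask shape does not match grid")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape does not match grid")
            if not np.all(np.isfinite(arr[~self.nodata_mask])):
                raise ValueError(f"layer {name!r} has non-finite valid cells")
            self.layers[name] = arr
        for name in self.layers:
            self.layer_kinds.setdefault(name, _infer_layer_kind(name))

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of valid cells in row-major order."""
        return np.nonzero(self.valid_mask)

    def env_matrix(self, variables: list[str] | None = None) -> np.ndarray:
        """(n_valid, n_vars) matrix of layer values over valid cells."""
        variables = list(self.layers) if variables is None else list(variables)
        missing = [v for v in variables if v not in self.layers]
        if missing:
            raise KeyError(f"stack is missing variable(s): {missing}")
        rows, cols = self.valid_indices()
        return np.column_stack([self.layers[v][rows, cols] for v in variables])

    def env_at_cells(self, rows, cols, variables: list[str]) -> np.ndarray:
        missing = [v for v in variables if v not in self.layers]
        if missing:
            raise KeyError(f"stack is missing variable(s): {missing}")
        return np.column_stack([self.layers[v][rows, cols] for v in variables])

    def same_geometry(self, other: "ClimateStack | SuitabilityRaster") -> bool:
        return self.grid == other.grid and np.array_equal(
            self.nodata_mask, other.nodata_mask
        )


@dataclass
class SuitabilityRaster:
    """Per-cell model output on a climate-stack grid.

    ``values`` holds NaN at nodata cells; ``kind`` is 'logistic' (bounded
    suitability in [0,1]) or 'raw' (Gibbs density over background).
    """

    grid: GridGeometry
    values: np.ndarray
    nodata_mask: np.ndarray
    kind: str = "logistic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError("nodata_mask shape does not match grid")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def same_geometry(self, other) -> bool:
        return self.grid == other.grid and np.array_equal(
            self.nodata_mask, other.nodata_mask
        )
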