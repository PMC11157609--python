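"""Range dynamics between climate periods.

Binary suitable/unsuitable matrices (p > 0.1), four-category change maps
(new / lost / retained / unsuitable), area-weighted range centroids with
geodesic displacement vectors, and cosine similarity between migration
vectors of different species or scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import (
    EARTH_RADIUS_KM,
    GridGeometry,
    SuitabilityRaster,
    cell_area_grid_km2,
)

CHANGE_LABELS = ("unsuitable", "new", "lost", "retained")
_CHANGE_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}


@dataclass
class BinaryRaster:
    """0/1 suitable mask on a raster grid (-1 at nodata)."""

    grid: GridGeometry
    values: np.ndarray
    nodata_mask: np.ndarray
    threshold: float

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def same_geometry(self, other) -> bool:
        return self.grid == other.grid and np.array_equal(self.nodata_mask,
                                                          other.nodata_mask)


def binarize(raster: SuitabilityRaster, threshold: float = 0.1) -> BinaryRaster:
    """Suitable (1) where p > threshold strictly, else 0; nodata -> -1."""
    values = np.full(raster.grid.shape, -1, dtype=int)
    valid = raster.valid_mask
    values[valid] = (raster.values[valid] > threshold).astype(int)
    return BinaryRaster(grid=raster.grid, values=values,
                        nodata_mask=raster.nodata_mask.copy(), threshold=threshold)


@dataclass
class ChangeRaster:
    """Four-way change classification between two periods.

    Categories: unsuitable (0->0), new (0->1), lost (1->0),
    retained (1->1).  The conservation identities
    retained + lost = current suitable and retained + new = future
    suitable hold exactly by construction.
    """

    grid: GridGeometry
    categories: np.ndarray  # codes per _CHANGE_CODE; -1 at nodata
    nodata_mask: np.ndarray
    areas_km2: dict[str, float]
    labels: tuple[str, ...] = CHANGE_LABELS

    def area_km2(self, label: str) -> float:
        return self.areas_km2[label]


def change_matrix(current: BinaryRaster, future: BinaryRaster) -> ChangeRaster:
    """Classify each valid cell by its (current, future) suitability pair."""
    if not current.same_geometry(future):
        raise ValueError("current and future binary grids have different geometry")
    valid = current.valid_mask
    cur = current.values
    fut = future.values
    cats = np.full(current.grid.shape, -1, dtype=int)
    cats[valid] = cur[valid] * 2 + fut[valid]  # 0:0->0, 1:0->1, 2:1->0, 3:1->1
    areas = cell_area_grid_km2(current.grid)
    area_of = {
        label: float(areas[valid & (cats == code)].sum())
        for (label, code) in zip(CHANGE_LABELS, range(4))
    }
    return ChangeRaster(grid=current.grid, categories=cats,
                        nodata_mask=current.nodata_mask.copy(), areas_km2=area_of)


def centroid(binary: BinaryRaster) -> tuple[float, float]:
    """Area-weighted mean coordinate of suitable cells.

    lon = sum(a_i lon_i)/sum(a_i), lat likewise, with a_i the spherical
    cell area; weights are the binary suitable mask, not suitability.
    """
    suitable = binary.valid_mask & (binary.values == 1)
    if not suitable.any():
        raise ValueError("no suitable cells; the centroid is undefined")
    areas = cell_area_grid_km2(binary.grid)
    rows, cols = np.nonzero(suitable)
    lon, lat = binary.grid.cell_center(rows, cols)
    w = areas[rows, cols]
    return float(np.average(lon, weights=w)), float(np.average(lat, weights=w))


@dataclass(frozen=True)
class Displacement:
    """Great-circle displacement between two centroids."""

    distance_km: float
    bearing_deg: float      # initial great-circle bearing, clockwise from north
    east_km: float          # local planar components at the mean latitude
    north_km: float

    @property
    def vector(self) -> tuple[float, float]:
        return (self.east_km, self.north_km)


def displacement(c1: tuple[float, float], c2: tuple[float, float]) -> Displacement:
    """Distance (haversine, R = 6371.0088 km), initial bearing, and local
    east/north components (equirectangular at the mean latitude)."""
    lon1, lat1 = np.deg2rad(c1)
    lon2, lat2 = np.deg2rad(c2)
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    dist = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    bearing = (np.rad2deg(np.arctan2(y, x)) + 360.0) % 360.0
    east = EARTH_RADIUS_KM * dlon * np.cos(0.5 * (lat1 + lat2))
    north = EARTH_RADIUS_KM * dlat
    return Displacement(distance_km=float(dist), bearing_deg=float(bearing),
                        east_km=float(east), north_km=float(north))


def cosine_similarity(v1: tuple[float, float], v2: tuple[float, float]) -> float:
    """Cosine of the angle between two displacement vectors (east, north).

    1 means the same direction, -1 opposite, 0 orthogonal; scale-invariant
    in both arguments.  Zero vectors have no direction and are rejected.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))


@dataclass
class CentroidTrack:
    """Sequence of range centroids across scenario/period labels, with
    displacement segments between consecutive entries."""

    points: pd.DataFrame     # columns: label, longitude, latitude
    segments: pd.DataFrame   # columns: from, to, distance_km, bearing_deg, east_km, north_km


def centroid_track(labels: list[str], binaries: list[BinaryRaster]) -> CentroidTrack:
    if len(labels) != len(binaries):
        raise ValueError("labels and rasters must pair up")
    pts = [centroid(b) for b in binaries]
    points = pd.DataFrame(
        {"label": labels, "longitude": [p[0] for p in pts],
         "latitude": [p[1] for p in pts]}
    )
    seg_rows = []
    for i in range(1, len(pts)):
        d = displacement(pts[i - 1], pts[i])
        seg_rows.append({
            "from": labels[i - 1], "to": labels[i],
            "distance_km": d.distance_km, "bearing_deg": d.bearing_deg,
            "east_km": d.east_km, "north_km": d.north_km,
        })
    segments = pd.DataFrame(
        seg_rows, columns=["from", "to", "distance_km", "bearing_deg",
                           "east_km", "north_km"]
    )
    return CentroidTrack(points=points, segments=segments)
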