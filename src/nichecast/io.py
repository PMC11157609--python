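"""File formats: ESRI ASCII grids, occurrence CSVs, stack manifests,
model JSON, and GeoJSON displacement vectors.

The ASCII grid writer emits values with repr-level precision ('%.17g'),
so a write/read round trip reproduces float64 arrays bit-exactly; the
reader parses header keys case-insensitively and accepts both cell-corner
(xllcorner/yllcorner) registration fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import CentroidTrack
from .maxent import MaxEntModel
from .occurrences import OccurrenceSet
from .rasters import ClimateStack, GridGeometry, SuitabilityRaster

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(
    path, values: np.ndarray, grid: GridGeometry,
    nodata_mask: np.ndarray | None = None, nodata_value: float = -9999.0,
) -> Path:
    """Write one 2-D layer as an ESRI ASCII grid (row 0 = north)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = values.copy()
    if nodata_mask is not None:
        out[np.asarray(nodata_mask, dtype=bool)] = nodata_value
    out[~np.isfinite(out)] = nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.west!r}\n")
        fh.write(f"yllcorner {grid.south!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata_value!r}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry, np.ndarray]:
    """Read an ESRI ASCII grid.

    Returns (values with NaN at nodata, grid, nodata_mask).  Header keys
    are parsed case-insensitively; a malformed header raises with the
    offending line.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {i + 1}: cannot parse header value {parts[1]!r}"
                ) from exc
        else:
            data_lines = lines[i:]
            break
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: header missing field(s) {missing} by line {i + 1}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(data_lines, dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data block is {values.shape}, header declares {(n_rows, n_cols)}"
        )
    mask = values == nodata
    values = values.copy()
    values[mask] = np.nan
    grid = GridGeometry(
        west=header["xllcorner"], south=header["yllcorner"],
        cell_size=header["cellsize"], n_rows=n_rows, n_cols=n_cols,
    )
    return values, grid, mask


def write_stack(directory, stack: ClimateStack, manifest_extra: dict | None = None) -> Path:
    """Write a climate stack as one .asc file per layer plus a YAML
    manifest recording layer kinds, grid and any provenance parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "crs": stack.crs_note,
        "grid": {
            "west": stack.grid.west, "south": stack.grid.south,
            "cell_size": stack.grid.cell_size,
            "n_rows": stack.grid.n_rows, "n_cols": stack.grid.n_cols,
        },
        "layers": {},
    }
    for name in stack.layers:
        write_ascii_grid(directory / f"{name}.asc", stack.layers[name],
                         stack.grid, nodata_mask=stack.nodata_mask)
        manifest["layers"][name] = {
            "file": f"{name}.asc", "kind": stack.layer_kinds.get(name, "other"),
        }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(directory / "stack.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory


def read_stack(directory) -> ClimateStack:
    """Read a stack written by :func:`write_stack`."""
    directory = Path(directory)
    with open(directory / "stack.yaml") as fh:
        manifest = yaml.safe_load(fh)
    layers: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    grid = None
    mask = None
    for name, meta in manifest["layers"].items():
        values, g, m = read_ascii_grid(directory / meta["file"])
        if grid is None:
            grid, mask = g, m
        elif g != grid or not np.array_equal(m, mask):
            raise ValueError(f"layer {name!r} disagrees with the stack grid/mask")
        values = values.copy()
        values[m] = 0.0  # placeholder under the shared mask
        layers[name] = values
        kinds[name] = meta.get("kind", "other")
    return ClimateStack(grid=grid, layers=layers, nodata_mask=mask,
                        layer_kinds=kinds, crs_note=manifest.get("crs", ""))


def write_occurrences(path, occurrences: OccurrenceSet) -> Path:
    path = Path(path)
    occurrences.records.to_csv(path, index=False)
    return path


def read_occurrences(path) -> OccurrenceSet:
    return OccurrenceSet(pd.read_csv(path))


def write_model(path, model: MaxEntModel) -> Path:
    path = Path(path)
    path.write_text(model.to_json())
    return path


def read_model(path) -> MaxEntModel:
    return MaxEntModel.from_json(Path(path).read_text())


def write_suitability(path, raster: SuitabilityRaster) -> Path:
    return write_ascii_grid(path, raster.values, raster.grid,
                            nodata_mask=raster.nodata_mask)


def read_suitability(path, kind: str = "logistic") -> SuitabilityRaster:
    values, grid, mask = read_ascii_grid(path)
    return SuitabilityRaster(grid=grid, values=values, nodata_mask=mask, kind=kind)


def centroid_track_geojson(track: CentroidTrack) -> dict:
    """Displacement segments as a GeoJSON FeatureCollection of lines."""
    features = []
    pts = track.points.set_index("label")
    for _, seg in track.segments.iterrows():
        a = pts.loc[seg["from"]]
        b = pts.loc[seg["to"]]
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [
                    [float(a["longitude"]), float(a["latitude"])],
                    [float(b["longitude"]), float(b["latitude"])],
                ],
            },
            "properties": {
                "from": seg["from"], "to": seg["to"],
                "distance_km": float(seg["distance_km"]),
                "bearing_deg": float(seg["bearing_deg"]),
                "east_km": float(seg["east_km"]),
                "north_km": float(seg["north_km"]),
            },
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path, document: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(document, indent=1))
    return path
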