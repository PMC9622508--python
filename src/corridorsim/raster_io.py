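"""File interchange: TIFF rasters, GeoJSON vectors, YAML config, CSV tables.

Rasters live in the pipeline's single planar metric frame (no geographic
CRS), so they are written as plain single- or multi-band TIFFs with the
grid geometry carried in the image description tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .footprint_history import Crossing
from .grid_core import Grid
from .recreation import Trail


def write_raster(path: str | Path, arrays: np.ndarray | list[np.ndarray], grid: Grid, band_names: list[str] | None = None) -> None:
    """Write one or more co-registered bands as a float32 TIFF."""
    if isinstance(arrays, np.ndarray) and arrays.ndim == 2:
        arrays = [arrays]
    stack = np.stack([np.asarray(a, dtype=np.float32) for a in arrays])
    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "band_names": band_names or [f"band_{i}" for i in range(len(stack))],
    }
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_raster(path: str | Path) -> tuple[np.ndarray, Grid, list[str]]:
    """Read a TIFF written by :func:`write_raster`; returns (bands, grid, names)."""
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    if stack.ndim == 2:
        stack = stack[None, :, :]
    grid = Grid(
        stack.shape[-2],
        stack.shape[-1],
        float(meta.get("cell_size", 100.0)),
        tuple(meta.get("origin", (0.0, 0.0))),
    )
    names = meta.get("band_names", [f"band_{i}" for i in range(stack.shape[0])])
    return stack, grid, names


def trails_to_geojson(trails: list[Trail], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": t.coords.tolist()},
            "properties": {"designated": bool(t.designated)},
        }
        for t in trails
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def trails_from_geojson(path: str | Path) -> list[Trail]:
    data = json.loads(Path(path).read_text())
    return [
        Trail(np.asarray(f["geometry"]["coordinates"]), bool(f["properties"]["designated"]))
        for f in data["features"]
    ]


def crossings_to_geojson(crossings: list[Crossing], grid: Grid, path: str | Path) -> None:
    features = []
    for c in crossings:
        x = grid.origin[0] + (c.col + 0.5) * grid.cell_size
        y = grid.origin[1] + (c.row + 0.5) * grid.cell_size
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"year_built": c.year_built},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_collar(collar: pd.DataFrame, path: str | Path) -> None:
    collar.to_csv(path, index=False)


def read_collar(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])
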