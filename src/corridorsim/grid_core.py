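"""Raster data model and spatial primitives shared by all pipeline stages.

The whole analysis lives on a single regular grid in a planar metric frame:
cell (i, j) has its centre at ``origin + ((j + 0.5) * cell_size,
(i + 0.5) * cell_size)`` with row-major storage. Land cover is represented
as per-cell cover *fractions* (a :class:`CoverStack`), so a 100 m cell can
be, say, 0.7 forest and 0.3 settlement; class areas are exact sums of
fractions times cell area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridMismatchError

#: Cover classes counted as development footprint.
ANTHROPOGENIC_CLASSES = (
    "linear",
    "recreation_facility",
    "settlement",
    "industrial",
    "farmland",
)

#: Undeveloped cover classes.
NATURAL_CLASSES = ("forest", "shrub", "alpine", "water")


@dataclass(frozen=True)
class Grid:
    """Geometry of the raster: shape, resolution and origin (metres)."""

    n_rows: int
    n_cols: int
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    @property
    def extent_km2(self) -> float:
        return self.n_rows * self.n_cols * self.cell_area_km2

    def check(self, raster: np.ndarray) -> np.ndarray:
        """Validate that ``raster`` matches this grid's shape."""
        if raster.shape[-2:] != self.shape:
            raise GridMismatchError(
                f"raster shape {raster.shape} does not match grid {self.shape}"
            )
        return raster

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre."""
        i, j = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        x = self.origin[0] + (j + 0.5) * self.cell_size
        y = self.origin[1] + (i + 0.5) * self.cell_size
        return x, y


@dataclass
class CoverStack:
    """Per-cell cover fractions for every class, summing to one per cell."""

    grid: Grid
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for arr in self.layers.values():
            self.grid.check(arr)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def fraction(self, name: str) -> np.ndarray:
        """Fraction raster for ``name``; zeros if the class is absent."""
        if name in self.layers:
            return self.layers[name]
        return np.zeros(self.grid.shape)

    def anthropogenic_fraction(self) -> np.ndarray:
        """Total development-footprint fraction per cell."""
        out = np.zeros(self.grid.shape)
        for cls in ANTHROPOGENIC_CLASSES:
            out += self.fraction(cls)
        return out

    def validate(self, atol: float = 1e-9) -> None:
        total = np.zeros(self.grid.shape)
        for name, arr in self.layers.items():
            if arr.min() < -atol or arr.max() > 1 + atol:
                raise ValueError(f"fractions of class {name!r} outside [0, 1]")
            total += arr
        if not np.allclose(total, 1.0, atol=max(atol, 1e-9)):
            worst = float(np.abs(total - 1.0).max())
            raise ValueError(f"cover fractions do not sum to 1 (max error {worst:g})")

    def copy(self) -> "CoverStack":
        return CoverStack(self.grid, {k: v.copy() for k, v in self.layers.items()})


@dataclass
class AreaReport:
    """Per-class areas in km² plus the anthropogenic total."""

    per_class: dict[str, float]
    total_footprint: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": k, "km2": v} for k, v in self.per_class.items()]
        rows.append({"class": "total_footprint", "km2": self.total_footprint})
        return pd.DataFrame(rows)


def distance_to(mask: np.ndarray, grid: Grid) -> np.ndarray:
    """Euclidean distance (m) from each cell centre to the nearest True cell.

    Returns 0 on True cells and ``inf`` everywhere if the mask is empty.
    """
    grid.check(mask)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(grid.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=grid.cell_size)


def circular_offsets(radius: float, cell_size: float) -> np.ndarray:
    """Boolean footprint of cells whose centre lies within ``radius`` of the focal centre."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius / cell_size + 1e-9))
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.hypot(di, dj) * cell_size) <= radius + 1e-9


def focal_mean(values: np.ndarray, radius: float, grid: Grid) -> np.ndarray:
    """Circular moving-window mean; edge windows shrink to in-bounds cells."""
    grid.check(values)
    if radius < 0:
        raise ValueError("radius must be non-negative")
    footprint = circular_offsets(radius, grid.cell_size)
    if footprint.size == 1:
        return values.astype(float).copy()
    kernel = footprint.astype(float)
    total = ndimage.convolve(values.astype(float), kernel, mode="constant", cval=0.0)
    count = ndimage.convolve(np.ones(grid.shape), kernel, mode="constant", cval=0.0)
    return total / count


def area_report(stack: CoverStack) -> AreaReport:
    """Per-class km² and the anthropogenic (footprint) total."""
    cell_km2 = stack.grid.cell_area_km2
    per_class = {name: float(arr.sum()) * cell_km2 for name, arr in stack.layers.items()}
    total = float(sum(per_class.get(cls, 0.0) for cls in ANTHROPOGENIC_CLASSES))
    return AreaReport(per_class=per_class, total_footprint=total)


def percent_change(base: float, new: float) -> float:
    """Percent change of ``new`` relative to ``base`` (e.g. 0.41 -> 0.55 is +34.1)."""
    if base == 0:
        return float("nan") if new == 0 else float("inf")
    return 100.0 * (new - base) / base
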