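"""Human-bear conflict risk: index, classification and extent accounting.

Risk is the product of 400 m moving-window averages of the 0-5
connectivity index and the 0-5 recreation activity level, so it ranges
over [0, 25]. Cut points at 1, 4 and 9 mark where, on average, both
inputs exceed very low (1), low (2) and moderate (3) values; exactly-zero
products get their own "none" category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import ConnectivityIndex
from .errors import DataRangeError, GridMismatchError
from .grid_core import Grid, focal_mean
from .recreation import ActivityRaster

CATEGORIES = ("none", "very_low", "low", "moderate", "high")
CATEGORY_CODES = {name: i for i, name in enumerate(CATEGORIES)}
#: Upper cut points of very_low, low and moderate.
CUT_POINTS = (1.0, 4.0, 9.0)

DEFAULT_WINDOW_RADIUS_M = 400.0


class RiskRaster:
    """Continuous conflict-risk index in [0, 25] with its 5-way classification."""

    def __init__(self, grid: Grid, index: np.ndarray):
        grid.check(index)
        self.grid = grid
        self.index = index
        self.category = classify(self)

    def category_mask(self, *names: str) -> np.ndarray:
        codes = [CATEGORY_CODES[n] for n in names]
        return np.isin(self.category, codes)


def risk_index(
    conn: ConnectivityIndex,
    act: ActivityRaster,
    window_radius: float = DEFAULT_WINDOW_RADIUS_M,
) -> RiskRaster:
    """Product of moving-window-averaged connectivity and activity levels."""
    if conn.grid.shape != act.grid.shape:
        raise GridMismatchError("connectivity and activity rasters are not co-registered")
    grid = conn.grid
    conn_avg = focal_mean(conn.level.astype(float), window_radius, grid)
    act_avg = focal_mean(act.level.astype(float), window_radius, grid)
    return RiskRaster(grid, conn_avg * act_avg)


def classify(risk: RiskRaster) -> np.ndarray:
    """Integer category codes: 0 none, 1 (0,1], 2 (1,4], 3 (4,9], 4 (9,25]."""
    idx = risk.index
    if not np.isfinite(idx).all():
        raise DataRangeError("risk index must be finite")
    if idx.min() < 0 or idx.max() > 25:
        raise DataRangeError("risk index outside [0, 25]")
    cat = np.digitize(idx, CUT_POINTS, right=True) + 1  # (0,1]->1 ... (9,..]->4
    return np.where(idx == 0, 0, cat).astype(np.int8)


def extent_summary(risks: dict[tuple[int, str], RiskRaster]) -> pd.DataFrame:
    """Tidy per-category areas with percent change of moderate+high vs Base Case.

    ``risks`` maps (year, scenario) to a risk raster on a common grid.
    Percent-change columns appear only when a non-base scenario shares a
    year with the base scenario.
    """
    rows = []
    base_mh: dict[int, float] = {}
    for (year, scenario), risk in risks.items():
        cell_km2 = risk.grid.cell_area_km2
        areas = {
            name: float((risk.category == code).sum()) * cell_km2
            for name, code in CATEGORY_CODES.items()
        }
        mh = areas["moderate"] + areas["high"]
        if scenario == "base":
            base_mh[year] = mh
        for name in CATEGORIES:
            rows.append(
                {"year": year, "scenario": scenario, "category": name, "km2": areas[name]}
            )
    df = pd.DataFrame(rows)
    if any(s != "base" for _, s in risks.keys()) and base_mh:
        changes = []
        for (year, scenario), risk in risks.items():
            if scenario == "base" or year not in base_mh:
                continue
            cell_km2 = risk.grid.cell_area_km2
            mh = float(risk.category_mask("moderate", "high").sum()) * cell_km2
            base = base_mh[year]
            pct = 0.0 if base == 0 and mh == 0 else 100.0 * (mh - base) / base if base else float("inf")
            changes.append(
                {"year": year, "scenario": scenario, "moderate_high_km2": mh, "pct_change_vs_base": pct}
            )
        if changes:
            df = df.merge(pd.DataFrame(changes), on=["year", "scenario"], how="left")
    return df
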