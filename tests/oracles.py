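"""Independent brute-force oracles used to pin down expected values.

These deliberately avoid the library's own computational paths: distances
come from pairwise enumeration, focal means from explicit window
enumeration, and least-cost paths from exhaustive simple-path search with
branch-and-bound pruning.
"""

from __future__ import annotations

import numpy as np

EDGE_EPS = 1e-9

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_distance(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Min Euclidean centre-to-centre distance to any True cell, by enumeration."""
    out = np.full(mask.shape, np.inf)
    true_cells = np.argwhere(mask)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            for ti, tj in true_cells:
                d = cell_size * np.hypot(i - ti, j - tj)
                out[i, j] = min(out[i, j], d)
    return out


def brute_focal_mean(values: np.ndarray, radius: float, cell_size: float) -> np.ndarray:
    """Circular-window mean by explicit enumeration with edge shrinkage."""
    n_rows, n_cols = values.shape
    out = np.zeros_like(values, dtype=float)
    for i in range(n_rows):
        for j in range(n_cols):
            acc, cnt = 0.0, 0
            for ii in range(n_rows):
                for jj in range(n_cols):
                    if cell_size * np.hypot(i - ii, j - jj) <= radius + 1e-9:
                        acc += values[ii, jj]
                        cnt += 1
            out[i, j] = acc / cnt
    return out


def exhaustive_min_path_cost(
    cost: np.ndarray,
    passable: np.ndarray,
    start: tuple[int, int],
    end: tuple[int, int],
    cell_size: float,
) -> float:
    """Minimum accumulated cost over all simple 8-connected paths.

    Edge cost is step length times the mean of the two endpoint cell costs
    plus a small floor, matching the accumulated-cost-surface convention.
    Branch-and-bound pruning keeps exhaustive search tractable on toy grids.
    """
    n_rows, n_cols = cost.shape
    best = [np.inf]
    visited = np.zeros_like(passable, dtype=bool)

    def dfs(r: int, c: int, acc: float) -> None:
        if acc >= best[0]:
            return
        if (r, c) == end:
            best[0] = acc
            return
        visited[r, c] = True
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and passable[rr, cc] and not visited[rr, cc]:
                step = cell_size * np.hypot(dr, dc)
                w = step * 0.5 * (cost[r, c] + cost[rr, cc]) + EDGE_EPS
                dfs(rr, cc, acc + w)
        visited[r, c] = False

    if passable[start] and passable[end]:
        dfs(start[0], start[1], 0.0)
    return best[0]
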