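"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library routines the implementation relies on
(scipy labeling, skimage thresholds): components are found by explicit
breadth-first search over foreground voxels, quantiles by sorting, and
distances by direct enumeration, so agreement with the pipeline is a real
cross-check rather than the same code called twice.
"""

from __future__ import annotations

from collections import deque

import numpy as np

#: Offsets of the 26-neighborhood.
NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def bfs_components(fg: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """26-connected components of a boolean grid via breadth-first search,
    in raster-scan order of their first voxel."""
    fg = np.asarray(fg, dtype=bool)
    shape = fg.shape
    seen = np.zeros(shape, dtype=bool)
    components = []
    for z, y, x in zip(*np.nonzero(fg)):
        if seen[z, y, x]:
            continue
        comp = set()
        queue = deque([(int(z), int(y), int(x))])
        seen[z, y, x] = True
        while queue:
            cz, cy, cx = queue.popleft()
            comp.add((cz, cy, cx))
            for dz, dy, dx in NEIGHBORS_26:
                nz, ny, nx = cz + dz, cy + dy, cx + dx
                if (
                    0 <= nz < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nx < shape[2]
                    and fg[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
        components.append(comp)
    return components


def bfs_component_sizes(fg: np.ndarray, min_voxels: int = 1) -> list[int]:
    """Voxel counts of 26-connected components, raster order, size-filtered."""
    return [len(c) for c in bfs_components(fg) if len(c) >= min_voxels]


def quantile_by_sorting(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile computed from an explicit sort."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def min_distance_to_set(
    point_vox: tuple[int, int, int],
    targets: np.ndarray,
    spacing: tuple[float, float, float],
) -> float:
    """Minimum anisotropic Euclidean distance from a voxel to a voxel set."""
    idx = np.argwhere(targets)
    deltas = (idx - np.asarray(point_vox)) * np.asarray(spacing)
    return float(np.sqrt((deltas**2).sum(axis=1)).min())


def ols_slope_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """OLS slope and (1−alpha) CI via the closed-form t interval."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    resid = y - (ym + slope * (x - xm))
    if n <= 2 or np.allclose(resid, 0):
        return slope, (slope, slope)
    se = np.sqrt((resid**2).sum() / (n - 2) / sxx)
    t = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return slope, (slope - t * se, slope + t * se)
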