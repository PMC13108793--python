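"""Shared fixtures and independent brute-force oracles for the geometry checks.

The oracles never touch the package's cell construction: assignment is an
exhaustive nearest-center scan over a probe raster, and adjacency is
4-connected pixel adjacency of the rasterized assignment.
"""

import numpy as np
import pytest

from voronoiclassmap.geometry import PointSet2D, Window, compute_window


def raster_assign(coords: np.ndarray, window: Window, res: int = 200) -> np.ndarray:
    """Assign each probe-raster point to its nearest center (exhaustive scan)."""
    xs = np.linspace(window.xmin, window.xmax, res)
    ys = np.linspace(window.ymin, window.ymax, res)
    gx, gy = np.meshgrid(xs, ys)
    probes = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((probes[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).reshape(res, res)


def raster_adjacency(owner_grid: np.ndarray) -> set:
    """Cell pairs that touch across a 4-connected pixel boundary."""
    pairs = set()
    h = np.stack([owner_grid[:, :-1].ravel(), owner_grid[:, 1:].ravel()], axis=1)
    v = np.stack([owner_grid[:-1, :].ravel(), owner_grid[1:, :].ravel()], axis=1)
    for a, b in np.vstack([h, v]):
        if a != b:
            pairs.add((min(int(a), int(b)), max(int(a), int(b))))
    return pairs


def nearest_center_scan(coords: np.ndarray, query: np.ndarray) -> int:
    """Exhaustive nearest-center search (lowest index on ties)."""
    best, best_d = 0, np.inf
    for i, c in enumerate(coords):
        d = float(np.hypot(*(query - c)))
        if d < best_d - 1e-15:
            best, best_d = i, d
    return best


@pytest.fixture
def grid3x3():
    """3x3 unit grid of points."""
    xs, ys = np.meshgrid([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
    return PointSet2D(np.column_stack([xs.ravel(), ys.ravel()]))


@pytest.fixture
def square_corners():
    """Four cocircular points on the unit square."""
    return PointSet2D([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def collinear3():
    """Three equally spaced collinear points."""
    return PointSet2D([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])


@pytest.fixture
def default_window():
    def make(points, margin=0.05):
        return compute_window(points, margin)

    return make
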