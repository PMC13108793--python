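"""Bounded Voronoi tessellation of 2-D point sets and its Delaunay-dual neighbor graph.

The plotting panel is a finite rectangular window; every Voronoi cell is the
intersection of the window with the half-planes defined by the perpendicular
bisectors between its generating point and the point's Delaunay neighbors.
Two points are *neighbors* when their clipped cells share a boundary segment
of positive length — zero-length contacts (e.g. the diagonal of a cocircular
square) do not count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "PointSet2D",
    "Window",
    "Tessellation",
    "NeighborGraph",
    "compute_window",
    "tessellate",
    "neighbor_graph",
    "locate",
]

# Relative tolerance below which two generating points count as identical.
_DUPLICATE_RTOL = 1e-9
# Shared boundary shorter than this fraction of the window diagonal is not adjacency.
_MIN_EDGE_FRAC = 1e-9
# Tolerance (fraction of window diagonal) for deciding a cell vertex lies on a bisector.
_ON_LINE_FRAC = 1e-7
# Below this size the candidate neighbor pairs are all pairs, which is exact even
# for degenerate (collinear / cocircular) configurations.
_SMALL_N_ALL_PAIRS = 16


class PointSet2D:
    """A set of n labelled points on the plane.

    Parameters
    ----------
    coords : array-like, shape (n, 2)
        Finite coordinates in projection/plot units.
    case_ids : sequence, optional
        Opaque per-point identifiers; defaults to 1-based row numbers.
    """

    def __init__(self, coords, case_ids=None):
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be an (n, 2) array, got shape {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("point set must contain at least one point")
        if not np.all(np.isfinite(coords)):
            bad = np.flatnonzero(~np.isfinite(coords).all(axis=1)) + 1
            raise ValueError(f"non-finite coordinates in rows {bad.tolist()}")
        n = coords.shape[0]
        if case_ids is None:
            case_ids = list(range(1, n + 1))
        else:
            case_ids = list(case_ids)
            if len(case_ids) != n:
                raise ValueError("case_ids length must match number of points")
        self.coords = coords
        self.case_ids = case_ids
        self._check_duplicates()

    def _check_duplicates(self):
        c = self.coords
        lo, hi = c.min(axis=0), c.max(axis=0)
        diag = float(np.hypot(*(hi - lo)))
        tol = _DUPLICATE_RTOL * max(1.0, diag)
        # O(n^2) pairwise check; point sets here are plot-sized.
        d = np.hypot(c[:, 0, None] - c[None, :, 0], c[:, 1, None] - c[None, :, 1])
        iu = np.triu_indices(len(c), k=1)
        dup = d[iu] <= tol
        if dup.any():
            pairs = [
                (self.case_ids[int(i)], self.case_ids[int(j)])
                for i, j in zip(iu[0][dup], iu[1][dup])
            ]
            raise ValueError(f"duplicate points (cell ownership undefined): {pairs}")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class Window:
    """Rectangular tessellation/plot domain."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("window must satisfy xmin < xmax and ymin < ymax")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    def contains(self, xy, atol: float = 0.0) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (
            (xy[:, 0] >= self.xmin - atol)
            & (xy[:, 0] <= self.xmax + atol)
            & (xy[:, 1] >= self.ymin - atol)
            & (xy[:, 1] <= self.ymax + atol)
        )

    def corners(self) -> np.ndarray:
        """Counter-clockwise corner ring."""
        return np.array(
            [
                [self.xmin, self.ymin],
                [self.xmax, self.ymin],
                [self.xmax, self.ymax],
                [self.xmin, self.ymax],
            ]
        )


def compute_window(points: PointSet2D, margin_frac: float = 0.05) -> Window:
    """Bounding box of the points expanded by ``margin_frac`` of each axis range per side.

    A degenerate zero-range axis is expanded by 1.0 absolute per side so the
    window always has positive area.
    """
    if margin_frac < 0:
        raise ValueError("margin_frac must be >= 0")
    c = points.coords
    lo, hi = c.min(axis=0), c.max(axis=0)
    rng = hi - lo
    pad = np.where(rng > 0, margin_frac * rng, 1.0)
    return Window(lo[0] - pad[0], hi[0] + pad[0], lo[1] - pad[1], hi[1] + pad[1])


def _polygon_area(poly: np.ndarray) -> float:
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _clip_halfplane(poly: np.ndarray, m: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Sutherland–Hodgman clip of a convex CCW polygon to {x : (x - m)·d <= 0}."""
    k = len(poly)
    if k == 0:
        return poly
    f = (poly - m) @ d
    out = []
    for i in range(k):
        j = (i + 1) % k
        fi, fj = f[i], f[j]
        if fi <= 0:
            out.append(poly[i])
        if (fi < 0 < fj) or (fj < 0 < fi):
            t = fi / (fi - fj)
            out.append(poly[i] + t * (poly[j] - poly[i]))
    return np.asarray(out) if out else np.empty((0, 2))


def _candidate_pairs(coords: np.ndarray) -> list[tuple[int, int]]:
    """Candidate Voronoi-neighbor pairs: Delaunay edges, or all pairs for small or
    degenerate inputs (where qhull's triangulation is unavailable or ambiguous)."""
    n = len(coords)
    if n <= _SMALL_N_ALL_PAIRS:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    try:
        tri = Delaunay(coords)
    except QhullError:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


@dataclass
class Tessellation:
    """Clipped Voronoi cells, one convex CCW polygon per point, over a window."""

    points: PointSet2D
    window: Window
    cells: list = field(repr=False)

    @property
    def n(self) -> int:
        return self.points.n

    @property
    def owners(self) -> list:
        """Map polygon index -> point index (identity by construction)."""
        return list(range(self.n))

    def areas(self) -> np.ndarray:
        return np.array([_polygon_area(c) for c in self.cells])


def tessellate(points: PointSet2D, window: Window | None = None) -> Tessellation:
    """Voronoi tessellation of ``points`` clipped to ``window``.

    Each cell is built by clipping the window rectangle against the
    perpendicular-bisector half-planes toward the point's (candidate
    Delaunay) neighbors; clipping against the full Delaunay neighbor set
    reproduces the exact Euclidean Voronoi cell.
    """
    if window is None:
        window = compute_window(points)
    coords = points.coords
    inside = window.contains(coords, atol=1e-12 * max(1.0, window.diagonal))
    if not inside.all():
        bad = [points.case_ids[i] for i in np.flatnonzero(~inside)]
        raise ValueError(f"points outside the window: {bad}")

    n = points.n
    nbr: list[set[int]] = [set() for _ in range(n)]
    for i, j in _candidate_pairs(coords):
        nbr[i].add(j)
        nbr[j].add(i)

    rect = window.corners()
    cells = []
    for i in range(n):
        poly = rect
        pi = coords[i]
        for j in sorted(nbr[i]):
            pj = coords[j]
            poly = _clip_halfplane(poly, (pi + pj) / 2.0, pj - pi)
            if len(poly) == 0:
                break
        cells.append(poly)
    return Tessellation(points=points, window=window, cells=cells)


def _shared_boundary_length(
    cell_i: np.ndarray, cell_j: np.ndarray, pi: np.ndarray, pj: np.ndarray, tol: float
) -> float:
    """Length of the segment the two cells share on the (i, j) bisector line."""
    d = pj - pi
    nd = float(np.hypot(*d))
    if nd == 0.0:
        return 0.0
    nhat = d / nd
    that = np.array([-nhat[1], nhat[0]])
    m = (pi + pj) / 2.0

    def interval(cell):
        if len(cell) == 0:
            return None
        off = (cell - m) @ nhat
        on = np.abs(off) <= tol
        if np.count_nonzero(on) < 2:
            return None
        s = (cell[on] - m) @ that
        return float(s.min()), float(s.max())

    a = interval(cell_i)
    if a is None:
        return 0.0
    b = interval(cell_j)
    if b is None:
        return 0.0
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class NeighborGraph:
    """Symmetric adjacency between points whose cells share a positive-length edge."""

    n: int
    edges: set  # of (i, j) tuples with i < j

    def __post_init__(self):
        self._adj: list[set[int]] = [set() for _ in range(self.n)]
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            self._adj[i].add(j)
            self._adj[j].add(i)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._adj[i])

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges


def neighbor_graph(points: PointSet2D, tess: Tessellation) -> NeighborGraph:
    """Delaunay-dual adjacency restricted to cell pairs whose clipped cells share
    a boundary segment longer than 1e-9 × the window diagonal."""
    coords = points.coords
    diag = tess.window.diagonal
    on_line_tol = _ON_LINE_FRAC * diag
    min_len = _MIN_EDGE_FRAC * diag
    edges = set()
    for i, j in _candidate_pairs(coords):
        length = _shared_boundary_length(
            tess.cells[i], tess.cells[j], coords[i], coords[j], on_line_tol
        )
        if length > min_len:
            edges.add((i, j))
    graph = NeighborGraph(n=points.n, edges=edges)
    if points.n >= 2 and any(graph.degree(i) == 0 for i in range(points.n)):
        isolated = [points.case_ids[i] for i in range(points.n) if graph.degree(i) == 0]
        warnings.warn(f"points with no Voronoi neighbor inside the window: {isolated}")
    return graph


def locate(tess: Tessellation, x) -> int:
    """Index of the center whose cell contains ``x`` (nearest center, Euclidean).

    Ties on the bisector are broken toward the lowest index.
    """
    x = np.asarray(x, dtype=float).reshape(2)
    if not tess.window.contains(x)[0]:
        raise ValueError(f"query point {x.tolist()} lies outside the window")
    d2 = ((tess.points.coords - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))
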