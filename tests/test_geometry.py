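"""Bounded Voronoi tessellation, duality and the locate rule."""

import numpy as np
import pytest
from conftest import nearest_center_scan, raster_adjacency, raster_assign
from hypothesis import given, settings
from hypothesis import strategies as st

from voronoiclassmap.geometry import (
    PointSet2D,
    Window,
    compute_window,
    locate,
    neighbor_graph,
    tessellate,
)


class TestPointSet:
    def test_rejects_duplicates_naming_case_ids(self):
        with pytest.raises(ValueError, match=r"duplicate points.*\('a', 'c'\)"):
            PointSet2D([[0, 0], [1, 1], [0, 0]], case_ids=["a", "b", "c"])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            PointSet2D([[0, 0], [np.nan, 1]])

    def test_default_case_ids_are_row_numbers(self):
        assert PointSet2D([[0, 0], [1, 1]]).case_ids == [1, 2]


class TestComputeWindow:
    @pytest.mark.parametrize(
        "pts, margin, expect",
        [
            ([[0, 0], [10, 10]], 0.05, (-0.5, 10.5, -0.5, 10.5)),
            ([[3, 4]], 0.05, (2, 4, 3, 5)),  # degenerate both axes -> 1.0 absolute
            ([[0, 0], [4, 0]], 0.0, (0, 4, -1, 1)),  # zero-range y expanded
        ],
    )
    def test_bounds(self, pts, margin, expect):
        w = compute_window(PointSet2D(pts), margin)
        assert (w.xmin, w.xmax, w.ymin, w.ymax) == pytest.approx(expect)

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            compute_window(PointSet2D([[0, 0], [1, 1]]), -0.1)


class TestTessellate:
    def test_two_points_split_at_bisector(self):
        ps = PointSet2D([[0.0, 0.0], [2.0, 0.0]])
        w = Window(-1, 3, -1, 1)
        tess = tessellate(ps, w)
        # bisector x = 1 splits the 4x2 window into two equal halves
        assert tess.areas() == pytest.approx([4.0, 4.0])
        assert tess.cells[0][:, 0].max() == pytest.approx(1.0)
        assert tess.cells[1][:, 0].min() == pytest.approx(1.0)

    def test_single_point_owns_window(self):
        ps = PointSet2D([[0.5, 0.5]])
        w = Window(0, 1, 0, 2)
        tess = tessellate(ps, w)
        assert len(tess.cells) == 1
        assert tess.areas()[0] == pytest.approx(w.area)

    def test_grid_center_cell_is_unit_square(self, grid3x3):
        w = Window(-0.5, 2.5, -0.5, 2.5)
        tess = tessellate(grid3x3, w)
        center = int(np.argmin(((grid3x3.coords - [1, 1]) ** 2).sum(axis=1)))
        cell = tess.cells[center]
        assert sorted(map(tuple, np.round(cell, 9))) == [
            (0.5, 0.5),
            (0.5, 1.5),
            (1.5, 0.5),
            (1.5, 1.5),
        ]
        # oracle: raster assignment puts each cell's probes with its owner
        owners = raster_assign(grid3x3.coords, w, res=200)
        vals, counts = np.unique(owners, return_counts=True)
        assert len(vals) == 9

    def test_partition_sums_to_window_area(self):
        rng = np.random.default_rng(7)
        ps = PointSet2D(rng.uniform(0, 10, size=(60, 2)))
        tess = tessellate(ps)
        assert tess.areas().sum() == pytest.approx(tess.window.area, rel=1e-6)

    def test_cells_contain_their_points(self):
        rng = np.random.default_rng(11)
        ps = PointSet2D(rng.normal(size=(40, 2)))
        tess = tessellate(ps)
        for i, cell in enumerate(tess.cells):
            assert locate(tess, cell.mean(axis=0)) == i  # centroid of a convex cell

    def test_point_outside_window_rejected(self):
        ps = PointSet2D([[0, 0], [5, 5]])
        with pytest.raises(ValueError, match="outside the window"):
            tessellate(ps, Window(0, 1, 0, 1))


class TestNeighborGraph:
    def test_two_points_single_edge(self):
        ps = PointSet2D([[0, 0], [2, 0]])
        tess = tessellate(ps)
        g = neighbor_graph(ps, tess)
        assert g.edges == {(0, 1)}

    def test_square_corners_no_diagonal_adjacency(self, square_corners):
        tess = tessellate(square_corners)
        g = neighbor_graph(square_corners, tess)
        assert g.edges == {(0, 1), (1, 2), (2, 3), (0, 3)}
        # oracle: 4-connected raster adjacency agrees
        oracle = raster_adjacency(raster_assign(square_corners.coords, tess.window, 200))
        assert g.edges == oracle

    def test_collinear_points_chain_only(self, collinear3):
        tess = tessellate(collinear3)
        g = neighbor_graph(collinear3, tess)
        assert g.edges == {(0, 1), (1, 2)}
        oracle = raster_adjacency(raster_assign(collinear3.coords, tess.window, 200))
        assert g.edges == oracle

    def test_grid_adjacency_matches_raster_oracle(self, grid3x3):
        tess = tessellate(grid3x3, Window(-0.5, 2.5, -0.5, 2.5))
        g = neighbor_graph(grid3x3, tess)
        oracle = raster_adjacency(raster_assign(grid3x3.coords, tess.window, 300))
        assert g.edges == oracle
        assert len(g.edges) == 12  # rook adjacency of a 3x3 grid

    def test_every_point_has_a_neighbor(self):
        rng = np.random.default_rng(3)
        ps = PointSet2D(rng.uniform(size=(30, 2)))
        tess = tessellate(ps)
        g = neighbor_graph(ps, tess)
        assert all(g.degree(i) >= 1 for i in range(ps.n))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        quarter_turns=st.integers(0, 3),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
    )
    def test_rigid_motion_equivariance(self, seed, quarter_turns, dx, dy):
        """Window-preserving rigid motions (translations, quarter turns) leave
        the neighbor relation unchanged. Generic rotations change the
        axis-aligned window, so adjacency of hull cells may legitimately
        differ there."""
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(25, 2))
        angle = quarter_turns * np.pi / 2
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = coords @ R.T + [dx, dy]
        g1 = neighbor_graph(PointSet2D(coords), tessellate(PointSet2D(coords)))
        g2 = neighbor_graph(PointSet2D(moved), tessellate(PointSet2D(moved)))
        assert g1.edges == g2.edges

    def test_generic_rotation_preserves_interior_adjacency(self):
        """Under an arbitrary rotation only hull-cell adjacency may change
        (the clipping window follows the data bounding box); edges between
        interior points are preserved."""
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(40, 2))
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = coords @ R.T
        g1 = neighbor_graph(PointSet2D(coords), tessellate(PointSet2D(coords)))
        g2 = neighbor_graph(PointSet2D(moved), tessellate(PointSet2D(moved)))
        from scipy.spatial import ConvexHull

        hull = set(ConvexHull(coords).vertices.tolist()) | set(
            ConvexHull(moved).vertices.tolist()
        )
        interior1 = {e for e in g1.edges if e[0] not in hull and e[1] not in hull}
        interior2 = {e for e in g2.edges if e[0] not in hull and e[1] not in hull}
        assert interior1 == interior2

    def test_permutation_invariance_on_case_ids(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(20, 2))
        ids = [f"c{i}" for i in range(20)]
        perm = rng.permutation(20)
        g1 = neighbor_graph(
            PointSet2D(coords, ids), tessellate(PointSet2D(coords, ids))
        )
        ps2 = PointSet2D(coords[perm], [ids[i] for i in perm])
        g2 = neighbor_graph(ps2, tessellate(ps2))
        by_ids_1 = {frozenset((ids[i], ids[j])) for i, j in g1.edges}
        by_ids_2 = {frozenset((ps2.case_ids[i], ps2.case_ids[j])) for i, j in g2.edges}
        assert by_ids_1 == by_ids_2


class TestLocate:
    def test_nearer_center_and_tie_break(self):
        ps = PointSet2D([[0, 0], [2, 0]])
        tess = tessellate(ps, Window(-1, 3, -1, 1))
        assert locate(tess, (0.4, 0.1)) == 0
        assert locate(tess, (1.0, 0.0)) == 0  # bisector tie -> lowest index

    def test_outside_window_rejected(self):
        ps = PointSet2D([[0, 0], [2, 0]])
        tess = tessellate(ps, Window(-1, 3, -1, 1))
        with pytest.raises(ValueError, match="outside"):
            locate(tess, (10.0, 0.0))

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        coords = rng.uniform(0, 100, size=(50, 2))
        ps = PointSet2D(coords)
        tess = tessellate(ps)
        w = tess.window
        queries = rng.uniform([w.xmin, w.ymin], [w.xmax, w.ymax], size=(1000, 2))
        for q in queries:
            assert locate(tess, q) == nearest_center_scan(coords, q)
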