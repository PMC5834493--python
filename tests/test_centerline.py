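"""Centerline stages: thinning, tracing, cutting, smoothing, parameterizing."""

import numpy as np
import pytest

from canalmorph import centerline as cl
from canalmorph._thinning import skeletonize_distance_ordered
from canalmorph.volume_io import LabelVolume


def _cylinder_volume(radius_vox=6, length_vox=60, pad=10):
    n = 2 * (radius_vox + pad) + 1
    x, y, z = np.meshgrid(np.arange(length_vox + 2 * pad), np.arange(n),
                          np.arange(n), indexing="ij")
    c = (n - 1) / 2
    m = (((y - c) ** 2 + (z - c) ** 2) <= radius_vox ** 2) \
        & (x >= pad) & (x < pad + length_vox)
    return LabelVolume(m.astype(np.uint8), 1.0)


class TestSkeletonize:
    def test_cylinder_skeleton_hugs_axis(self):
        v = _cylinder_volume()
        vox = cl.skeletonize(v, "bony")
        c = (v.grid.shape[1] - 1) / 2
        # away from the flat end caps (within one radius) the skeleton
        # tracks the axis; cap erosion tails are trimmed by the cut loci
        interior = (vox[:, 0] >= 16) & (vox[:, 0] < 64)
        dev = np.hypot(vox[interior, 1] - c, vox[interior, 2] - c)
        assert dev.max() <= 1.0
        assert interior.sum() >= 40

    def test_single_voxel(self):
        g = np.zeros((5, 5, 5), dtype=np.uint8)
        g[2, 2, 2] = 1
        vox = cl.skeletonize(LabelVolume(g, 1.0), "bony")
        assert np.array_equal(vox, [[2, 2, 2]])

    def test_torus_skeleton_is_single_cycle(self):
        x, y, z = np.meshgrid(np.arange(50), np.arange(50), np.arange(21),
                              indexing="ij")
        rho = np.hypot(x - 25, y - 25)
        m = np.hypot(rho - 15, z - 10) <= 4
        skel = skeletonize_distance_ordered(m)
        g = cl._skeleton_graph(np.argwhere(skel))
        import networkx as nx
        ncomp = nx.number_connected_components(g)
        cycles = g.number_of_edges() - g.number_of_nodes() + ncomp
        assert ncomp == 1 and cycles == 1

    def test_skeleton_subset_of_foreground(self):
        v = _cylinder_volume()
        vox = cl.skeletonize(v, "bony")
        assert (v.grid[tuple(vox.T)] > 0).all()

    def test_multi_component_rejected(self):
        g = np.zeros((10, 5, 5), dtype=np.uint8)
        g[1:3, 1:3, 1:3] = 1
        g[7:9, 1:3, 1:3] = 1
        with pytest.raises(ValueError, match="2 26-connected components"):
            cl.skeletonize(LabelVolume(g, 1.0), "bony")

    def test_empty_rejected(self):
        g = np.zeros((5, 5, 5), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty"):
            cl.skeletonize(LabelVolume(g, 1.0), "bony")


class TestTraceAndPrune:
    def test_path_graph_preserved_in_order(self):
        vox = np.array([[i, 0, 0] for i in range(50)])
        poly = cl.trace_and_prune(vox, 1.0)
        assert len(poly) == 50
        d = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        assert (d == 1.0).all()

    def test_short_spur_removed(self):
        main = [[i, 0, 0] for i in range(40)]
        spur = [[20, j, 0] for j in range(1, 4)]
        poly = cl.trace_and_prune(np.array(main + spur), 1.0)
        assert len(poly) == 40
        assert (poly[:, 1] == 0).all()

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cl.trace_and_prune(np.empty((0, 3), dtype=int), 1.0)


class TestCutAtLoci:
    line = np.column_stack([np.zeros(11), np.zeros(11), np.arange(11.0)])

    def test_cut_endpoints_exactly_on_planes(self):
        planes = [(np.array([0, 0, 2.0]), np.array([0, 0, 1.0])),
                  (np.array([0, 0, 8.0]), np.array([0, 0, 1.0]))]
        cut = cl.cut_at_loci(self.line, planes)
        assert cut[0, 2] == pytest.approx(2.0)
        assert cut[-1, 2] == pytest.approx(8.0)
        assert cl.cumulative_arc_length(cut)[-1] == pytest.approx(6.0)

    def test_cut_outside_extent_rejected(self):
        planes = [(np.array([0, 0, -5.0]), np.array([0, 0, 1.0])),
                  (np.array([0, 0, 8.0]), np.array([0, 0, 1.0]))]
        with pytest.raises(ValueError, match="misses the first cut plane"):
            cl.cut_at_loci(self.line, planes)

    def test_fractional_interpolation(self):
        planes = [(np.array([0, 0, 2.5]), np.array([0, 0, 1.0])),
                  (np.array([0, 0, 7.25]), np.array([0, 0, 1.0]))]
        cut = cl.cut_at_loci(self.line, planes)
        assert cut[0, 2] == pytest.approx(2.5)
        assert cut[-1, 2] == pytest.approx(7.25)


class TestSmooth:
    def test_collinear_points_are_fixed_point(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        out = cl.smooth(pts, cl.SmoothingParams(0.8, 0.05, 100))
        np.testing.assert_allclose(out, pts, atol=1e-12)

    def test_identity_parameters(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((20, 3))
        out = cl.smooth(pts, cl.SmoothingParams(smoothing=0.0, adherence=1.0,
                                                iterations=50))
        np.testing.assert_allclose(out, pts)

    def test_zigzag_curvature_decreases_and_displacement_bounded(self):
        n = 60
        pts = np.column_stack([np.arange(n, dtype=float),
                               0.5 * (-1.0) ** np.arange(n), np.zeros(n)])
        out = cl.smooth(pts, cl.SmoothingParams(0.8, 0.05, 100))

        def curvature(p):
            return np.linalg.norm(np.diff(p, 2, axis=0), axis=1).sum()

        assert curvature(out) < curvature(pts)
        assert np.linalg.norm(out - pts, axis=1).max() <= 1.0  # amplitude
        np.testing.assert_allclose(out[[0, -1]], pts[[0, -1]])  # ends fixed

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cl.SmoothingParams(smoothing=1.5)
        with pytest.raises(ValueError):
            cl.SmoothingParams(iterations=-1)


class TestParameterize:
    def test_three_four_five_lengths(self):
        pts = np.array([[0, 0, 0], [3, 4, 0], [3, 4, 5.0]])
        line = cl.parameterize(pts, ampulla_end="end", n_points=11)
        assert line.length_mm == pytest.approx(10.0)
        # the original middle point sits at 50% of arc length
        k = np.argmin(np.linalg.norm(line.points - [3, 4, 0], axis=1))
        assert line.percent[k] == pytest.approx(50.0, abs=1e-9)

    def test_reversed_input_gives_identical_output(self):
        rng = np.random.default_rng(1)
        pts = np.cumsum(rng.standard_normal((30, 3)), axis=0)
        target = pts[-1]
        a = cl.parameterize(pts, ampulla_end=target)
        b = cl.parameterize(pts[::-1], ampulla_end=target)
        np.testing.assert_allclose(a.points, b.points, atol=1e-12)

    def test_resampling_changes_length_below_half_percent(self, small_volume):
        spec, vol, gt = small_volume
        vox = cl.skeletonize(vol, "bony")
        poly = cl.trace_and_prune(vox, vol.voxel_size, vol.origin)
        poly = cl.cut_at_loci(poly, gt.end_planes[("posterior", "bony")])
        poly = cl.smooth(poly)
        raw_len = cl.cumulative_arc_length(poly)[-1]
        line = cl.parameterize(poly, gt.ampulla_ends["posterior"])
        assert abs(line.length_mm - raw_len) / raw_len < 0.005


class TestPipelineAccuracy:
    def test_length_recovery_small_phantom(self, small_volume):
        spec, vol, gt = small_volume
        for comp in ("bony", "membranous"):
            line = cl.extract_centerline(
                vol, comp, gt.end_planes[("posterior", comp)],
                gt.ampulla_ends["posterior"], canal="posterior")
            true = gt.lengths[("posterior", comp)]
            assert line.length_mm == pytest.approx(true, rel=0.02)

    def test_smoothed_line_stays_inside_tube(self, small_volume):
        spec, vol, gt = small_volume
        line = cl.extract_centerline(
            vol, "bony", gt.end_planes[("posterior", "bony")],
            gt.ampulla_ends["posterior"])
        idx = np.round(vol.world_to_index(line.points)).astype(int)
        assert (vol.grid[tuple(idx.T)] > 0).all()
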