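"""Lengths, distances, ratios and weighted plane fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canalmorph import morphometry as mm
from canalmorph.centerline import Centerline


def _circle_points(n=100, radius=1.0, normal=None, noise=0.0, rng=None):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                           np.zeros(n)])
    if noise and rng is not None:
        pts[:, 2] += noise * rng.standard_normal(n)
    if normal is not None:
        # rotate z onto the requested normal
        z = np.array([0, 0, 1.0])
        v = np.cross(z, normal)
        s = np.linalg.norm(v)
        if s > 1e-12:
            c = z @ normal
            K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                          [-v[1], v[0], 0]])
            R = np.eye(3) + K + K @ K * (1 - c) / s ** 2
            pts = pts @ R.T
    return pts


class TestLength:
    def test_collinear(self):
        assert mm.centerline_length(np.array([[0, 0, 0], [1, 0, 0],
                                              [2, 0, 0.0]])) == 2.0

    def test_three_four_five(self):
        assert mm.centerline_length(np.array([[0, 0, 0], [3, 4, 0.0]])) == 5.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            mm.centerline_length(np.array([[0, 0, 0.0]]))


class TestDistanceProfile:
    def test_identical_lines_zero(self):
        pts = np.column_stack([np.linspace(0, 10, 101), np.zeros(101),
                               np.zeros(101)])
        line = Centerline(points=pts)
        d, flags = mm.perpendicular_distance_profile(line, line)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        assert flags.all()

    def test_parallel_lines_constant_offset(self):
        x = np.linspace(0, 10, 101)
        a = Centerline(points=np.column_stack([x, np.zeros(101), np.zeros(101)]))
        b = Centerline(points=np.column_stack([x, 0.4 * np.ones(101),
                                               np.zeros(101)]))
        d, flags = mm.perpendicular_distance_profile(a, b)
        np.testing.assert_allclose(d[flags], 0.4, atol=1e-9)

    def test_offset_phantom_recovers_duct_displacement(self, small_volume):
        from canalmorph.centerline import extract_centerline
        spec, vol, gt = small_volume
        bony = extract_centerline(vol, "bony",
                                  gt.end_planes[("posterior", "bony")],
                                  gt.ampulla_ends["posterior"])
        memb = extract_centerline(vol, "membranous",
                                  gt.end_planes[("posterior", "membranous")],
                                  gt.ampulla_ends["posterior"])
        d, flags = mm.perpendicular_distance_profile(bony, memb)
        mid = (bony.percent > 15) & (bony.percent < 85) & flags
        # generator's centrifugal offset is 0.2 mm
        assert np.median(d[mid]) == pytest.approx(0.2, abs=0.02)


class TestRatio:
    def test_direct_ratio(self):
        p = mm.ProfileSet(canal="x", percent=np.array([0.0]),
                          area_endo_mm2=np.array([0.1]),
                          area_peri_mm2=np.array([0.9]),
                          area_bony_mm2=np.array([1.0]),
                          distance_mm=np.array([0.0]),
                          valid_bony=np.array([True]),
                          valid_endo=np.array([True]))
        assert p.ratio[0] == pytest.approx(0.10)

    def test_nested_tube_ratio(self):
        # nested circular tubes: ratio = (r_m / r_b)^2
        r = (0.18 / 0.57) ** 2
        p = mm.ProfileSet(canal="x", percent=np.array([0.0]),
                          area_endo_mm2=np.array([np.pi * 0.18 ** 2]),
                          area_peri_mm2=np.array([np.pi * (0.57 ** 2 - 0.18 ** 2)]),
                          area_bony_mm2=np.array([np.pi * 0.57 ** 2]),
                          distance_mm=np.array([0.0]),
                          valid_bony=np.array([True]),
                          valid_endo=np.array([True]))
        assert p.ratio[0] == pytest.approx(r, rel=1e-9)

    def test_invalid_flag_propagates(self):
        p = mm.ProfileSet(canal="x", percent=np.array([0.0, 1.0]),
                          area_endo_mm2=np.array([0.1, 0.1]),
                          area_peri_mm2=np.array([0.9, 0.9]),
                          area_bony_mm2=np.array([1.0, 1.0]),
                          distance_mm=np.array([0.0, 0.0]),
                          valid_bony=np.array([True, True]),
                          valid_endo=np.array([True, False]))
        assert np.isnan(p.ratio[1]) and not np.isnan(p.ratio[0])


class TestAssembleFitPoints:
    def _line(self, n=101, y=0.0):
        return Centerline(points=np.column_stack(
            [np.linspace(0, 10, n), np.full(n, y), np.zeros(n)]))

    def test_lateral_no_crus(self):
        pts, w, _ = mm.assemble_fit_points(self._line(), np.ones(101))
        assert len(pts) == 101

    def test_crus_appended(self):
        pts, w, _ = mm.assemble_fit_points(self._line(), np.ones(101),
                                           self._line(y=1.0), np.full(101, 2.0))
        assert len(pts) == 202
        # crus weights are 1/area^2 of its own areas
        assert w[101] == pytest.approx(0.25)

    def test_invalid_area_drops_point(self):
        areas = np.ones(101)
        areas[3] = np.nan
        pts, w, _ = mm.assemble_fit_points(self._line(), areas)
        assert len(pts) == 100

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError, match="no valid areas"):
            mm.assemble_fit_points(self._line(), np.full(101, np.nan))


def _grid_search_normal(points, weights, coarse_deg=2.0, fine_deg=0.1):
    """Independent brute-force oracle: spherical grid search (coarse, then
    locally refined to ``fine_deg``) minimizing the weighted squared
    point-plane distance about the weighted centroid."""
    w = weights / weights.sum()
    centroid = (w[:, None] * points).sum(axis=0)
    q = points - centroid

    def objective(normals):
        d = q @ normals.T
        return (weights[:, None] * d ** 2).sum(axis=0)

    def sphere(th_lo, th_hi, ph_lo, ph_hi, step):
        th = np.arange(th_lo, th_hi + step / 2, step)
        phi = np.arange(ph_lo, ph_hi + step / 2, step)
        T, P = np.meshgrid(th, phi, indexing="ij")
        n = np.column_stack([np.sin(T.ravel()) * np.cos(P.ravel()),
                             np.sin(T.ravel()) * np.sin(P.ravel()),
                             np.cos(T.ravel())])
        return n, T.ravel(), P.ravel()

    step = np.deg2rad(coarse_deg)
    n, T, P = sphere(0, np.pi, -np.pi, np.pi, step)
    k = np.argmin(objective(n))
    t0, p0 = T[k], P[k]
    step_f = np.deg2rad(fine_deg)
    n, T, P = sphere(t0 - 2 * step, t0 + 2 * step,
                     p0 - 2 * step, p0 + 2 * step, step_f)
    k = np.argmin(objective(n))
    return n[k]


class TestFitPlane:
    def test_exact_circle(self):
        pts = _circle_points()
        plane = mm.fit_plane_weighted(pts, np.ones(len(pts)))
        assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-12)
        assert plane.rms_residual < 1e-12

    def test_weights_irrelevant_for_exact_fit(self):
        rng = np.random.default_rng(2)
        pts = _circle_points()
        w = rng.uniform(0.1, 10, len(pts))
        plane = mm.fit_plane_weighted(pts, w)
        assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        """Weighted SVD fit agrees with the brute-force spherical grid
        search (0.1 degree resolution) on noisy weighted clouds."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            normal = rng.standard_normal(3)
            normal /= np.linalg.norm(normal)
            pts = _circle_points(60, normal=normal, noise=0.05, rng=rng)
            w = rng.uniform(0.2, 5.0, len(pts))
            fit = mm.fit_plane_weighted(pts, w)
            oracle = _grid_search_normal(pts, w)
            ang = np.rad2deg(np.arccos(np.clip(abs(fit.normal @ oracle), -1, 1)))
            assert ang <= 0.2

    def test_uniform_weights_reduce_to_unweighted_tls(self):
        rng = np.random.default_rng(3)
        pts = _circle_points(80, noise=0.1, rng=rng)
        a = mm.fit_plane_weighted(pts, np.ones(len(pts)))
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c)
        assert abs(a.normal @ vt[-1]) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(a.point, c, atol=1e-12)

    def test_downweighted_region_loses_influence(self):
        """Inflating the areas (weights / 100) of a contiguous 10% of points
        moves the fit toward the rest: their residual never increases."""
        rng = np.random.default_rng(5)
        pts = _circle_points(100, noise=0.02, rng=rng)
        pts[:10, 2] += 0.5          # a displaced contiguous block
        w = np.ones(100)
        base = mm.fit_plane_weighted(pts, w)
        w2 = w.copy()
        w2[:10] /= 100.0
        down = mm.fit_plane_weighted(pts, w2)

        def resid(plane, sel):
            d = (pts[sel] - plane.point) @ plane.normal
            return float((d ** 2).sum())

        assert resid(down, slice(10, None)) <= resid(base, slice(10, None)) + 1e-12

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear"):
            mm.fit_plane_weighted(pts, np.ones(10))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_rigid_equivariance(self, seed):
        """Rotating the cloud rotates the fitted normal identically."""
        rng = np.random.default_rng(seed)
        pts = _circle_points(50, noise=0.05, rng=rng)
        w = rng.uniform(0.5, 2.0, 50)
        base = mm.fit_plane_weighted(pts, w)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0, np.pi)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
        rotated = mm.fit_plane_weighted(pts @ R.T, w)
        expected = R @ base.normal
        err = np.rad2deg(np.arccos(np.clip(abs(rotated.normal @ expected),
                                           -1, 1)))
        assert err < 1e-5   # SVD round-off on near-degenerate arccos


class TestAngles:
    def test_identical_normals_zero(self):
        n = np.array([0.2, -0.5, 0.84])
        assert mm.plane_angle(n, n) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_normals(self):
        assert mm.plane_angle(np.array([0, 0, 1.0]),
                              np.array([1.0, 0, 0])) == pytest.approx(90.0)

    def test_oriented_normals_exceed_ninety(self):
        a = np.array([0, 0, 1.0])
        b = np.array([np.sin(np.deg2rad(95)), 0, np.cos(np.deg2rad(95))])
        assert mm.plane_angle(a, b) == pytest.approx(95.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 3))
        assert mm.plane_angle(a, b) == pytest.approx(mm.plane_angle(b, a))
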