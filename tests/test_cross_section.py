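"""Cross-section frames, resampling, adjacency rejection and areas."""

import numpy as np
import pytest

from canalmorph import cross_section as cs
from canalmorph.centerline import Centerline
from canalmorph.volume_io import LabelVolume


def _frame(percent=50.0, origin=(0, 0, 0), tangent=(1, 0, 0),
           u=(0, 1, 0), v=(0, 0, 1), pixel=0.015, roi=2.0, image=None):
    f = cs.SectionFrame(percent=percent, origin=np.asarray(origin, float),
                        tangent=np.asarray(tangent, float),
                        basis_u=np.asarray(u, float),
                        basis_v=np.asarray(v, float),
                        pixel_size=pixel, roi_mm=roi)
    f.image = image
    return f


def _disk_image(n=134, radius_px=30, center=None, pixel=0.015):
    img = np.zeros((n, n), dtype=np.uint8)
    if center is None:
        center = (n // 2, n // 2)
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px ** 2] = 1
    return img


class TestFramesAlong:
    def test_straight_line_constant_frames(self):
        pts = np.column_stack([np.linspace(0, 10, 21), np.zeros(21), np.zeros(21)])
        frames = cs.frames_along(Centerline(points=pts), pixel_mm=0.05)
        for f in frames:
            np.testing.assert_allclose(f.tangent, [1, 0, 0], atol=1e-12)
            np.testing.assert_allclose(f.basis_u, frames[0].basis_u, atol=1e-12)

    def test_circle_tangent_perpendicular_to_radius(self):
        t = np.linspace(0, 1.5 * np.pi, 101)
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        frames = cs.frames_along(Centerline(points=pts), pixel_mm=0.05)
        for f in frames[1:-1]:   # ends use one-sided differences (O(h))
            assert abs(f.tangent @ f.origin) < 1e-2

    def test_helix_parallel_transport_never_flips(self):
        t = np.linspace(0, 4 * np.pi, 101)
        pts = np.column_stack([np.cos(t), np.sin(t), 0.3 * t])
        frames = cs.frames_along(Centerline(points=pts), pixel_mm=0.05)
        dots = [frames[i].basis_u @ frames[i + 1].basis_u
                for i in range(len(frames) - 1)]
        assert min(dots) > 0.9

    def test_orthonormal_basis(self):
        t = np.linspace(0, np.pi, 50)
        pts = np.column_stack([np.cos(t), np.sin(t), 0.1 * t])
        for f in cs.frames_along(Centerline(points=pts), pixel_mm=0.05):
            for a, b in [(f.tangent, f.basis_u), (f.tangent, f.basis_v),
                         (f.basis_u, f.basis_v)]:
                assert abs(a @ b) < 1e-9
                assert np.linalg.norm(a) == pytest.approx(1.0)


class TestExtractSection:
    def _cylinder(self, radius=0.3, voxel=0.015):
        n = int(1.2 / voxel)
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        c = (n - 1) / 2
        m = ((y - c) ** 2 + (z - c) ** 2) * voxel ** 2 <= radius ** 2
        return LabelVolume(m.astype(np.uint8), voxel), c * voxel

    def test_perpendicular_disk_area(self):
        v, c = self._cylinder()
        f = _frame(origin=(c, c, c), roi=1.0)
        cs.extract_section(v, f)
        area = cs.section_area(f, "bony")
        assert area == pytest.approx(np.pi * 0.09, rel=0.05)

    def test_oblique_cut_inflates_area(self):
        v, c = self._cylinder()
        t = np.array([np.cos(np.deg2rad(60)), 0, np.sin(np.deg2rad(60))])
        t /= np.linalg.norm(t)
        u = np.array([0, 1.0, 0])
        w = np.cross(t, u)
        f = _frame(origin=(c, c, c), tangent=t, u=u, v=w, roi=1.6)
        cs.extract_section(v, f)
        area = cs.section_area(f, "bony")
        # cylinder cut at 60 deg from the axis: ellipse of area disk/cos(60)
        assert area == pytest.approx(np.pi * 0.09 / np.cos(np.deg2rad(60)),
                                     rel=0.06)

    def test_background_region_flagged_empty(self):
        v, c = self._cylinder()
        f = _frame(origin=(c, c + 0.55, c + 0.55), roi=0.2)
        cs.extract_section(v, f)
        cs.reject_adjacent(f, "bony")
        assert not f.valid and f.invalid_reason == cs.EMPTY

    def test_origin_outside_volume_flagged_edge(self):
        v, _ = self._cylinder()
        f = _frame(origin=(-5.0, 0, 0))
        cs.extract_section(v, f)
        assert not f.valid and f.invalid_reason == cs.EDGE


class TestRejectAdjacent:
    def test_single_disk_untouched(self):
        f = _frame(image=_disk_image())
        cs.reject_adjacent(f, "bony")
        assert f.valid
        assert cs.section_area(f, "bony") == pytest.approx(
            np.pi * (30 * 0.015) ** 2, rel=0.05)

    def test_equal_corner_disk_invalidates(self):
        img = _disk_image(radius_px=20)
        img += _disk_image(radius_px=20, center=(30, 30))
        f = _frame(image=np.clip(img, 0, 1))
        cs.reject_adjacent(f, "bony")
        assert not f.valid and f.invalid_reason == cs.ADJACENT

    def test_small_speck_erased(self):
        img = _disk_image(radius_px=20)
        img[10, 10] = img[10, 11] = 1
        f = _frame(image=img)
        cs.reject_adjacent(f, "bony")
        assert f.valid
        assert f.image[10, 10] == 0
        assert cs.section_area(f, "bony") == pytest.approx(
            np.pi * (20 * 0.015) ** 2, rel=0.05)

    def test_lumen_touching_border_invalidates(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        img[18:22, :] = 1   # band through the center to the edges
        f = _frame(image=img)
        cs.reject_adjacent(f, "bony")
        assert not f.valid and f.invalid_reason == cs.ADJACENT


class TestSectionArea:
    def test_pixel_count_formula_exact(self):
        img = np.zeros((20, 20), dtype=np.uint8)
        img[:10, :10] = 1
        f = _frame(image=img)
        assert cs.section_area(f, "bony") == pytest.approx(100 * 0.015 ** 2)

    def test_zero_pixels(self):
        f = _frame(image=np.zeros((20, 20), dtype=np.uint8))
        assert cs.section_area(f, "bony") == 0.0

    def test_invalid_frame_raises(self):
        f = _frame(image=np.zeros((20, 20), dtype=np.uint8))
        f.mark_invalid(cs.ADJACENT)
        with pytest.raises(ValueError, match="invalid"):
            cs.section_area(f, "bony")

    def test_slender_duct_scale_disk(self):
        """A 0.18 mm radius disk rasterized at 15 um pixels measures within
        5% of pi r^2 (~0.10 mm^2, the slender endolymph scale)."""
        px = 0.015
        n = 40
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        c = (n - 1) / 2 + 0.3   # sub-pixel offset, no symmetric alignment
        img = (((yy - c) ** 2 + (xx - c) ** 2) * px ** 2
               <= 0.18 ** 2).astype(np.uint8)
        f = _frame(image=img, pixel=px, roi=n * px)
        assert cs.section_area(f, "bony") == pytest.approx(
            np.pi * 0.18 ** 2, rel=0.05)


class TestProfileOnPhantom:
    def test_slender_span_areas_within_five_percent(self, small_volume):
        from canalmorph.centerline import extract_centerline
        spec, vol, gt = small_volume
        line = extract_centerline(vol, "bony",
                                  gt.end_planes[("posterior", "bony")],
                                  gt.ampulla_ends["posterior"])
        frames = cs.section_profile(vol, line)
        for f in frames:
            if not f.valid or not 10 <= f.percent <= 88:
                continue
            true = np.interp(f.percent, gt.PERCENT,
                             gt.areas[("posterior", "bony")])
            assert f.area_mm2["bony"] == pytest.approx(true, rel=0.05)
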