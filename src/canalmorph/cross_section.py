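"""Cross-sectional label images perpendicular to the bony centerline.

A square region of interest (default edge 2 mm) slides along the centerline;
at each percent-grid position the volume is resampled on the plane
perpendicular to the local tangent (nearest-neighbor lookup, so labels stay
crisp).  The in-plane basis is propagated by parallel transport to avoid
frame flips on curved canals; areas are basis-invariant regardless.
Membranous and bony sections share the bony centerline's frames so that
area ratios are position-matched.

Sections showing structures besides the pierced lumen (e.g. the adjacent
canal near the common crus) are rejected by a connected-component rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .centerline import Centerline
from .volume_io import BACKGROUND, ENDOLYMPH, LabelVolume

VALID = "none"
ADJACENT = "adjacent_region"
EMPTY = "empty"
EDGE = "edge_of_volume"


@dataclass
class SectionFrame:
    """One cross-section: plane geometry, resampled label image and state."""

    percent: float
    origin: np.ndarray               # centerline point, mm
    tangent: np.ndarray              # unit
    basis_u: np.ndarray              # unit, in-plane
    basis_v: np.ndarray              # unit, in-plane
    pixel_size: float = 0.015        # mm
    roi_mm: float = 2.0
    image: np.ndarray | None = None  # 2D label array
    valid: bool = True
    invalid_reason: str = VALID
    area_mm2: dict = field(default_factory=dict)

    def mark_invalid(self, reason: str) -> None:
        self.valid = False
        self.invalid_reason = reason


def _any_perpendicular(t: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0, 0]) if abs(t[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(t, ref)
    return u / np.linalg.norm(u)


def frames_along(line: Centerline, roi_mm: float = 2.0,
                 pixel_mm: float = 0.015) -> list[SectionFrame]:
    """Geometry-only frames at every percent-grid point of a centerline.

    Tangents are normalized central differences; the in-plane basis of the
    first frame is propagated by parallel transport (project the previous
    ``basis_u`` onto the new plane), so consecutive frames never flip.
    """
    pts = line.points
    if len(pts) < 2:
        raise ValueError("centerline needs at least two points")
    tangents = line.tangents()
    frames: list[SectionFrame] = []
    u = _any_perpendicular(tangents[0])
    # seed the transport with a fixed in-plane rotation: a canonical basis is
    # often exactly grid-aligned, and with pixel size == voxel size the
    # sampling lattice then resonates with the voxel lattice (aliased areas)
    ang = np.deg2rad(27.59)
    u = np.cos(ang) * u + np.sin(ang) * np.cross(tangents[0], u)
    for i, (p, t) in enumerate(zip(pts, tangents)):
        u = u - (u @ t) * t
        norm = np.linalg.norm(u)
        if norm < 1e-9:          # pathological kink; restart the transport
            u = _any_perpendicular(t)
        else:
            u = u / norm
        v = np.cross(t, u)
        frames.append(SectionFrame(
            percent=float(line.percent[i]), origin=p.copy(), tangent=t,
            basis_u=u.copy(), basis_v=v, pixel_size=pixel_mm, roi_mm=roi_mm))
    return frames


def extract_section(v: LabelVolume, frame: SectionFrame) -> SectionFrame:
    """Resample the volume on the frame plane (nearest-neighbor).

    Pixels sampled outside the volume read background; if any of them is
    8-adjacent to foreground the frame is marked ``edge_of_volume``, as is a
    frame whose origin lies outside the volume altogether.
    """
    half = frame.roi_mm / 2.0
    coords = np.arange(-half, half, frame.pixel_size) + frame.pixel_size / 2.0
    npix = len(coords)
    uu, vv = np.meshgrid(coords, coords, indexing="ij")
    world = (frame.origin[None, :]
             + uu.reshape(-1, 1) * frame.basis_u[None, :]
             + vv.reshape(-1, 1) * frame.basis_v[None, :])
    idx = v.world_to_index(world)
    oidx = v.world_to_index(frame.origin)
    shape = np.asarray(v.grid.shape)
    if np.any(oidx < -0.5) or np.any(oidx > shape - 0.5):
        frame.image = np.zeros((npix, npix), dtype=v.grid.dtype)
        frame.mark_invalid(EDGE)
        return frame
    img = ndimage.map_coordinates(v.grid, idx.T, order=0, mode="constant",
                                  cval=BACKGROUND).reshape(npix, npix)
    oob = (np.any(idx < -0.5, axis=1) | np.any(idx > shape - 0.5, axis=1)
           ).reshape(npix, npix)
    frame.image = img
    if oob.any():
        fg = img != BACKGROUND
        near_fg = ndimage.binary_dilation(fg, np.ones((3, 3), bool))
        if (oob & near_fg).any():
            frame.mark_invalid(EDGE)
    return frame


def _lumen_label(mask: np.ndarray, max_spiral: int = 5) -> int | None:
    """Connected-component id (8-connectivity) of the pierced lumen: the
    component at the image center, searching outward up to ``max_spiral``
    pixels if the center pixel itself misses the compartment."""
    lab = cc_label(mask, connectivity=2)
    c = np.asarray(mask.shape) // 2
    if mask[c[0], c[1]]:
        return lab[c[0], c[1]]
    yy, xx = np.nonzero(mask)
    if len(yy) == 0:
        return None
    d2 = (yy - c[0]) ** 2 + (xx - c[1]) ** 2
    k = d2.argmin()
    if d2[k] > max_spiral ** 2:
        return None
    return lab[yy[k], xx[k]]


def reject_adjacent(frame: SectionFrame, compartment: str = "bony",
                    threshold: float = 0.2,
                    lumen_extent_frac: float = 0.45) -> SectionFrame:
    """Detect sections that also show an adjacent structure.

    The 8-connected component of ``compartment`` containing the image center
    (the centerline pierce point) is the lumen.  If any other component has
    at least ``threshold`` of the lumen's area the frame is invalidated as
    ``adjacent_region``; smaller specks are erased in place.  A lumen that
    reaches the ROI border is likewise invalid: the closed canal lumen fits
    inside the ROI, so a component running out of it has merged with an
    adjacent structure (this is what happens where a canal joins the common
    crus and the two lumina become one region).
    """
    if frame.image is None:
        raise ValueError("frame has no image; run extract_section first")
    if not frame.valid:
        return frame
    mask = _compartment_mask(frame.image, compartment)
    lumen = _lumen_label(mask, max_spiral=5)
    if lumen is None:
        frame.mark_invalid(EMPTY)
        return frame
    lab = cc_label(mask, connectivity=2)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (border & (lab == lumen)).any():
        frame.mark_invalid(ADJACENT)
        return frame
    # the closed canal lumen stays near the pierce point; a component that
    # reaches much farther has merged with an adjacent structure (junctions)
    yy, xx = np.nonzero(lab == lumen)
    c = np.asarray(mask.shape) / 2.0 - 0.5
    extent = np.sqrt((yy - c[0]) ** 2 + (xx - c[1]) ** 2).max() * frame.pixel_size
    if extent > lumen_extent_frac * frame.roi_mm:
        frame.mark_invalid(ADJACENT)
        return frame
    sizes = np.bincount(lab.ravel())
    lumen_area = sizes[lumen]
    others = [k for k in range(1, len(sizes))
              if k != lumen and sizes[k] > 0]
    if any(sizes[k] >= threshold * lumen_area for k in others):
        frame.mark_invalid(ADJACENT)
        return frame
    for k in others:
        frame.image[(lab == k)] = BACKGROUND
    return frame


def _compartment_mask(img: np.ndarray, compartment: str) -> np.ndarray:
    if compartment in ("endolymph", "membranous"):
        return img == ENDOLYMPH
    if compartment == "perilymph":
        return img == 1
    if compartment in ("bony", "foreground"):
        return img != BACKGROUND
    raise ValueError(f"unknown compartment {compartment!r}")


def section_area(frame: SectionFrame, compartment: str = "bony") -> float:
    """Area = pixel count x pixel size squared (mm^2).  Raises on invalid
    frames; the caller is expected to propagate the flag instead."""
    if not frame.valid:
        raise ValueError(f"frame at {frame.percent:.0f}% is invalid "
                         f"({frame.invalid_reason})")
    mask = _compartment_mask(frame.image, compartment)
    area = float(mask.sum()) * frame.pixel_size ** 2
    frame.area_mm2[compartment] = area
    return area


def section_profile(v: LabelVolume, line: Centerline, roi_mm: float = 2.0,
                    pixel_mm: float | None = None,
                    adjacency_threshold: float = 0.2) -> list[SectionFrame]:
    """Frames along a (bony) centerline with images, adjacency filtering on
    the bony compartment, and endolymph/perilymph/bony areas attached."""
    if pixel_mm is None:
        pixel_mm = v.voxel_size
    frames = frames_along(line, roi_mm=roi_mm, pixel_mm=pixel_mm)
    for f in frames:
        extract_section(v, f)
        if not f.valid:
            continue
        reject_adjacent(f, "bony", threshold=adjacency_threshold)
        if not f.valid:
            continue
        section_area(f, "bony")
        section_area(f, "endolymph")
        section_area(f, "perilymph")
    return frames
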