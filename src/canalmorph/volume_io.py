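"""Label-volume container, file I/O and pre-analysis volume transformations.

A :class:`LabelVolume` is a 3D integer voxel grid with isotropic voxel size.
Axes are ordered (x, y, z) and world coordinates follow the right-handed
convention ``world = origin + index * voxel_size`` (the coordinate of a voxel
is that of its center).  Label codes are fixed package-wide:

    0  background
    1  perilymph   (fluid between bone and membrane)
    2  endolymph   (fluid inside the membranous duct)

The *bony labyrinth* is operationalized as the union of the perilymphatic and
endolymphatic compartments; :func:`merge_labels` collapses both onto code 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile
from scipy import ndimage

BACKGROUND = 0
PERILYMPH = 1
ENDOLYMPH = 2
VALID_CODES = (BACKGROUND, PERILYMPH, ENDOLYMPH)

LABEL_MAP = {
    "background": BACKGROUND,
    "perilymph": PERILYMPH,
    "endolymph": ENDOLYMPH,
}

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class LabelVolume:
    """3D integer label grid with isotropic voxel size (mm)."""

    grid: np.ndarray                      # int array, axes (x, y, z)
    voxel_size: float                     # mm, isotropic
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")

    # -- coordinate conversions -------------------------------------------
    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.voxel_size

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.voxel_size

    # -- masks -------------------------------------------------------------
    def mask(self, compartment: str) -> np.ndarray:
        """Boolean mask for 'endolymph'/'membranous', 'perilymph', 'bony' or
        'foreground'."""
        if compartment in ("endolymph", "membranous"):
            return self.grid == ENDOLYMPH
        if compartment == "perilymph":
            return self.grid == PERILYMPH
        if compartment in ("bony", "foreground"):
            return self.grid != BACKGROUND
        raise ValueError(f"unknown compartment {compartment!r}")

    def copy(self) -> "LabelVolume":
        return replace(self, grid=self.grid.copy(), origin=self.origin.copy())


@dataclass
class RigidTransform:
    """4x4 homogeneous transform acting on world coordinates (mm).

    The upper-left 3x3 block must be orthogonal; determinant +1 for a proper
    rigid motion, -1 for a mirror.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        R = self.matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-5):
            raise ValueError("upper-left 3x3 block is not orthogonal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray,
                                  translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @property
    def is_mirror(self) -> bool:
        return np.linalg.det(self.matrix[:3, :3]) < 0

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if out.shape[0] == 1 and pts.ndim == 1 else out

    def apply_vectors(self, vecs: np.ndarray) -> np.ndarray:
        return np.asarray(vecs, dtype=float) @ self.matrix[:3, :3].T

    # plain-text 4x4 row-major files
    def save(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls(np.loadtxt(path).reshape(4, 4))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "mha"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def write_label_volume(v: LabelVolume, path) -> None:
    """Write a label volume as NIfTI, MHA or multipage TIFF (by extension)."""
    path = Path(path)
    fmt = _detect_format(path)
    if fmt == "tiff":
        # pages along z; voxel size kept in the image description
        desc = json.dumps({"voxel_size_mm": v.voxel_size,
                           "origin_mm": list(v.origin)})
        tifffile.imwrite(path, np.ascontiguousarray(v.grid.T.astype(np.uint8)),
                         description=desc)
        return
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.grid.T.astype(np.uint8)))
    img.SetSpacing((v.voxel_size,) * 3)
    img.SetOrigin(tuple(float(o) for o in v.origin))
    sitk.WriteImage(img, str(path))


def read_label_volume(path, voxel_size: float | None = None,
                      label_remap: dict[int, int] | None = None) -> LabelVolume:
    """Read a label volume, remapping foreign codes onto the canonical map.

    Parameters
    ----------
    voxel_size : overrides/declares the voxel size (required for TIFF stacks
        without an embedded description).
    label_remap : mapping from file codes to canonical codes, e.g. ``{7: 1,
        9: 2}``.  Codes absent from the map and not already canonical raise.
    """
    path = Path(path)
    fmt = _detect_format(path)
    origin = np.zeros(3)
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
        vs = voxel_size
        if vs is None and desc:
            try:
                meta = json.loads(desc)
                vs = meta.get("voxel_size_mm")
                origin = np.asarray(meta.get("origin_mm", [0, 0, 0]), dtype=float)
            except (ValueError, AttributeError):
                pass
        if vs is None:
            raise ValueError("TIFF stack carries no voxel size; pass voxel_size=")
        grid = arr.T
    else:
        img = sitk.ReadImage(str(path))
        sp = np.asarray(img.GetSpacing())
        if not np.allclose(sp, sp[0], rtol=1e-5):
            raise ValueError(f"anisotropic voxels {tuple(sp)} are not supported")
        vs = voxel_size if voxel_size is not None else float(sp[0])
        origin = np.asarray(img.GetOrigin(), dtype=float)
        grid = sitk.GetArrayFromImage(img).T

    grid = np.asarray(grid)
    if label_remap:
        out = np.zeros_like(grid)
        for src, dst in label_remap.items():
            out[grid == src] = dst
        known = set(label_remap) | {0}
        offenders = sorted(int(c) for c in np.unique(grid) if int(c) not in known)
        if offenders:
            raise ValueError(f"unknown label codes in {path.name}: {offenders}")
        grid = out
    else:
        offenders = sorted(int(c) for c in np.unique(grid)
                           if int(c) not in VALID_CODES)
        if offenders:
            raise ValueError(
                f"unknown label codes in {path.name}: {offenders}; "
                f"pass label_remap= to translate them")
    return LabelVolume(grid.astype(np.uint8), float(vs), origin)


# ---------------------------------------------------------------------------
# volume transformations
# ---------------------------------------------------------------------------

def merge_labels(v: LabelVolume) -> LabelVolume:
    """Merge endolymphatic and perilymphatic compartments into one bony
    foreground (code 1).  Voxel counts add exactly."""
    out = v.copy()
    out.grid = np.where(v.grid != BACKGROUND, PERILYMPH, BACKGROUND).astype(v.grid.dtype)
    return out


def fill_holes(v: LabelVolume) -> LabelVolume:
    """Fill interior background cavities (6-connectivity to the grid boundary).

    Filled voxels take the label of their nearest foreground voxel so that
    cavities inside the endolymphatic duct stay endolymph.  Foreground never
    shrinks; through-holes connected to the boundary stay open.
    """
    fg = v.grid != BACKGROUND
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    filled = ndimage.binary_fill_holes(fg, structure=structure)
    new = filled & ~fg
    out = v.copy()
    if new.any():
        _, (ix, iy, iz) = ndimage.distance_transform_edt(~fg, return_indices=True)
        out.grid[new] = v.grid[ix[new], iy[new], iz[new]]
    return out


def mirror_volume(v: LabelVolume, axis: str = "x") -> tuple[LabelVolume, RigidTransform]:
    """Reflect the grid about the volume center along ``axis``.

    Returns the mirrored volume and the world-coordinate reflection it
    realizes (determinant -1).  Mirroring twice restores the original grid.
    """
    ax = _AXES[axis]
    out = v.copy()
    out.grid = np.flip(v.grid, axis=ax).copy()
    center = v.origin[ax] + (v.grid.shape[ax] - 1) / 2.0 * v.voxel_size
    m = np.eye(4)
    m[ax, ax] = -1.0
    m[ax, 3] = 2.0 * center
    return out, RigidTransform(m)


def apply_transform(v: LabelVolume, t: RigidTransform) -> LabelVolume:
    """Resample ``v`` under the world-coordinate motion ``t`` (moving the
    object by ``t``), with nearest-neighbor interpolation so labels never
    blend.  The output grid keeps the input shape and origin."""
    if abs(np.linalg.det(t.matrix)) < 1e-12:
        raise ValueError("transform matrix is not invertible")
    inv = np.linalg.inv(t.matrix)
    A, b = inv[:3, :3], inv[:3, 3]
    # output index -> input index:  i_in = A i_out + (A o + b - o)/s
    offset = (A @ v.origin + b - v.origin) / v.voxel_size
    out = v.copy()
    out.grid = ndimage.affine_transform(
        v.grid, A, offset=offset, order=0, mode="constant", cval=BACKGROUND,
        output=v.grid.dtype)
    return out
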