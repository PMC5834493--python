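"""Signed-distance-map rigid registration and anatomical reorientation.

Specimens are scanned in random orientations; each one is registered onto a
reference specimen by aligning signed Euclidean distance maps of the merged
(bony) label.  The dissimilarity is the mean squared difference between the
maps — on signed distance maps this is smooth and well-behaved near the
optimum, serving the same purpose as an information-theoretic metric on
labels.  Optimization is rigid (3 rotations + 3 translations) over a
coarse-to-fine pyramid, with optional seeded multi-starts for large initial
misalignments.

Anatomical (Reid's frame) orientation is restored by composing the
registration with an externally supplied 4x4 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume_io import LabelVolume, RigidTransform, apply_transform


@dataclass
class DistanceMap:
    """Signed Euclidean distance to the foreground boundary, in mm:
    negative inside, positive outside."""

    grid: np.ndarray             # float array, axes (x, y, z)
    voxel_size: float
    origin: np.ndarray


@dataclass
class RegistrationResult:
    transform: RigidTransform    # maps moving world coords onto fixed
    final_metric: float
    initial_metric: float
    converged: bool


def signed_distance_map(v: LabelVolume, compartment: str = "bony") -> DistanceMap:
    """Signed Euclidean distance transform of a compartment, scaled to mm."""
    fg = v.mask(compartment)
    if not fg.any():
        raise ValueError(f"empty {compartment} foreground")
    outside = ndimage.distance_transform_edt(~fg)
    inside = ndimage.distance_transform_edt(fg)
    return DistanceMap((outside - inside) * v.voxel_size, v.voxel_size,
                       v.origin.copy())


def _to_sitk(m: DistanceMap) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(m.grid.T.astype(np.float32)))
    img.SetSpacing((m.voxel_size,) * 3)
    img.SetOrigin(tuple(float(o) for o in m.origin))
    return img


def _euler_to_matrix(tr: sitk.Euler3DTransform) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = np.asarray(tr.GetMatrix()).reshape(3, 3)
    c = np.asarray(tr.GetCenter())
    t = np.asarray(tr.GetTranslation())
    m[:3, 3] = c + t - m[:3, :3] @ c
    return m


_CLAMP_MM = 0.6   # distance band (~canal radius) used to score alignment


def _mean_sq_diff(fixed: sitk.Image, moving: sitk.Image,
                  transform: sitk.Transform) -> float:
    """SSD between distance maps clamped to a band around the boundary, so
    far-field values (and out-of-bounds resampling) do not dominate."""
    res = sitk.Resample(moving, fixed, transform, sitk.sitkLinear, _CLAMP_MM)
    a = np.clip(sitk.GetArrayViewFromImage(fixed), -_CLAMP_MM, _CLAMP_MM)
    b = np.clip(sitk.GetArrayViewFromImage(res), -_CLAMP_MM, _CLAMP_MM)
    return float(np.mean((a - b) ** 2))


def register_rigid(moving: DistanceMap, fixed: DistanceMap,
                   init: RigidTransform | None = None,
                   n_starts: int = 0, seed: int = 0,
                   improvement_tol: float = 1e-3) -> RegistrationResult:
    """Rigid registration of two signed distance maps.

    Returns the transform that maps the moving volume's world coordinates
    onto the fixed frame (apply it to the moving volume to align it).  If
    the optimizer fails to improve on the initialization beyond
    ``improvement_tol`` (relative), the result is flagged non-converged and
    carries the best transform found.  ``n_starts`` extra seeded random
    rotational initializations guard against large misalignments.
    """
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    # sitk's resampling transform maps fixed-space points into moving space;
    # our convention is the inverse (moving onto fixed)
    init_sitk = sitk.Euler3DTransform()
    center = np.asarray(f_img.TransformContinuousIndexToPhysicalPoint(
        [(s - 1) / 2.0 for s in f_img.GetSize()]))
    init_sitk.SetCenter(tuple(center))
    inits = [init_sitk]
    if init is not None:
        base = sitk.Euler3DTransform()
        base.SetCenter(tuple(center))
        inv = np.linalg.inv(init.matrix)
        base.SetMatrix(tuple(inv[:3, :3].ravel()))
        base.SetTranslation(tuple(inv[:3, :3] @ center + inv[:3, 3] - center))
        inits = [base]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        extra = sitk.Euler3DTransform()
        extra.SetCenter(tuple(center))
        extra.SetRotation(*rng.uniform(-np.pi / 2, np.pi / 2, 3))
        inits.append(extra)

    initial_metric = _mean_sq_diff(f_img, m_img, inits[0])
    best = (initial_metric, inits[0])
    for start in inits:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=2.0, minStep=5e-6, numberOfIterations=200,
            relaxationFactor=0.7, gradientMagnitudeTolerance=1e-10)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(sitk.Euler3DTransform(start), inPlace=False)
        try:
            out = reg.Execute(f_img, m_img)
        except RuntimeError:
            continue
        if isinstance(out, sitk.CompositeTransform):
            out = out.GetNthTransform(0)
        euler = sitk.Euler3DTransform(out)
        metric = _mean_sq_diff(f_img, m_img, euler)
        if metric < best[0]:
            best = (metric, euler)
    final_metric, best_tr = best
    converged = final_metric < initial_metric * (1.0 - improvement_tol) \
        or final_metric <= improvement_tol * float(np.mean(fixed.grid ** 2))
    matrix = np.linalg.inv(_euler_to_matrix(best_tr))
    return RegistrationResult(RigidTransform(matrix), final_metric,
                              initial_metric, converged)


def reorient(v: LabelVolume, skull_matrix: RigidTransform,
             registration: RigidTransform | None = None) -> LabelVolume:
    """Apply the anatomical-frame matrix (optionally composed with the
    specimen's registration transform) to a label volume in one resampling.

    The skull matrix expresses the reference specimen's pose in the
    anatomical (Reid's) frame and must be supplied externally; without it,
    absolute canal-plane orientations are frame-dependent and meaningless.
    """
    if skull_matrix is None:
        raise ValueError(
            "anatomical orientation requires the external 4x4 skull matrix; "
            "plane angles are frame-dependent without it")
    total = skull_matrix if registration is None \
        else skull_matrix.compose(registration)
    return apply_transform(v, total)
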