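"""Voxel phantoms of the semicircular-canal labyrinth with analytic ground truth.

Each canal is modeled as a circular-arc tube pair: a bony canal of radius
``r_b(percent)`` around an arc centerline, and a membranous duct of radius
``r_m(percent)`` whose centerline is the concentric arc displaced radially
*outward* (centrifugally) by ``membranous_offset`` and optionally tilted out
of the bony canal plane by a few degrees.  The common crus is a straight tube
joining the non-ampullary (0 %) ends of the posterior and superior canals,
running along the intersection line of their planes so that appending it to a
plane fit does not bias the fitted normal.

Cross-sections perpendicular to the arc tangent are circles, so every
downstream quantity has a closed form: arc length = major_radius x arc span,
area(percent) = pi r(percent)^2, plane normals and inter-canal angles are the
construction inputs.  Default dimensions give a posterior/superior/lateral
bony centerline of 16.716 / 15.047 / 12.571 mm and bony plane normals
subtending 90.374 / 87.158 / 91.801 degrees pairwise.

Rasterization decides voxel membership at voxel centers (no anti-aliasing):
endolymph where the voxel center lies inside the membranous tube, perilymph
where inside the bony tube only.  Tubes are extended beyond both measurement
endpoints by ``end_margin_mm`` so skeletons can be cut back at the exact
ground-truth end planes, emulating the cut-off loci applied to real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import BACKGROUND, ENDOLYMPH, PERILYMPH, LabelVolume

CANAL_NAMES = ("posterior", "superior", "lateral")
ALL_NAMES = CANAL_NAMES + ("common_crus",)

# default dimensions (mm / degrees)
_LENGTHS = {"posterior": 16.716, "superior": 15.047, "lateral": 12.571}
_LENGTH_SD = {"posterior": 1.334, "superior": 1.211, "lateral": 0.896}
_SPANS_DEG = {"posterior": 250.0, "superior": 240.0, "lateral": 235.0}
_PAIR_ANGLES_DEG = {("posterior", "superior"): 90.374,
                    ("posterior", "lateral"): 87.158,
                    ("superior", "lateral"): 91.801}
_MEMB_TILT_DEG = {"posterior": 3.37, "superior": 4.23, "lateral": 2.36}
_MEMB_TILT_SD = {"posterior": 1.84, "superior": 1.56, "lateral": 1.36}
_MEMB_OFFSET = {"posterior": 0.25, "superior": 0.20, "lateral": 0.25}
BONY_RADIUS = 0.57          # mm, slender-part bony canal radius
MEMB_RADIUS = 0.18          # mm, slender-part membranous duct radius
CRUS_LENGTH = 2.683         # mm
CRUS_LENGTH_SD = 0.564
CRUS_BONY_RADIUS = BONY_RADIUS * np.sqrt(2.0)   # crus area ~ 2x canal area
CRUS_MEMB_RADIUS = 0.36
CRUS_MEMB_OFFSET = 0.05
NORMAL_JITTER_SD_DEG = 3.2  # per-canal plane jitter for synthetic cohorts


@dataclass
class Bump:
    """Gaussian widening of a radius profile: position/width in percent of
    the measured span, amplitude in mm added to the base radius."""
    position_pct: float
    amplitude_mm: float
    width_pct: float

    def __call__(self, pct: np.ndarray) -> np.ndarray:
        return self.amplitude_mm * np.exp(
            -0.5 * ((np.asarray(pct, float) - self.position_pct) / self.width_pct) ** 2)


@dataclass
class RadiusProfile:
    """Base radius plus Gaussian bumps, evaluated on the 0-100 percent axis
    (clamped outside the measured span, i.e. in the end margins)."""
    base_mm: float
    bumps: tuple[Bump, ...] = ()

    def __call__(self, pct: np.ndarray) -> np.ndarray:
        pct = np.clip(np.asarray(pct, dtype=float), 0.0, 100.0)
        r = np.full_like(pct, self.base_mm)
        for b in self.bumps:
            r = r + b(pct)
        return r


@dataclass
class CanalSpec:
    """Geometry of one canal (arc tube pair) or of the straight common crus.

    For arcs the centerline is ``center + R(cos t a + sin t b)`` with
    ``b = normal x a``; percent 0 is at t=0 (the crus/non-ampullary end) and
    percent 100 at t=arc_span.  For the common crus ``segment_start/end``
    replace the arc fields.
    """

    name: str
    plane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    major_radius: float = 3.0
    arc_span_deg: float = 250.0
    start_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    bony_radius_profile: RadiusProfile = field(
        default_factory=lambda: RadiusProfile(BONY_RADIUS))
    membranous_radius_profile: RadiusProfile = field(
        default_factory=lambda: RadiusProfile(MEMB_RADIUS))
    membranous_offset: float = 0.25
    membranous_tilt_deg: float = 0.0    # rotation of the duct plane about start_direction
    end_margin_mm: float = 1.2          # tube extension beyond both measurement ends
    segment_start: np.ndarray | None = None
    segment_end: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("plane_normal", "center", "start_direction"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = np.linalg.norm(self.plane_normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"{self.name}: plane_normal must be unit length")
        if self.segment_start is not None:
            self.segment_start = np.asarray(self.segment_start, dtype=float)
            self.segment_end = np.asarray(self.segment_end, dtype=float)

    # -- derived geometry --------------------------------------------------
    @property
    def is_segment(self) -> bool:
        return self.segment_start is not None

    @property
    def arc_span_rad(self) -> float:
        return np.deg2rad(self.arc_span_deg)

    @property
    def length_mm(self) -> float:
        """Analytic bony centerline length between the measurement ends."""
        if self.is_segment:
            return float(np.linalg.norm(self.segment_end - self.segment_start))
        return self.major_radius * self.arc_span_rad

    @property
    def membranous_length_mm(self) -> float:
        if self.is_segment:
            return self.length_mm
        return (self.major_radius + self.membranous_offset) * self.arc_span_rad

    def _frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(a, b, n) with a the start radial direction, b = n x a."""
        n = self.plane_normal
        a = self.start_direction - (self.start_direction @ n) * n
        norm = np.linalg.norm(a)
        if norm < 1e-9:
            raise ValueError(f"{self.name}: start_direction parallel to plane normal")
        a = a / norm
        return a, np.cross(n, a), n

    def _membranous_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Membranous duct frame: canal frame rotated by the plane tilt about
        the start radial direction (keeps the 0 % junction point fixed)."""
        a, b, n = self._frame()
        t = np.deg2rad(self.membranous_tilt_deg)
        if abs(t) < 1e-15:
            return a, b, n
        c, s = np.cos(t), np.sin(t)
        rot = (np.eye(3) * c + s * _skew(a) + (1 - c) * np.outer(a, a))
        return a, rot @ b, rot @ n

    def membranous_plane_normal(self) -> np.ndarray:
        if self.is_segment:
            return self.plane_normal
        return self._membranous_frame()[2]

    def centerline_points(self, pct: np.ndarray, compartment: str = "bony") -> np.ndarray:
        """Analytic centerline points at the given percent positions."""
        pct = np.asarray(pct, dtype=float)
        if self.is_segment:
            d = (self.segment_end - self.segment_start)
            pts = self.segment_start + (pct / 100.0)[:, None] * d
            if compartment in ("membranous", "endolymph"):
                pts = pts + self.membranous_offset * _perp(d / np.linalg.norm(d))
            return pts
        if compartment in ("membranous", "endolymph"):
            a, b, _ = self._membranous_frame()
            radius = self.major_radius + self.membranous_offset
        else:
            a, b, _ = self._frame()
            radius = self.major_radius
        theta = (pct / 100.0) * self.arc_span_rad
        return (self.center
                + radius * (np.cos(theta)[:, None] * a + np.sin(theta)[:, None] * b))

    def end_planes(self, compartment: str = "bony") -> list[tuple[np.ndarray, np.ndarray]]:
        """Measurement cut planes: (point, inward tangent) at 0 % and 100 %."""
        pts = self.centerline_points(np.array([0.0, 1.0, 99.0, 100.0]), compartment)
        t0 = pts[1] - pts[0]
        t1 = pts[2] - pts[3]
        return [(pts[0], t0 / np.linalg.norm(t0)), (pts[3], t1 / np.linalg.norm(t1))]

    def radius(self, pct, compartment: str) -> np.ndarray:
        if compartment in ("membranous", "endolymph"):
            return self.membranous_radius_profile(pct)
        return self.bony_radius_profile(pct)

    # -- validity ----------------------------------------------------------
    def validate(self) -> None:
        """Reject geometries whose membranous duct leaves the bony canal or
        whose tube self-intersects."""
        pct = np.linspace(0.0, 100.0, 501)
        rb = self.bony_radius_profile(pct)
        rm = self.membranous_radius_profile(pct)
        if not self.is_segment and self.major_radius <= rb.max():
            raise ValueError(
                f"{self.name}: major_radius {self.major_radius:.3f} mm must exceed "
                f"the peak bony radius {rb.max():.3f} mm (tube self-intersects)")
        memb = self.centerline_points(pct, "membranous")
        bony = self.centerline_points(np.linspace(0, 100, 2001), "bony")
        # distance of each membranous centerline point to the bony centerline
        d = np.sqrt(((memb[:, None, :] - bony[None, :, :]) ** 2).sum(-1))
        j = d.argmin(axis=1)
        gap = d[np.arange(len(pct)), j] + rm - self.bony_radius_profile(
            np.linspace(0, 100, 2001)[j])
        if gap.max() > 1e-9:
            k = int(gap.argmax())
            raise ValueError(
                f"{self.name}: membranous duct leaves the bony canal near "
                f"{pct[k]:.0f}% (excess {gap.max():.3f} mm); reduce the offset, "
                f"tilt or duct radius")


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


def _perp(v: np.ndarray) -> np.ndarray:
    """Some unit vector perpendicular to v (deterministic)."""
    ref = np.array([1.0, 0, 0]) if abs(v[0]) < 0.9 else np.array([0, 1.0, 0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


@dataclass
class PhantomSpec:
    canals: list[CanalSpec]
    voxel_size: float = 0.015   # mm
    pad: int = 4                # voxels of padding around the tube bounding box
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        names = [c.name for c in self.canals]
        if len(names) != len(set(names)):
            raise ValueError(f"canal names must be unique, got {names}")

    def canal(self, name: str) -> CanalSpec:
        for c in self.canals:
            if c.name == name:
                return c
        raise KeyError(name)

    def subset(self, names: list[str]) -> "PhantomSpec":
        return PhantomSpec([c for c in self.canals if c.name in names],
                           self.voxel_size, self.pad, self.seed)


# ---------------------------------------------------------------------------
# default labyrinth
# ---------------------------------------------------------------------------

def _canal_normals(pair_angles: dict[tuple[str, str], float]) -> dict[str, np.ndarray]:
    """Three unit normals realizing the prescribed pairwise angles, via the
    Cholesky factor of the Gram matrix."""
    c = {k: np.cos(np.deg2rad(v)) for k, v in pair_angles.items()}
    G = np.array([
        [1.0, c[("posterior", "superior")], c[("posterior", "lateral")]],
        [c[("posterior", "superior")], 1.0, c[("superior", "lateral")]],
        [c[("posterior", "lateral")], c[("superior", "lateral")], 1.0]])
    L = np.linalg.cholesky(G)
    return dict(zip(CANAL_NAMES, L))


def _shrink_to_nested(canal: CanalSpec, max_iter: int = 40) -> None:
    """Shrink a jittered canal's duct offset (first) and plane tilt (second)
    until the membranous duct fits inside the bony canal.  Circular nested
    tubes cannot host every drawn (offset, tilt) combination; real ducts
    evade this by being non-circular and wall-hugging, which the phantom
    does not model."""
    for _ in range(max_iter):
        try:
            canal.validate()
            return
        except ValueError:
            if canal.membranous_offset > 0.06:
                canal.membranous_offset *= 0.85
            else:
                canal.membranous_tilt_deg *= 0.85
    canal.validate()


def default_labyrinth_spec(seed: int = 0, lateral_bulge: bool = False,
                           jitter_scale: float = 0.0,
                           voxel_size: float = 0.015) -> PhantomSpec:
    """Default four-structure labyrinth phantom.

    With ``jitter_scale == 0`` the geometry is exact: bony centerline lengths
    16.716 / 15.047 / 12.571 mm, bony plane angles 90.374 / 87.158 / 91.801
    degrees, crus length 2.683 mm, membranous plane tilts 3.37 / 4.23 / 2.36
    degrees.  ``jitter_scale = 1`` perturbs lengths, plane orientations and
    tilts by the corresponding cohort standard deviations (seeded), which is
    how synthetic cohorts are drawn.  ``lateral_bulge`` widens the lateral
    membranous duct over the 0-20 % span (the end opposing the ampulla), a
    variant seen in roughly a third of real specimens.
    """
    rng = np.random.default_rng(seed)
    normals = _canal_normals(_PAIR_ANGLES_DEG)

    lengths = dict(_LENGTHS)
    tilts = dict(_MEMB_TILT_DEG)
    crus_length = CRUS_LENGTH
    if jitter_scale > 0:
        for k in lengths:
            lengths[k] += jitter_scale * _LENGTH_SD[k] * rng.standard_normal()
            tilts[k] = max(0.0, tilts[k]
                           + jitter_scale * _MEMB_TILT_SD[k] * rng.standard_normal())
        crus_length = max(1.0, crus_length
                          + jitter_scale * CRUS_LENGTH_SD * rng.standard_normal())
        for k in normals:
            ang = np.deg2rad(jitter_scale * NORMAL_JITTER_SD_DEG) * rng.standard_normal()
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            c, s = np.cos(ang), np.sin(ang)
            rot = np.eye(3) * c + s * _skew(axis) + (1 - c) * np.outer(axis, axis)
            normals[k] = rot @ normals[k]

    junction = np.zeros(3)
    zhat = np.array([0.0, 0.0, 1.0])
    ampulla = Bump(95.0, 0.35 - MEMB_RADIUS, 4.0)
    bony_ampulla = Bump(95.0, 0.85 - BONY_RADIUS, 5.0)

    canals: list[CanalSpec] = []
    for name in CANAL_NAMES:
        n = normals[name]
        span = _SPANS_DEG[name]
        R = lengths[name] / np.deg2rad(span)
        memb_bumps: list[Bump] = [ampulla]
        bony_bumps: list[Bump] = [bony_ampulla]
        if name == "lateral":
            # perilymphatic widening toward both canal ends ("parabolic" bony
            # area course of the lateral canal)
            bony_bumps += [Bump(0.0, 0.25, 12.0), Bump(100.0, 0.10, 8.0)]
            if lateral_bulge:
                memb_bumps.append(Bump(5.0, 0.33 - MEMB_RADIUS, 7.0))
            start_dir = np.array([0.0, 1.0, 0.0])
            start_point = np.array([0.8, -0.8, -0.6])
        else:
            start_dir = zhat
            start_point = junction
        a = start_dir - (start_dir @ n) * n
        a /= np.linalg.norm(a)
        canal = CanalSpec(
            name=name, plane_normal=n, center=start_point - R * a,
            major_radius=R, arc_span_deg=span, start_direction=start_dir,
            bony_radius_profile=RadiusProfile(BONY_RADIUS, tuple(bony_bumps)),
            membranous_radius_profile=RadiusProfile(MEMB_RADIUS, tuple(memb_bumps)),
            membranous_offset=_MEMB_OFFSET[name],
            membranous_tilt_deg=tilts[name])
        if jitter_scale > 0:
            _shrink_to_nested(canal)
        canals.append(canal)

    # common crus along the intersection line of the posterior and superior
    # planes so that appending it to either plane fit is unbiased
    e = np.cross(normals["posterior"], normals["superior"])
    e /= np.linalg.norm(e)
    if e @ zhat < 0:
        e = -e
    canals.append(CanalSpec(
        name="common_crus",
        plane_normal=e,                       # records the axis direction
        segment_start=junction.copy(),
        segment_end=junction + crus_length * e,
        bony_radius_profile=RadiusProfile(CRUS_BONY_RADIUS),
        membranous_radius_profile=RadiusProfile(CRUS_MEMB_RADIUS),
        membranous_offset=CRUS_MEMB_OFFSET,
        end_margin_mm=0.9))

    return PhantomSpec(canals, voxel_size=voxel_size, seed=seed)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomGroundTruth:
    """Analytic quantities for every structure of a phantom, on a 101-point
    percent grid: centerlines (mm), lengths (mm), area profiles (mm^2),
    plane normals and pairwise inter-canal angles (degrees)."""

    voxel_size: float
    centerlines: dict          # (name, compartment) -> (101, 3) array
    lengths: dict              # (name, compartment) -> mm
    areas: dict                # (name, compartment) -> (101,) array, pi r^2
    plane_normals: dict        # (name, compartment) -> unit 3-vector
    end_planes: dict           # (name, compartment) -> [(point, tangent), x2]
    ampulla_ends: dict         # name -> 3-vector, the 100 % endpoint (bony)
    angles: dict               # (name_a, name_b, compartment) -> degrees
    tilt_angles: dict          # name -> bony-vs-membranous plane angle, degrees

    PERCENT = np.linspace(0.0, 100.0, 101)

    def to_json(self, path) -> None:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            return o
        payload = {
            "voxel_size": self.voxel_size,
            "lengths": {f"{k[0]}/{k[1]}": float(v) for k, v in self.lengths.items()},
            "angles": {f"{a}/{b}/{c}": float(v) for (a, b, c), v in self.angles.items()},
            "tilt_angles": {k: float(v) for k, v in self.tilt_angles.items()},
            "plane_normals": {f"{k[0]}/{k[1]}": conv(v)
                              for k, v in self.plane_normals.items()},
            "areas": {f"{k[0]}/{k[1]}": conv(v) for k, v in self.areas.items()},
            "centerlines": {f"{k[0]}/{k[1]}": conv(v)
                            for k, v in self.centerlines.items()},
        }
        Path(path).write_text(json.dumps(payload))


def ground_truth(spec: PhantomSpec) -> PhantomGroundTruth:
    pct = PhantomGroundTruth.PERCENT
    centerlines, lengths, areas, normals, end_planes, amp_ends = {}, {}, {}, {}, {}, {}
    for c in spec.canals:
        for comp in ("bony", "membranous"):
            key = (c.name, comp)
            centerlines[key] = c.centerline_points(pct, comp)
            lengths[key] = c.length_mm if comp == "bony" else c.membranous_length_mm
            areas[key] = np.pi * c.radius(pct, comp) ** 2
            normals[key] = (c.plane_normal if comp == "bony"
                            else c.membranous_plane_normal())
            end_planes[key] = c.end_planes(comp)
        amp_ends[c.name] = centerlines[(c.name, "bony")][-1]
    angles = {}
    for comp in ("bony", "membranous"):
        for i, a in enumerate(CANAL_NAMES):
            for b in CANAL_NAMES[i + 1:]:
                if (a, comp) in normals and (b, comp) in normals:
                    cosang = np.clip(normals[(a, comp)] @ normals[(b, comp)], -1, 1)
                    angles[(a, b, comp)] = float(np.rad2deg(np.arccos(cosang)))
    tilts = {}
    for c in spec.canals:
        cosang = np.clip(normals[(c.name, "bony")] @ normals[(c.name, "membranous")],
                         -1, 1)
        tilts[c.name] = float(np.rad2deg(np.arccos(cosang)))
    return PhantomGroundTruth(spec.voxel_size, centerlines, lengths, areas,
                              normals, end_planes, amp_ends, angles, tilts)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _arc_distance(pts: np.ndarray, center: np.ndarray, a: np.ndarray,
                  b: np.ndarray, n: np.ndarray, radius: float,
                  span_rad: float, margin_rad: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Perpendicular distance of points from an arc, an in-range mask for the
    angular extent (span plus end margins, flat cut), and the percent
    coordinate (clamped to [0, 100]) of the nearest arc point."""
    d = pts - center
    z = d @ n
    u = d @ a
    v = d @ b
    theta = np.arctan2(v, u)
    # unwrap around the arc midpoint so the residual gap splits evenly
    mid = span_rad / 2.0
    theta = np.where(theta < mid - np.pi, theta + 2 * np.pi, theta)
    rho = np.hypot(u, v)
    dist = np.hypot(rho - radius, z)
    in_range = (theta >= -margin_rad) & (theta <= span_rad + margin_rad)
    pct = np.clip(theta / span_rad, 0.0, 1.0) * 100.0
    return dist, in_range, pct


def _segment_distance(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                      margin_mm: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = p1 - p0
    L = np.linalg.norm(d)
    d = d / L
    t = (pts - p0) @ d
    radial = pts - p0 - t[:, None] * d
    dist = np.linalg.norm(radial, axis=1)
    in_range = (t >= -margin_mm) & (t <= L + margin_mm)
    pct = np.clip(t / L, 0.0, 1.0) * 100.0
    return dist, in_range, pct


def _tube_mask(pts: np.ndarray, c: CanalSpec, compartment: str) -> np.ndarray:
    """Boolean membership of world points in the (extended, flat-capped)
    tube."""
    if c.is_segment:
        p0 = c.centerline_points(np.array([0.0]), compartment)[0]
        p1 = c.centerline_points(np.array([100.0]), compartment)[0]
        dist, in_range, pct = _segment_distance(pts, p0, p1, c.end_margin_mm)
    else:
        if compartment in ("membranous", "endolymph"):
            a, b, n = c._membranous_frame()
            radius = c.major_radius + c.membranous_offset
        else:
            a, b, n = c._frame()
            radius = c.major_radius
        margin_rad = c.end_margin_mm / radius
        dist, in_range, pct = _arc_distance(pts, c.center, a, b, n, radius,
                                            c.arc_span_rad, margin_rad)
    return in_range & (dist <= c.radius(pct, compartment))


def _bounding_box(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    pct = np.linspace(0, 100, 200)
    for c in spec.canals:
        for comp in ("bony", "membranous"):
            pts = c.centerline_points(pct, comp)
            r = c.radius(pct, comp).max() + c.end_margin_mm
            lo = np.minimum(lo, pts.min(axis=0) - r)
            hi = np.maximum(hi, pts.max(axis=0) + r)
    return lo, hi


def rasterize(spec: PhantomSpec) -> tuple[LabelVolume, PhantomGroundTruth]:
    """Rasterize a phantom at voxel centers.

    Labels: 0 background, 1 perilymph (inside a bony tube but outside every
    membranous tube), 2 endolymph (inside a membranous tube).  Raises if any
    canal violates the nesting invariant.  Deterministic: identical specs
    produce bit-identical volumes.
    """
    for c in spec.canals:
        c.validate()
    gt = ground_truth(spec)
    if not spec.canals:
        return LabelVolume(np.zeros((1, 1, 1), np.uint8), spec.voxel_size), gt

    vs = spec.voxel_size
    lo, hi = _bounding_box(spec)
    # distinct sub-voxel grid shifts per axis: keeps object symmetry planes
    # (including diagonal ones) off inter-voxel planes, where thinning of
    # perfectly symmetric tubes is degenerate
    origin = lo - (spec.pad + np.array([0.2347, 0.1123, 0.3741])) * vs
    shape = np.ceil((hi - origin) / vs).astype(int) + spec.pad
    grid = np.zeros(tuple(shape), dtype=np.uint8)

    xs = origin[0] + np.arange(shape[0]) * vs
    ys = origin[1] + np.arange(shape[1]) * vs
    zs = origin[2] + np.arange(shape[2]) * vs
    # process in x-slabs to bound the size of float temporaries
    slab = max(1, int(4e6 // (shape[1] * shape[2])))
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    for x0 in range(0, shape[0], slab):
        x1 = min(x0 + slab, shape[0])
        nx = x1 - x0
        pts = np.empty((nx * shape[1] * shape[2], 3))
        pts[:, 0] = np.repeat(xs[x0:x1], shape[1] * shape[2])
        pts[:, 1] = np.tile(yy.ravel(), nx)
        pts[:, 2] = np.tile(zz.ravel(), nx)
        labels = np.zeros(len(pts), dtype=np.uint8)
        for c in spec.canals:
            inside_b = _tube_mask(pts, c, "bony")
            labels[inside_b & (labels == BACKGROUND)] = PERILYMPH
            inside_m = _tube_mask(pts, c, "membranous")
            labels[inside_m] = ENDOLYMPH
        grid[x0:x1] = labels.reshape(nx, shape[1], shape[2])
    return LabelVolume(grid, vs, origin), gt


def cohort_specs(n: int, seed: int = 0, voxel_size: float = 0.015,
                 lateral_bulge_fraction: float = 0.29) -> list[PhantomSpec]:
    """Draw a synthetic cohort: jittered labyrinths, a seeded fraction of
    which carry the lateral membranous widening."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        bulge = bool(rng.random() < lateral_bulge_fraction)
        specs.append(default_labyrinth_spec(
            seed=sub, lateral_bulge=bulge, jitter_scale=1.0, voxel_size=voxel_size))
    return specs
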