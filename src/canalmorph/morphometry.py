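"""Per-specimen morphometric quantities.

Centerline lengths (summed Euclidean segment norms), perpendicular
bony-membranous centerline distances, endolymph/bony area-ratio profiles,
inverse-area^2-weighted total-least-squares canal-plane fits (SVD), and the
angle tables between fitted planes.

Plane fits weight every centerline point by 1/area^2 of its cross-section,
which pulls the fit toward the slender portion of the canal and away from
the ampulla, approximating the functionally relevant canal plane.  The
common-crus centerline is appended to the posterior and superior point sets
(with its own area-derived weights) before fitting.  Fitted normals are
oriented by the right-hand rule around the canal's 0 % -> 100 % traversal,
so angles between oriented normals are meaningful beyond 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centerline import PERCENT_GRID, Centerline

CANAL_ORDER = ("posterior", "superior", "lateral")


@dataclass
class ProfileSet:
    """Per-percent-point quantities of one canal on the shared 101-point
    grid.  Invalid frames carry NaN and a False flag."""

    canal: str
    percent: np.ndarray = field(default_factory=lambda: PERCENT_GRID.copy())
    area_endo_mm2: np.ndarray = None
    area_peri_mm2: np.ndarray = None
    area_bony_mm2: np.ndarray = None
    distance_mm: np.ndarray = None
    valid_bony: np.ndarray = None
    valid_endo: np.ndarray = None

    @property
    def ratio(self) -> np.ndarray:
        """Endolymph / bony area per frame; NaN where either is invalid."""
        r = np.where(self.valid & (self.area_bony_mm2 > 0),
                     self.area_endo_mm2 / self.area_bony_mm2, np.nan)
        return r

    @property
    def valid(self) -> np.ndarray:
        return self.valid_bony & self.valid_endo

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "percent": self.percent,
            "area_endo_mm2": self.area_endo_mm2,
            "area_peri_mm2": self.area_peri_mm2,
            "area_bony_mm2": self.area_bony_mm2,
            "distance_mm": self.distance_mm,
            "ratio": self.ratio,
            "valid_bony": self.valid_bony,
            "valid_endo": self.valid_endo,
        })


def profile_from_frames(canal: str, frames, distances=None,
                        distance_flags=None) -> ProfileSet:
    """Assemble a :class:`ProfileSet` from extracted section frames."""
    n = len(frames)
    p = ProfileSet(canal=canal,
                   percent=np.array([f.percent for f in frames]),
                   area_endo_mm2=np.full(n, np.nan),
                   area_peri_mm2=np.full(n, np.nan),
                   area_bony_mm2=np.full(n, np.nan),
                   distance_mm=np.full(n, np.nan),
                   valid_bony=np.zeros(n, bool),
                   valid_endo=np.zeros(n, bool))
    for i, f in enumerate(frames):
        if not f.valid:
            continue
        p.area_bony_mm2[i] = f.area_mm2.get("bony", np.nan)
        p.area_endo_mm2[i] = f.area_mm2.get("endolymph", np.nan)
        p.area_peri_mm2[i] = f.area_mm2.get("perilymph", np.nan)
        p.valid_bony[i] = np.isfinite(p.area_bony_mm2[i])
        p.valid_endo[i] = (np.isfinite(p.area_endo_mm2[i])
                           and p.area_endo_mm2[i] > 0)
    if distances is not None:
        p.distance_mm = np.asarray(distances, dtype=float)
        if distance_flags is not None:
            p.distance_mm[~np.asarray(distance_flags, bool)] = np.nan
    return p


@dataclass
class FitPlane:
    """Weighted total-least-squares plane for one canal and compartment."""

    normal: np.ndarray           # unit, oriented by canal traversal
    point: np.ndarray            # weighted centroid, mm
    rms_residual: float          # weighted RMS point-plane distance, mm
    canal: str = ""
    compartment: str = ""


# ---------------------------------------------------------------------------
# scalar quantities
# ---------------------------------------------------------------------------

def centerline_length(line: Centerline | np.ndarray) -> float:
    """Sum of Euclidean distances between consecutive points (mm)."""
    pts = line.points if isinstance(line, Centerline) else np.asarray(line)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def perpendicular_distance_profile(bony: Centerline, memb: Centerline,
                                   roi_mm: float = 2.0
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Bony-to-membranous centerline distance at every bony grid point.

    At each bony point the membranous polyline is intersected with the plane
    perpendicular to the bony tangent; the distance is to the nearest
    intersection.  Where no intersection lies within ``roi_mm`` the nearest
    membranous point is used instead and the position is flagged (False).
    """
    tangents = bony.tangents()
    mpts = memb.points
    dists = np.empty(len(bony.points))
    flags = np.ones(len(bony.points), bool)
    for i, (origin, t) in enumerate(zip(bony.points, tangents)):
        s = (mpts - origin) @ t
        hits = []
        for j in range(len(s) - 1):
            if s[j] == 0.0 or s[j] * s[j + 1] < 0:
                f = 0.0 if s[j] == 0.0 else s[j] / (s[j] - s[j + 1])
                x = mpts[j] + f * (mpts[j + 1] - mpts[j])
                hits.append(np.linalg.norm(x - origin))
        if s[-1] == 0.0:
            hits.append(np.linalg.norm(mpts[-1] - origin))
        hits = [h for h in hits if h <= roi_mm]
        if hits:
            dists[i] = min(hits)
        else:
            dists[i] = np.linalg.norm(mpts - origin, axis=1).min()
            flags[i] = False
    return dists, flags


def ratio_profile(p: ProfileSet) -> np.ndarray:
    """Endolymph/bony area ratio with invalidity propagated as NaN."""
    return p.ratio


# ---------------------------------------------------------------------------
# weighted plane fits
# ---------------------------------------------------------------------------

def assemble_fit_points(canal_line: Centerline, areas: np.ndarray,
                        crus_line: Centerline | None = None,
                        crus_areas: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centerline points with weights w = 1/area^2; invalid (NaN or
    non-positive) areas drop their points.  The common crus, when given, is
    appended with its own area-derived weights.  Returns (points, weights,
    traversal polyline for normal orientation)."""
    pts = [canal_line.points]
    ars = [np.asarray(areas, dtype=float)]
    if crus_line is not None:
        if crus_areas is None:
            raise ValueError("crus areas required when appending the crus")
        pts.append(crus_line.points)
        ars.append(np.asarray(crus_areas, dtype=float))
    points = np.vstack(pts)
    area = np.concatenate(ars)
    ok = np.isfinite(area) & (area > 0)
    if not ok.any():
        raise ValueError(f"{canal_line.canal}: no valid areas to weight the fit")
    return points[ok], 1.0 / area[ok] ** 2, canal_line.points


def fit_plane_weighted(points: np.ndarray, weights: np.ndarray,
                       orientation_polyline: np.ndarray | None = None,
                       canal: str = "", compartment: str = "") -> FitPlane:
    """Weighted total-least-squares plane via SVD.

    Minimizes sum(w_i d_i^2) over planes: the centroid is the weighted mean
    and the normal is the right-singular vector with smallest singular value
    of the sqrt(w)-scaled centered point matrix.  The normal is oriented by
    the right-hand rule around the traversal polyline (default: the points
    in their given order).
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(points) < 3:
        raise ValueError("plane fit needs at least three points")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    wsum = weights.sum()
    centroid = (weights[:, None] * points).sum(axis=0) / wsum
    centered = (points - centroid) * np.sqrt(weights)[:, None]
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("points are collinear; plane is undefined")
    normal = vt[-1]
    d = (points - centroid) @ normal
    rms = float(np.sqrt((weights * d ** 2).sum() / wsum))
    if orientation_polyline is None:
        orientation_polyline = points
    tr = np.asarray(orientation_polyline, dtype=float) - centroid
    moment = np.cross(tr[:-1], tr[1:]).sum(axis=0)
    if normal @ moment < 0:
        normal = -normal
    return FitPlane(normal=normal, point=centroid, rms_residual=rms,
                    canal=canal, compartment=compartment)


def plane_angle(a: FitPlane | np.ndarray, b: FitPlane | np.ndarray) -> float:
    """Angle between oriented plane normals in degrees, range [0, 180)."""
    na = a.normal if isinstance(a, FitPlane) else np.asarray(a, dtype=float)
    nb = b.normal if isinstance(b, FitPlane) else np.asarray(b, dtype=float)
    na = na / np.linalg.norm(na)
    nb = nb / np.linalg.norm(nb)
    return float(np.rad2deg(np.arccos(np.clip(na @ nb, -1.0, 1.0))))


def bony_membranous_angle(bony: FitPlane, memb: FitPlane) -> float:
    """Angular disparity between the two compartments' planes of one canal."""
    return plane_angle(bony, memb)


def angle_table(planes: dict[tuple[str, str], FitPlane]) -> pd.DataFrame:
    """Pairwise canal-plane angles per compartment plus per-canal
    bony-vs-membranous disparity, as a tidy DataFrame."""
    rows = []
    for comp in ("bony", "membranous"):
        for i, a in enumerate(CANAL_ORDER):
            for b in CANAL_ORDER[i + 1:]:
                if (a, comp) in planes and (b, comp) in planes:
                    rows.append({"compartment": comp, "pair": f"{a}-{b}",
                                 "angle_deg": plane_angle(planes[(a, comp)],
                                                          planes[(b, comp)])})
    for c in CANAL_ORDER:
        if (c, "bony") in planes and (c, "membranous") in planes:
            rows.append({"compartment": "bony-vs-membranous", "pair": c,
                         "angle_deg": bony_membranous_angle(
                             planes[(c, "bony")], planes[(c, "membranous")])})
    return pd.DataFrame(rows)
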