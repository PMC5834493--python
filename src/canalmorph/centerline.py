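"""Centerline extraction for one canal of one compartment.

Stages mirror the semi-automated workflow used on real segmentations:
topology-preserving 3D thinning, conversion of the voxel skeleton to a graph
and reduction to a single unbranched polyline (replacing manual filament
editing with a deterministic spur/loop rule), cutting at shared end loci,
constrained Laplacian smoothing, and parameterization on a common 0-100 %
arc-length grid oriented so that 100 % is the ampullary end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._thinning import skeletonize_distance_ordered
from .volume_io import LabelVolume

PERCENT_GRID = np.linspace(0.0, 100.0, 101)


@dataclass
class SmoothingParams:
    """Constrained Laplacian smoothing: per iteration each interior point
    moves toward the midpoint of its neighbors by ``smoothing``, then back
    toward its original position by ``adherence``.  Endpoints are fixed."""

    smoothing: float = 0.8
    adherence: float = 0.05
    iterations: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.smoothing <= 1.0 and 0.0 <= self.adherence <= 1.0):
            raise ValueError("smoothing and adherence must lie in [0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")


@dataclass
class Centerline:
    """Ordered centerline on the percent grid.

    ``percent`` runs from 0 at the canal end opposing the ampulla to 100 at
    the ampullary end; ``cumulative_length`` is the running sum of Euclidean
    segment lengths (mm).
    """

    points: np.ndarray                 # (n, 3) mm
    canal: str = ""
    compartment: str = ""
    cumulative_length: np.ndarray = field(default=None)
    percent: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.cumulative_length is None:
            self.cumulative_length = cumulative_arc_length(self.points)
        total = self.cumulative_length[-1]
        if self.percent is None:
            self.percent = 100.0 * self.cumulative_length / total if total > 0 \
                else np.zeros(len(self.points))

    @property
    def length_mm(self) -> float:
        return float(self.cumulative_length[-1])

    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences (one-sided at the ends)."""
        t = np.gradient(self.points, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


def cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def skeletonize(v: LabelVolume, compartment: str = "bony") -> np.ndarray:
    """Thin a compartment to a one-voxel-wide, topology-preserving skeleton.

    The input foreground must form a single 26-connected component.  Returns
    the skeleton voxel indices as an (n, 3) integer array; the skeleton is a
    subset of the foreground.
    """
    mask = v.mask(compartment)
    if not mask.any():
        raise ValueError(f"empty {compartment} foreground")
    _, ncomp = ndimage.label(mask, structure=_STRUCT26)
    if ncomp != 1:
        sizes = np.bincount(ndimage.label(mask, structure=_STRUCT26)[0].ravel())[1:]
        raise ValueError(
            f"{compartment} foreground has {ncomp} 26-connected components "
            f"(sizes {sorted(sizes, reverse=True)[:5]}...); expected one")
    skel = skeletonize_distance_ordered(mask)
    return np.argwhere(skel)


# ---------------------------------------------------------------------------
# graph tracing and pruning
# ---------------------------------------------------------------------------

def _skeleton_graph(voxels: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(voxels)))
    tree = cKDTree(voxels.astype(float))
    pairs = tree.query_pairs(np.sqrt(3.0) * 1.001, output_type="ndarray")
    if len(pairs):
        w = np.linalg.norm(voxels[pairs[:, 0]] - voxels[pairs[:, 1]], axis=1)
        g.add_weighted_edges_from(
            (int(i), int(j), float(d)) for (i, j), d in zip(pairs, w))
    return g


def _farthest(g: nx.Graph, source: int) -> tuple[int, dict]:
    dist = nx.single_source_dijkstra_path_length(g, source, weight="weight")
    far = max(dist, key=dist.get)
    return far, dist


def _diameter_path(g: nx.Graph) -> list[int]:
    """Approximate weighted diameter path by double-sweep Dijkstra."""
    start = next(iter(g.nodes))
    u, _ = _farthest(g, start)
    v, _ = _farthest(g, u)
    return nx.dijkstra_path(g, u, v, weight="weight")


def trace_and_prune(skeleton_voxels: np.ndarray, voxel_size: float,
                    origin: np.ndarray | None = None,
                    spur_fraction: float = 0.1) -> np.ndarray:
    """Reduce a voxel skeleton to one unbranched polyline (world mm).

    The skeleton becomes a graph (voxels as nodes, 26-neighbor links weighted
    by Euclidean length).  Leaf branches shorter than ``spur_fraction`` of
    the current diameter path are deleted iteratively; the returned polyline
    is the weighted diameter path of what remains, which also resolves loops
    (the path takes one side; small parasitic cycles from thick diagonal
    connectivity are shortcut by the shortest-path weighting).
    """
    voxels = np.asarray(skeleton_voxels)
    if len(voxels) == 0:
        raise ValueError("empty skeleton")
    if origin is None:
        origin = np.zeros(3)
    if len(voxels) == 1:
        return origin + voxels.astype(float) * voxel_size
    g = _skeleton_graph(voxels)
    if g.number_of_edges() == 0:
        raise ValueError("skeleton voxels are not 26-connected")

    # iterative spur removal
    for _ in range(100):
        path = _diameter_path(g)
        diam_len = sum(g[a][b]["weight"] for a, b in zip(path, path[1:]))
        keep = set(path)
        removed = False
        junctions = {n for n in g.nodes if g.degree(n) > 2}
        leaves = [n for n in g.nodes if g.degree(n) == 1 and n not in keep]
        for leaf in leaves:
            if leaf not in g:
                continue
            branch = [leaf]
            length = 0.0
            node = leaf
            prev = None
            while True:
                nbrs = [m for m in g.neighbors(node) if m != prev]
                if node != leaf and (g.degree(node) != 2 or node in junctions):
                    branch.pop()     # keep the junction node itself
                    break
                if not nbrs:
                    break
                length += g[node][nbrs[0]]["weight"]
                prev, node = node, nbrs[0]
                branch.append(node)
            if length < spur_fraction * diam_len and not set(branch) & keep:
                g.remove_nodes_from(branch)
                removed = True
        if not removed:
            break
    if g.number_of_nodes() == 0:
        raise ValueError("skeleton empty after pruning")
    path = _diameter_path(g)
    return origin + voxels[path].astype(float) * voxel_size


# ---------------------------------------------------------------------------
# cutting, smoothing, parameterization
# ---------------------------------------------------------------------------

def _plane_crossings(points: np.ndarray, plane_point: np.ndarray,
                     plane_normal: np.ndarray) -> list[tuple[int, float]]:
    """(segment index, interpolation fraction) of every polyline crossing."""
    s = (points - plane_point) @ plane_normal
    out = []
    for i in range(len(s) - 1):
        if s[i] == 0.0:
            out.append((i, 0.0))
        elif s[i] * s[i + 1] < 0:
            out.append((i, s[i] / (s[i] - s[i + 1])))
    if len(s) and s[-1] == 0.0:
        out.append((len(s) - 2, 1.0))
    return out


def cut_at_loci(polyline: np.ndarray,
                planes: tuple[tuple[np.ndarray, np.ndarray],
                              tuple[np.ndarray, np.ndarray]],
                window_mm: float = 1.5, slack_mm: float = 0.3) -> np.ndarray:
    """Retain the sub-polyline between two cut loci.

    Each locus is a plane given as a ``(point, normal)`` pair.  Because a
    curved line can pierce an infinite plane far from the intended locus —
    or approach it tangentially without a clean sign change — the cut is
    anchored at the polyline point nearest the plane's reference point: the
    exact plane crossing is searched within ``window_mm`` of arc length
    around that anchor and the cut endpoint interpolated onto the plane.  If
    the line only grazes the plane there (no sign change), the in-window
    point closest to the plane is projected onto it, provided it lies within
    ``slack_mm``; otherwise the plane genuinely misses the line and an error
    names it.
    """
    pts = np.asarray(polyline, dtype=float)
    cum = cumulative_arc_length(pts)

    def cut_position(plane_point, plane_normal, which):
        q = np.asarray(plane_point, dtype=float)
        nrm = np.asarray(plane_normal, dtype=float)
        anchor = np.argmin(np.linalg.norm(pts - q, axis=1))
        lo = np.searchsorted(cum, cum[anchor] - window_mm)
        hi = min(np.searchsorted(cum, cum[anchor] + window_mm) + 1, len(pts))
        s = (pts[lo:hi] - q) @ nrm
        crossings = []
        for i in range(len(s) - 1):
            if s[i] == 0.0 or s[i] * s[i + 1] < 0:
                f = 0.0 if s[i] == 0.0 else s[i] / (s[i] - s[i + 1])
                x = pts[lo + i] + f * (pts[lo + i + 1] - pts[lo + i])
                crossings.append((lo + i, f, x))
        if crossings:
            i, f, x = min(crossings, key=lambda c: np.linalg.norm(c[2] - q))
            return i + f, x
        k = int(np.argmin(np.abs(s)))
        if abs(s[k]) > slack_mm:
            raise ValueError(
                f"polyline misses the {which} cut plane at {q} by "
                f"{abs(s[k]):.3f} mm (> {slack_mm} mm)")
        return lo + float(k), pts[lo + k] - s[k] * nrm   # project onto plane

    (ia, pa), (ib, pb) = (cut_position(*planes[0], "first"),
                          cut_position(*planes[1], "second"))
    if ia > ib:
        (ia, pa), (ib, pb) = (ib, pb), (ia, pa)
    inner = pts[int(np.floor(ia)) + 1: int(np.ceil(ib))]
    out = [p for p in [pa, *inner, pb]]
    return np.asarray(out)


def smooth(polyline: np.ndarray, params: SmoothingParams | None = None) -> np.ndarray:
    """Constrained Laplacian smoothing (see :class:`SmoothingParams`)."""
    if params is None:
        params = SmoothingParams()
    pts = np.asarray(polyline, dtype=float).copy()
    if len(pts) < 3 or params.iterations == 0:
        return pts
    orig = pts.copy()
    s, a = params.smoothing, params.adherence
    for _ in range(params.iterations):
        mid = 0.5 * (pts[:-2] + pts[2:])
        pts[1:-1] += s * (mid - pts[1:-1])
        pts[1:-1] += a * (orig[1:-1] - pts[1:-1])
    return pts


def parameterize(polyline: np.ndarray, ampulla_end: np.ndarray | str,
                 canal: str = "", compartment: str = "",
                 n_points: int = 101) -> Centerline:
    """Orient and resample a polyline onto the uniform percent grid.

    ``ampulla_end`` is either a world point (the polyline end nearer to it
    becomes 100 %) or the string ``"start"``/``"end"``.  Resampling is linear
    in cumulative arc length; orientation is canonical, so reversing the
    input yields the identical centerline.
    """
    pts = np.asarray(polyline, dtype=float)
    if isinstance(ampulla_end, str):
        flip = ampulla_end == "start"
    else:
        target = np.asarray(ampulla_end, dtype=float)
        flip = (np.linalg.norm(pts[0] - target)
                < np.linalg.norm(pts[-1] - target))
    if flip:
        pts = pts[::-1]
    cum = cumulative_arc_length(pts)
    total = cum[-1]
    grid = np.linspace(0.0, total, n_points)
    resampled = np.column_stack([np.interp(grid, cum, pts[:, k]) for k in range(3)])
    return Centerline(points=resampled, canal=canal, compartment=compartment,
                      cumulative_length=cumulative_arc_length(resampled))


def extract_centerline(v: LabelVolume, compartment: str,
                       cut_planes, ampulla_end,
                       params: SmoothingParams | None = None,
                       spur_fraction: float = 0.1,
                       canal: str = "") -> Centerline:
    """Full chain: skeletonize, trace/prune, cut, smooth, parameterize."""
    voxels = skeletonize(v, compartment)
    poly = trace_and_prune(voxels, v.voxel_size, v.origin, spur_fraction)
    poly = cut_at_loci(poly, cut_planes)
    poly = smooth(poly, params)
    return parameterize(poly, ampulla_end, canal=canal, compartment=compartment)
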