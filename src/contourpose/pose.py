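"""Pseudo-skeleton (body midline) extraction from a contour.

A limbless animal's pose is its body midline.  The midline is recovered
from the contour alone: 100 evenly spaced seed points on the contour define
a Voronoi tessellation whose interior vertices concentrate along the medial
axis; the vertices and the Voronoi edges connecting them (both endpoints
strictly inside the contour) form the skeleton graph, and the midline is
the minimum-length Dijkstra path between the two interior vertices closest
to the boundary — the medial axis approaches the boundary exactly at the
body ends.  The resulting point chain supports body-length, bending-angle
and curvature measurements without any anatomical markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point, Polygon

from .errors import ContractError
from .hough_ellipse import EllipseDetection
from .segmentation import Contour


@dataclass
class PseudoSkeleton:
    """Ordered midline chain from one body end to the other.

    Polarity (which end is first) is arbitrary but consistent under
    reversal; length_px is the summed segment length of the chain.
    """

    points: np.ndarray
    length_px: float
    frame_index: int = 0
    identity: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if len(self.points) < 2:
            raise ContractError("skeleton needs >= 2 points")


@dataclass
class SkeletonGraph:
    """Interior Voronoi vertices and the edges connecting them."""

    vertices: np.ndarray                    # (V, 2) float
    edges: list[tuple[int, int, float]]     # (i, j, euclidean length)

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0 or len(self.edges) == 0


def sample_contour(contour: Contour, n: int = 100) -> np.ndarray:
    """n points at equal arc-length spacing along the closed contour.

    Starts at the contour's first point; n is reduced to the contour's
    point count for very short contours.
    """
    pts = contour.points
    if len(pts) < 3:
        raise ContractError("degenerate contour")
    n = min(n, len(pts))
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(n) * total / n
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


def build_skeleton_graph(seeds: np.ndarray, contour: Contour,
                         prune_factor: float = 1.5) -> SkeletonGraph:
    """Voronoi tessellation of the seeds, restricted to the contour interior.

    Only finite Voronoi edges with BOTH endpoints strictly inside the
    contour are kept; coincident vertices are deduplicated.  Vertices whose
    clearance (distance to the nearest seed) is below ``prune_factor``
    times the seed spacing are spurious medial-axis branches induced by the
    finite boundary sampling (they hug the contour between neighbouring
    seeds) and are pruned; ``prune_factor=0`` disables pruning.
    """
    seeds = np.asarray(seeds, dtype=np.float64)
    if len(seeds) < 4:
        raise ContractError("need >= 4 seeds for a Voronoi tessellation")
    vor = Voronoi(seeds)
    poly = Polygon(contour.points)
    if not poly.is_valid:
        poly = poly.buffer(0)

    verts = vor.vertices
    import shapely
    inside = shapely.contains_xy(poly, verts[:, 0], verts[:, 1])

    if prune_factor > 0 and inside.any():
        from scipy.spatial import cKDTree
        spacing = contour.length_px / len(seeds)
        clearance, _ = cKDTree(seeds).query(verts, k=1)
        inside &= clearance > prune_factor * spacing

    # dedupe retained vertices within 1e-6 px
    index_map: dict[int, int] = {}
    new_pts: list[np.ndarray] = []
    key_map: dict[tuple[int, int], int] = {}
    for vi in np.nonzero(inside)[0]:
        p = verts[vi]
        key = (int(round(p[0] * 1e6)), int(round(p[1] * 1e6)))
        if key not in key_map:
            key_map[key] = len(new_pts)
            new_pts.append(p)
        index_map[vi] = key_map[key]

    edges: set[tuple[int, int]] = set()
    for v0, v1 in vor.ridge_vertices:
        if v0 < 0 or v1 < 0:
            continue
        if v0 in index_map and v1 in index_map:
            i, j = index_map[v0], index_map[v1]
            if i != j:
                edges.add((min(i, j), max(i, j)))
    vertices = np.array(new_pts) if new_pts else np.empty((0, 2))
    weighted = [(i, j, float(np.linalg.norm(vertices[i] - vertices[j])))
                for i, j in sorted(edges)]
    return SkeletonGraph(vertices, weighted)


def _boundary_distances(vertices: np.ndarray, contour: Contour) -> np.ndarray:
    ring = LineString(np.vstack([contour.points, contour.points[:1]]))
    return np.array([ring.distance(Point(p)) for p in vertices])


def midline_path(graph: SkeletonGraph, contour: Contour,
                 frame_index: int = 0, identity: int = 0) -> PseudoSkeleton:
    """Dijkstra midline between the skeleton graph's two end vertices.

    The body ends are where the medial axis runs out to the boundary, i.e.
    the geodesically extremal vertices of the skeleton graph.  They are
    found by the deterministic two-sweep rule: starting from the vertex
    closest to the contour, take the geodesically farthest vertex u, then
    the vertex v farthest from u; the midline is the minimum-total-length
    (Dijkstra) path u→v.  A frame whose graph is fragmented is handled on
    the largest connected component and flagged.
    """
    if graph.is_empty:
        raise ContractError("empty skeleton graph")
    g = nx.Graph()
    g.add_nodes_from(range(len(graph.vertices)))
    g.add_weighted_edges_from(graph.edges)

    dists = _boundary_distances(graph.vertices, contour)
    flagged = nx.number_connected_components(g) > 1
    comp = max(nx.connected_components(g), key=len)
    seed_v = min(comp, key=lambda i: (dists[i], i))

    lengths = nx.single_source_dijkstra_path_length(g, seed_v)
    start = min(lengths, key=lambda i: (-lengths[i], i))
    lengths = nx.single_source_dijkstra_path_length(g, start)
    end = min(lengths, key=lambda i: (-lengths[i], i))
    path = nx.dijkstra_path(g, start, end)
    weight = float(lengths[end])

    return PseudoSkeleton(graph.vertices[path], weight,
                          frame_index, identity, flagged)


def skeletonize_contour(contour: Contour, n_seeds: int = 100,
                        extend_to_contour: bool = True,
                        smooth: bool = False,
                        frame_index: int = 0,
                        identity: int = 0) -> PseudoSkeleton:
    """Full contour → pseudo-skeleton convenience chain.

    With extend_to_contour the midline is prolonged along its end tangents
    to the contour, so its length tracks the full snout-to-tail body length
    rather than stopping half a body-width short at each rounded end.
    """
    seeds = sample_contour(contour, n_seeds)
    graph = build_skeleton_graph(seeds, contour)
    skel = midline_path(graph, contour, frame_index, identity)
    pts = skel.points
    if smooth and len(pts) >= 3:
        sm = pts.copy()
        sm[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
        pts = sm
    if extend_to_contour:
        pts = _extend_ends(pts, contour)
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return PseudoSkeleton(pts, length, frame_index, identity, skel.flagged)


def _extend_ends(pts: np.ndarray, contour: Contour) -> np.ndarray:
    """Prolong each end of the chain along its tangent to the contour ring."""
    ring = LineString(np.vstack([contour.points, contour.points[:1]]))
    span = max(ring.bounds[2] - ring.bounds[0], ring.bounds[3] - ring.bounds[1])
    out = pts
    for endi, refi, prepend in ((0, 1, True), (-1, -2, False)):
        p_end, p_ref = pts[endi], pts[refi]
        direction = p_end - p_ref
        nrm = np.linalg.norm(direction)
        if nrm < 1e-9:
            continue
        direction = direction / nrm
        ray = LineString([p_end, p_end + direction * 2 * span])
        hit = ray.intersection(ring)
        if hit.is_empty:
            continue
        geoms = getattr(hit, "geoms", [hit])
        cand = min(geoms, key=lambda gm: Point(p_end).distance(gm))
        tip = np.array(cand.coords[0]) if cand.geom_type == "Point" else None
        if tip is None:
            continue
        out = (np.vstack([tip, out]) if prepend else np.vstack([out, tip]))
    return out


def resample_skeleton(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a point chain to n equidistant points along its arc length."""
    pts = np.asarray(pts, dtype=np.float64)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        raise ContractError("zero-length skeleton")
    targets = np.linspace(0, cum[-1], n)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    return np.column_stack([x, y])


def bending_angle(skel: PseudoSkeleton | np.ndarray, k_segments: int = 10) -> float:
    """Mean inter-segment angle of the resampled skeleton, in degrees.

    A perfectly straight body gives 180°; the angle decreases as the body
    bends (a right-angle elbow of two segments gives 90°).
    """
    pts = skel.points if isinstance(skel, PseudoSkeleton) else np.asarray(skel)
    if len(pts) < 3:
        raise ContractError("bending angle needs >= 3 points")
    k = min(k_segments, len(pts) - 1)
    if k < 2:
        raise ContractError("need >= 2 segments after resampling")
    rs = resample_skeleton(pts, k + 1)
    v = np.diff(rs, axis=0)
    angles = []
    for i in range(len(v) - 1):
        a, b = v[i], v[i + 1]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 or nb < 1e-12:
            continue
        cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
        angles.append(180.0 - np.degrees(np.arccos(cosang)))
    if not angles:
        raise ContractError("degenerate skeleton")
    return float(np.mean(angles))


def eccentricity(det: EllipseDetection) -> float:
    """Ellipse eccentricity e = sqrt(1 - (b/a)^2) of a detection."""
    a, b = det.semi_major, det.semi_minor
    if not (a >= b > 0):
        raise ContractError("need a >= b > 0")
    return float(np.sqrt(1.0 - (b / a) ** 2))
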