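"""Ellipse detection on edge points via the pair-sampling Hough transform.

The classical 5-D ellipse accumulator is intractable, so the detector uses
the pair-sampling reduction: every pair of edge points whose separation
falls inside the allowed major-axis range is hypothesised to span the major
axis.  The pair fixes centre, semi-major length and orientation; every other
edge point then implies a semi-minor length, and those lengths are voted
into a 1-D accumulator.  A sharp accumulator peak means many edge points are
consistent with one ellipse; the peak height, normalised by the perimeter an
ideal complete ellipse of that size would contribute, is the detection
quality q ∈ [0, 1].  Partially occluded bodies still vote coherently and are
found with proportionally lower q.

For tractability a multi-animal frame is first split into per-boundary
sub-images so each Hough run sees a single animal's edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from shapely import affinity
from shapely.geometry import Point

from .errors import ConfigurationError
from .segmentation import BinaryMask, Contour

_MAX_ANCHOR_POINTS = 400   # above this, anchor points are subsampled (seeded)
_MAX_PAIRS = 6000          # hard cap on voting pairs per sub-image
_TOP_K_BEFORE_NMS = 40


@dataclass
class DetectionParams:
    """User priors for the ellipse search.

    min_major/max_major bound the *full* major-axis length in pixels;
    n_animals is the expected animal count; quality_threshold separates
    accepted detections from the sub-threshold candidate pool kept for the
    correction stages.
    """

    min_major: float
    max_major: float
    n_animals: int = 1
    quality_threshold: float = 0.3
    max_subthreshold_kept: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.min_major < self.max_major):
            raise ConfigurationError("need 0 < min_major < max_major")
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        if not (0 < self.quality_threshold < 1):
            raise ConfigurationError("quality_threshold must be in (0,1)")

    @property
    def expected_major(self) -> float:
        """Single-animal full major-axis prior: midpoint of the range."""
        return 0.5 * (self.min_major + self.max_major)


@dataclass
class EllipseDetection:
    """One ellipse hypothesis: centre, semi-axes, orientation, quality.

    quality is the normalised accumulator peak in [0, 1], or -1 once a
    correction rule introduced or modified the detection.  rank_quality
    preserves the pre-correction quality for deterministic ranking.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # degrees in [0, 180)
    quality: float
    is_subthreshold: bool = False
    contour_index: int = -1
    rank_quality: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.semi_minor > self.semi_major:  # swap-and-rotate normalisation
            self.semi_major, self.semi_minor = self.semi_minor, self.semi_major
            self.orientation += 90.0
        self.orientation = float(self.orientation) % 180.0
        if self.rank_quality is None:
            self.rank_quality = self.quality

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    @property
    def perimeter(self) -> float:
        return ramanujan_perimeter(self.semi_major, self.semi_minor)

    def polygon(self, n: int = 32):
        """Shapely polygon approximation (for overlap computations)."""
        circ = Point(self.center).buffer(1.0, quad_segs=max(4, n // 4))
        ell = affinity.scale(circ, self.semi_major, self.semi_minor,
                             origin=self.center)
        return affinity.rotate(ell, self.orientation, origin=self.center)


@dataclass
class FrameDetections:
    """All candidates for one frame, split at the quality threshold."""

    frame_index: int
    accepted: list[EllipseDetection]
    subthreshold: list[EllipseDetection]
    problem_code: int = 0
    unresolved: bool = False


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's first approximation to the ellipse perimeter."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))


def overlap_fraction(d1: EllipseDetection, d2: EllipseDetection) -> float:
    """Intersection area over the smaller ellipse's area."""
    inter = d1.polygon().intersection(d2.polygon()).area
    return inter / max(min(d1.area, d2.area), 1e-9)


def split_subimages(mask: BinaryMask, contours: list[Contour],
                    pad: int = 5) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Crop one padded edge image per contour.

    Each crop contains only that contour's rasterised edge pixels; the
    returned offset (x0, y0) maps crop coordinates back to frame
    coordinates (frame_xy = crop_xy + offset).
    """
    h, w = mask.mask.shape
    out = []
    for c in contours:
        pts = np.round(c.points).astype(int)
        x0 = max(0, pts[:, 0].min() - pad)
        y0 = max(0, pts[:, 1].min() - pad)
        x1 = min(w - 1, pts[:, 0].max() + pad)
        y1 = min(h - 1, pts[:, 1].max() + pad)
        crop = np.zeros((y1 - y0 + 1, x1 - x0 + 1), dtype=bool)
        xs = np.clip(pts[:, 0], x0, x1) - x0
        ys = np.clip(pts[:, 1], y0, y1) - y0
        crop[ys, xs] = True
        out.append((crop, (int(x0), int(y0))))
    return out


def detect_ellipses(edge_points: np.ndarray, params: DetectionParams,
                    rng_seed: int = 0) -> list[EllipseDetection]:
    """Pair-sampling ellipse Hough transform over one edge set.

    Returns all surviving candidates sorted by descending quality, each
    flagged sub-threshold when q < params.quality_threshold.  Deterministic
    for a fixed rng_seed.
    """
    pts = np.asarray(edge_points, dtype=np.float64).reshape(-1, 2)
    n = len(pts)
    if n < 3:
        return []
    rng = np.random.default_rng(rng_seed)

    anchors = pts
    if n > _MAX_ANCHOR_POINTS:
        idx = rng.choice(n, _MAX_ANCHOR_POINTS, replace=False)
        anchors = pts[np.sort(idx)]
    m = len(anchors)

    ii, jj = np.triu_indices(m, k=1)
    p1 = anchors[ii]
    p2 = anchors[jj]
    sep = p2 - p1
    dist = np.hypot(sep[:, 0], sep[:, 1])
    keep = (dist >= params.min_major) & (dist <= params.max_major)
    p1, p2, sep, dist = p1[keep], p2[keep], sep[keep], dist[keep]
    if len(dist) == 0:
        return []
    if len(dist) > _MAX_PAIRS:
        idx = rng.choice(len(dist), _MAX_PAIRS, replace=False)
        idx.sort()
        p1, p2, sep, dist = p1[idx], p2[idx], sep[idx], dist[idx]

    centers = 0.5 * (p1 + p2)
    a = 0.5 * dist                                   # (P,)
    theta = np.degrees(np.arctan2(sep[:, 1], sep[:, 0])) % 180.0

    # Semi-minor implied by every third point, per pair.
    dx = pts[None, :, 0] - centers[:, None, 0]       # (P, N)
    dy = pts[None, :, 1] - centers[:, None, 1]
    d2 = dx * dx + dy * dy
    fx = pts[None, :, 0] - p2[:, None, 0]
    fy = pts[None, :, 1] - p2[:, None, 1]
    f2 = fx * fx + fy * fy
    a2 = (a * a)[:, None]
    d = np.sqrt(np.maximum(d2, 1e-12))
    cos_t = np.clip((a2 + d2 - f2) / (2.0 * a[:, None] * d), -1.0, 1.0)
    cos2 = cos_t * cos_t
    denom = a2 - d2 * cos2
    with np.errstate(invalid="ignore", divide="ignore"):
        b2 = a2 * d2 * (1.0 - cos2) / denom
    valid = (d2 < a2 * (1 - 1e-6)) & (denom > 1e-9) & (b2 > 0.25)
    b = np.sqrt(np.where(valid, b2, 1.0))
    valid &= b <= a[:, None] + 0.5

    n_bins = int(np.ceil(params.max_major / 2)) + 2
    bins = np.clip(np.round(b).astype(np.int64), 0, n_bins - 1)
    pair_idx = np.broadcast_to(np.arange(len(a))[:, None], bins.shape)
    flat = (pair_idx[valid] * n_bins + bins[valid])
    acc = np.bincount(flat, minlength=len(a) * n_bins).reshape(len(a), n_bins)

    smoothed = uniform_filter1d(acc.astype(np.float64), size=3, axis=1,
                                mode="constant")
    b_peak = np.argmax(smoothed, axis=1)             # first max → smaller b
    votes = 3.0 * smoothed[np.arange(len(a)), b_peak]
    ok = (b_peak >= 1) & (b_peak <= np.ceil(a).astype(int))
    if not ok.any():
        return []
    q = votes / ramanujan_perimeter(a, b_peak.astype(np.float64))
    q = np.clip(q, 0.0, 1.0)
    q[~ok] = -np.inf

    order = np.argsort(-q, kind="stable")[:_TOP_K_BEFORE_NMS]
    order = order[np.isfinite(q[order])]

    # Vote counts rank the hypotheses; the reported quality is the boundary
    # support: the fraction of the hypothesised ellipse's perimeter that has
    # an edge point within 1.5 px.  This is robust to the vote scatter that
    # raster discretisation causes near the major-axis endpoints.
    cands: list[EllipseDetection] = []
    seen: list[tuple[float, float, float, float, float]] = []
    for k in order:
        par = (centers[k, 0], centers[k, 1], a[k], float(max(b_peak[k], 1)),
               theta[k])
        if any(abs(par[0] - s[0]) < 2 and abs(par[1] - s[1]) < 2
               and abs(par[2] - s[2]) < 2 and abs(par[3] - s[3]) < 2
               and min(abs(par[4] - s[4]), 180 - abs(par[4] - s[4])) < 8
               for s in seen):
            continue
        seen.append(par)
        sq = _support_quality(pts, par)
        cands.append(EllipseDetection(
            center=(float(par[0]), float(par[1])),
            semi_major=float(par[2]),
            semi_minor=float(par[3]),
            orientation=float(par[4]),
            quality=sq,
            is_subthreshold=bool(sq < params.quality_threshold),
        ))
    cands.sort(key=lambda c: -c.quality)
    return _non_maximum_suppression(cands, 0.6)


def _support_quality(pts: np.ndarray,
                     par: tuple[float, float, float, float, float]) -> float:
    """Fraction of the ellipse perimeter covered by nearby edge points.

    The candidate boundary is sampled at ~1 px arc spacing; a sample is
    covered when an edge point lies within 1.5 px.  Coverage (rather than a
    raw count of nearby edge points) stops degenerate sliver hypotheses
    that graze a dense arc from outranking the true partially-occluded
    ellipse.
    """
    cx, cy, a, b, theta = par
    perim = ramanujan_perimeter(a, b)
    n = max(32, int(perim))
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    th = np.deg2rad(theta)
    bx = cx + a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
    by = cy + a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
    boundary = np.column_stack([bx, by])
    from scipy.spatial import cKDTree
    d, _ = cKDTree(pts).query(boundary, k=1)
    return float(np.count_nonzero(d <= 1.5) / n)


def _non_maximum_suppression(cands: list[EllipseDetection],
                             max_overlap: float) -> list[EllipseDetection]:
    """Greedy NMS: candidates sharing > max_overlap area (over the smaller
    ellipse) with an already kept, higher-quality candidate are demoted to
    the sub-threshold pool rather than discarded — the correction stages
    draw on them when the count prior is violated."""
    kept: list[EllipseDetection] = []
    demoted: list[EllipseDetection] = []
    for c in cands:
        if all(overlap_fraction(c, k) <= max_overlap for k in kept):
            kept.append(c)
        else:
            demoted.append(replace(c, is_subthreshold=True))
    return kept + demoted


def detect_frame(mask: BinaryMask, contours: list[Contour],
                 params: DetectionParams, frame_index: int = 0,
                 rng_seed: int = 0, pad: int = 5) -> FrameDetections:
    """Per-boundary Hough detection for one segmented frame."""
    all_cands: list[EllipseDetection] = []
    crops = split_subimages(mask, contours, pad)
    for ci, (crop, (x0, y0)) in enumerate(crops):
        ys, xs = np.nonzero(crop)
        pts = np.column_stack([xs + x0, ys + y0]).astype(np.float64)
        for det in detect_ellipses(pts, params, rng_seed=rng_seed + ci):
            all_cands.append(replace(det, contour_index=ci))
    all_cands.sort(key=lambda d: -d.quality)
    accepted = [d for d in all_cands if not d.is_subthreshold]
    sub = [d for d in all_cands if d.is_subthreshold]
    return FrameDetections(frame_index, accepted,
                           sub[:params.max_subthreshold_kept])
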