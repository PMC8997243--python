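"""Difference-image segmentation: frame → candidate animal boundaries.

Six-step chain per frame: (1) absolute difference against the background,
(2) normalisation to the maximum, (3) fixed-threshold binarisation, (4)
optional ROI masking, (5) disk erosion to break contact sites between
touching animals, (6) outer-boundary tracing of the surviving connected
components.  Everything downstream (ellipse voting, skeletonisation) works
on the traced boundaries.

Coordinates are (x=column, y=row), 0-based, pixel centres at integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.draw import polygon2mask

from .errors import ConfigurationError, ContractError, FormatError


@dataclass
class Roi:
    """Region of interest: axis-aligned rectangle or simple polygon.

    Vertices are (x, y) pixel coordinates.  A rectangle is given by two
    opposite corners or four corners.
    """

    shape: str  # "rectangle" | "polygon"
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.shape not in ("rectangle", "polygon"):
            raise ConfigurationError(f"unknown roi shape {self.shape!r}")
        n = len(self.vertices)
        if self.shape == "polygon" and n < 3:
            raise ConfigurationError("polygon roi needs >= 3 vertices")
        if self.shape == "rectangle" and n < 2:
            raise ConfigurationError("rectangle roi needs 2 or 4 corners")


@dataclass
class BinaryMask:
    mask: np.ndarray
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class Contour:
    """Closed outer boundary of one connected component.

    ``points`` is an ordered (N, 2) chain of (x, y) coordinates whose last
    point is adjacent to the first; ``area_px`` is the enclosed pixel count.
    """

    points: np.ndarray
    length_px: float
    area_px: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if len(self.points) < 3:
            raise ContractError("contour needs >= 3 points")


def difference_image(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Per-pixel absolute difference; static structures cancel to ~0.

    Absolute (not signed) difference so dark-on-bright and bright-on-dark
    animals share one code path.
    """
    frame = np.asarray(frame, dtype=np.float64)
    bg = np.asarray(getattr(background, "image", background), dtype=np.float64)
    if frame.shape != bg.shape:
        raise FormatError(f"shape mismatch: frame {frame.shape} vs "
                          f"background {bg.shape}")
    return np.abs(frame - bg)


def normalize_image(diff: np.ndarray) -> np.ndarray:
    """Scale so the brightest pixel is exactly 1.0; all-zero input unchanged."""
    diff = np.asarray(diff, dtype=np.float64)
    m = diff.max()
    if m <= 0:
        return diff.copy()
    return diff / m


def binarize(norm: np.ndarray, threshold: float) -> BinaryMask:
    """Strict-greater threshold; ties go to background (deterministic)."""
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"threshold must be in (0,1), got {threshold}")
    return BinaryMask(np.asarray(norm) > threshold, threshold)


def roi_mask(roi: Roi, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise an ROI into a boolean image of the given (H, W) shape."""
    h, w = shape
    v = roi.vertices
    if roi.shape == "rectangle":
        x0, y0 = v.min(axis=0)
        x1, y1 = v.max(axis=0)
        m = np.zeros((h, w), dtype=bool)
        xs = slice(max(0, int(np.ceil(x0))), min(w, int(np.floor(x1)) + 1))
        ys = slice(max(0, int(np.ceil(y0))), min(h, int(np.floor(y1)) + 1))
        m[ys, xs] = True
        return m
    # polygon2mask takes (row, col) vertices
    return polygon2mask((h, w), v[:, ::-1])


def apply_roi(mask: BinaryMask, roi: Roi) -> BinaryMask:
    """Zero every pixel outside the ROI."""
    m = roi_mask(roi, mask.mask.shape)
    if not m.any():
        raise ConfigurationError("roi lies fully outside the image")
    return BinaryMask(mask.mask & m, mask.threshold_used)


def erode_mask(mask: BinaryMask, radius: int = 1) -> BinaryMask:
    """Morphological erosion with a disk; radius 0 is the identity."""
    if radius < 0:
        raise ConfigurationError("erosion radius must be >= 0")
    if radius == 0:
        return BinaryMask(mask.mask.copy(), mask.threshold_used)
    eroded = morphology.erosion(mask.mask, morphology.disk(radius))
    return BinaryMask(eroded, mask.threshold_used)


def extract_boundaries(mask: BinaryMask, min_area: float = 0.0) -> list[Contour]:
    """Trace the closed outer boundary of every foreground component.

    Components are 8-connected; holes are ignored; results are ordered by
    descending enclosed area and filtered at ``min_area`` (px²).
    """
    m = mask.mask
    if not m.any():
        return []
    labels = measure.label(m, connectivity=2)
    out: list[Contour] = []
    for region in measure.regionprops(labels):
        if region.area < max(min_area, 3):
            continue
        comp = labels == region.label
        # marching squares on the padded component; level 0.5 traces the
        # outer rim; take the longest closed contour (outer > any hole)
        padded = np.pad(comp.astype(np.float64), 1)
        rings = measure.find_contours(padded, 0.5)
        if not rings:
            continue
        ring = max(rings, key=len)
        pts = ring[:, ::-1] - 1.0  # (row,col) -> (x,y), undo padding
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            continue
        seglen = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        out.append(Contour(pts, float(seglen.sum()), float(region.area)))
    out.sort(key=lambda c: -c.area_px)
    return out


def equivalent_ellipse(contour: Contour) -> tuple[float, float, float, float, float]:
    """Moment-equivalent ellipse of the contour's enclosed polygon.

    Returns (cx, cy, semi_major, semi_minor, theta_deg) from the polygon's
    area moments (Green's theorem); sub-pixel stable, unlike accumulator
    peaks that live on a half-pixel grid.
    """
    p = np.vstack([contour.points, contour.points[:1]])
    x0, y0 = p[:-1, 0], p[:-1, 1]
    x1, y1 = p[1:, 0], p[1:, 1]
    cross = x0 * y1 - x1 * y0
    area = 0.5 * cross.sum()
    if abs(area) < 1e-9:
        raise ContractError("degenerate contour (zero area)")
    cx = ((x0 + x1) * cross).sum() / (6 * area)
    cy = ((y0 + y1) * cross).sum() / (6 * area)
    ix2 = ((x0 ** 2 + x0 * x1 + x1 ** 2) * cross).sum() / (12 * area) - cx ** 2
    iy2 = ((y0 ** 2 + y0 * y1 + y1 ** 2) * cross).sum() / (12 * area) - cy ** 2
    ixy = ((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() \
        / (24 * area) - cx * cy
    cov = np.array([[ix2, ixy], [ixy, iy2]])
    evals, evecs = np.linalg.eigh(cov)
    a = 2.0 * np.sqrt(max(evals[1], 1e-12))
    b = 2.0 * np.sqrt(max(evals[0], 1e-12))
    theta = np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])) % 180.0
    return float(cx), float(cy), float(a), float(b), float(theta)


def segment_frame(frame: np.ndarray, background, threshold: float,
                  roi: Roi | None = None, erosion_radius: int = 1,
                  min_area: float = 0.0) -> tuple[BinaryMask, list[Contour]]:
    """Run the full six-step chain on one frame."""
    diff = difference_image(frame, background)
    norm = normalize_image(diff)
    mask = binarize(norm, threshold)
    if roi is not None:
        mask = apply_roi(mask, roi)
    mask = erode_mask(mask, erosion_radius)
    return mask, extract_boundaries(mask, min_area)
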