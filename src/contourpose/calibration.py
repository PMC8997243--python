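"""Pixel-to-metric calibration from a marked object of known size.

A line, rectangle or circle of known physical size marked in a frame fixes
an isotropic scale (meters per pixel).  Rectangle and circle marks also move
the world origin (designated corner / circle centre); a line mark only
changes units and keeps the pixel origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError


@dataclass
class Calibration:
    kind: str                       # "line" | "rectangle" | "circle"
    scale: float                    # meters per pixel
    origin_px: tuple[float, float] = (0.0, 0.0)
    flip_y: bool = False            # world +y up instead of image-down
    side_disagreement: float = 0.0  # relative spread of rectangle estimates

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")


def build_calibration(kind: str, marks, true_size,
                      origin_corner: int = 0, flip_y: bool = False) -> Calibration:
    """Derive scale and origin from marked pixel coordinates.

    kind="line": marks are 2 points, true_size the line length in m; the
    pixel origin is kept.  kind="rectangle": marks are 4 corners in order,
    true_size = (width_m, height_m); scale is the mean of the two
    independent side estimates and origin the designated corner.
    kind="circle": marks are centre + one rim point (or >= 3 rim points),
    true_size the diameter in m; origin is the centre.
    """
    marks = np.asarray(marks, dtype=np.float64).reshape(-1, 2)
    if kind == "line":
        if len(marks) != 2:
            raise ConfigurationError("line calibration needs exactly 2 points")
        d = np.linalg.norm(marks[1] - marks[0])
        if d < 1e-9:
            raise ConfigurationError("coincident line marks")
        return Calibration("line", float(true_size) / d, (0.0, 0.0), flip_y)

    if kind == "rectangle":
        if len(marks) != 4:
            raise ConfigurationError("rectangle calibration needs 4 corners")
        w_m, h_m = true_size
        sides = np.linalg.norm(np.diff(np.vstack([marks, marks[:1]]), axis=0),
                               axis=1)
        if sides.min() < 1e-9:
            raise ConfigurationError("coincident rectangle corners")
        # opposite sides averaged: sides 0,2 span the width, 1,3 the height
        s_w = w_m / (0.5 * (sides[0] + sides[2]))
        s_h = h_m / (0.5 * (sides[1] + sides[3]))
        scale = 0.5 * (s_w + s_h)
        disagreement = abs(s_w - s_h) / scale
        if disagreement > 0.10:
            warnings.warn(
                f"rectangle side scale estimates disagree by "
                f"{disagreement:.1%}; check marks/true sizes", stacklevel=2)
        origin = tuple(marks[origin_corner % 4])
        return Calibration("rectangle", float(scale), origin, flip_y,
                           float(disagreement))

    if kind == "circle":
        if len(marks) == 2:           # centre + rim point
            center = marks[0]
            r = np.linalg.norm(marks[1] - marks[0])
        elif len(marks) >= 3:         # rim points: least-squares circle
            center, r = _fit_circle(marks)
        else:
            raise ConfigurationError("circle calibration needs >= 2 points")
        if r < 1e-9:
            raise ConfigurationError("coincident circle marks")
        scale = float(true_size) / (2.0 * r)
        return Calibration("circle", scale, (float(center[0]), float(center[1])),
                           flip_y)

    raise ConfigurationError(f"unknown calibration kind {kind!r}")


def _fit_circle(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares circle through >= 3 points."""
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    r = float(np.sqrt(sol[2] + center @ center))
    return center, r


def to_world(points_px, cal: Calibration) -> np.ndarray:
    """Map pixel coordinates to world meters: (px - origin) * scale."""
    pts = np.asarray(points_px, dtype=np.float64)
    out = (pts - np.asarray(cal.origin_px)) * cal.scale
    if cal.flip_y:
        out = out * np.array([1.0, -1.0])
    return out


def to_pixels(points_m, cal: Calibration) -> np.ndarray:
    """Inverse of to_world."""
    pts = np.asarray(points_m, dtype=np.float64)
    if cal.flip_y:
        pts = pts * np.array([1.0, -1.0])
    return pts / cal.scale + np.asarray(cal.origin_px)


def save_calibration(cal: Calibration, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "kind": cal.kind,
        "scale_m_per_px": float(cal.scale),
        "origin_px": [float(cal.origin_px[0]), float(cal.origin_px[1])],
        "flip_y": bool(cal.flip_y),
    }))


def load_calibration(path: str | Path) -> Calibration:
    d = yaml.safe_load(Path(path).read_text())
    return Calibration(d["kind"], d["scale_m_per_px"],
                       tuple(d.get("origin_px", (0.0, 0.0))),
                       bool(d.get("flip_y", False)))
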