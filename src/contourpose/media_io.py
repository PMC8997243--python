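"""Frame-sequence loading and background estimation.

Videos, image sequences, and multi-page stacks are normalised into a single
in-memory representation: a ``FrameSequence`` of grayscale frames scaled to
[0, 1].  An animal-free background image is obtained by temporal projection
(min/max/mean per pixel): a dark animal on a bright background vanishes under
a max projection, a bright animal on a dark background under a min
projection, and a mean projection trades residual animal traces for
robustness against mild lighting drift.
"""

from __future__ import annotations

import glob as _glob
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ConfigurationError, FormatError, InputError

_VIDEO_SUFFIXES = {".avi", ".mp4", ".mov", ".mkv", ".webm"}
_STACK_SUFFIXES = {".tif", ".tiff"}


@dataclass
class FrameSequence:
    """Time-indexed grayscale frames with an acquisition rate.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Intensities in [0, 1].
    fps : float
        Acquisition rate in Hz.
    source_path : str
        Provenance string (file, glob, or ``"synthetic:…"``).
    """

    frames: np.ndarray
    fps: float
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("frames must be a (T, H, W) array with T >= 1")
        if not (self.fps > 0):
            raise ConfigurationError(f"fps must be positive, got {self.fps}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise FormatError(f"intensities outside [0,1]: [{lo}, {hi}]")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class BackgroundImage:
    """Animal-free background estimate from a temporal projection."""

    image: np.ndarray
    mode: str
    n_frames_used: int
    source_path: str = ""


def _natural_key(path: str) -> list:
    """Sort key splitting digit runs so frame_2 < frame_10."""
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", Path(path).name)]


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an image array to float64 grayscale in [0, 1].

    Color images use the Rec. 601 luminance weighting; integer types are
    divided by their type maximum so thresholds are bit-depth independent.
    """
    arr = np.asarray(img)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        arr = arr.astype(np.float64)
        arr = arr @ np.array([0.299, 0.587, 0.114])
        if np.issubdtype(np.asarray(img).dtype, np.integer):
            arr /= np.iinfo(np.asarray(img).dtype).max
        return np.clip(arr, 0.0, 1.0)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _read_one(path: Path) -> np.ndarray:
    try:
        return iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise InputError(f"cannot read image {path}: {exc}") from exc


def open_source(path: str | Path, fps_override: float | None = None) -> FrameSequence:
    """Load a video container, an image sequence/glob, or a TIFF stack.

    Parameters
    ----------
    path : str or Path
        A video file, a single image, a multi-page TIFF, a directory of
        images, or a glob pattern.  Image files are ordered by natural sort
        of their filenames.
    fps_override : float, optional
        Acquisition rate in Hz.  Required for image sequences and stacks
        (which carry no rate metadata); overrides container metadata for
        videos.
    """
    spath = str(path)
    p = Path(spath)

    if any(ch in spath for ch in "*?[") or p.is_dir():
        pattern = str(p / "*") if p.is_dir() else spath
        image_suffixes = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
        files = sorted(_glob.glob(pattern), key=_natural_key)
        files = [f for f in files if Path(f).is_file()
                 and Path(f).suffix.lower() in image_suffixes]
        if not files:
            raise InputError(f"no files match {spath!r}")
        return _from_image_files(files, fps_override, spath)

    if not p.exists():
        raise InputError(f"path does not exist: {spath}")

    suffix = p.suffix.lower()
    if suffix in _VIDEO_SUFFIXES:
        return _from_video(p, fps_override)
    if suffix in _STACK_SUFFIXES:
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        if fps_override is None:
            raise ConfigurationError(
                "fps_override is required for image stacks (no rate metadata)")
        frames = np.stack([to_grayscale(fr) for fr in arr])
        return FrameSequence(frames, fps_override, spath)
    # single image
    if fps_override is None:
        fps_override = 1.0  # degenerate single-frame sequence
    return FrameSequence(to_grayscale(_read_one(p))[None], fps_override, spath)


def _from_image_files(files: list[str], fps: float | None, src: str) -> FrameSequence:
    if fps is None:
        raise ConfigurationError(
            "fps_override is required for image sequences (no rate metadata)")
    frames = []
    shape = None
    for f in files:
        g = to_grayscale(_read_one(Path(f)))
        if shape is None:
            shape = g.shape
        elif g.shape != shape:
            raise FormatError(
                f"mixed frame sizes in sequence: {shape} vs {g.shape} ({f})")
        frames.append(g)
    return FrameSequence(np.stack(frames), fps, src)


def _from_video(p: Path, fps_override: float | None) -> FrameSequence:
    try:
        meta = iio.immeta(p, plugin="pyav") if fps_override is None else {}
    except Exception:
        meta = {}
    fps = fps_override or meta.get("fps")
    try:
        arr = iio.imread(p)
    except Exception as exc:
        raise InputError(f"cannot decode video {p}: {exc}") from exc
    if fps is None:
        raise ConfigurationError(f"no fps metadata in {p}; pass fps_override")
    frames = np.stack([to_grayscale(fr) for fr in arr])
    return FrameSequence(frames, float(fps), str(p))


def compute_background(seq: FrameSequence, mode: str = "max",
                       stride: int = 1) -> BackgroundImage:
    """Temporal projection of a frame sequence.

    ``mode='max'`` removes a dark animal on a bright background, ``'min'`` a
    bright animal on a dark background, ``'mean'`` averages out mild lighting
    drift.  ``stride`` projects every k-th frame only (memory/time bound).
    """
    if mode not in ("min", "max", "mean"):
        raise ConfigurationError(f"unknown projection mode {mode!r}")
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    sub = seq.frames[::stride]
    op = {"min": np.min, "max": np.max, "mean": np.mean}[mode]
    img = op(sub, axis=0)
    return BackgroundImage(img, mode, sub.shape[0], seq.source_path)


def save_background(bg: BackgroundImage, path: str | Path) -> None:
    """Write the background as 16-bit PNG/TIFF plus a JSON sidecar."""
    p = Path(path)
    arr16 = np.clip(np.round(bg.image * 65535), 0, 65535).astype(np.uint16)
    if p.suffix.lower() in _STACK_SUFFIXES:
        tifffile.imwrite(p, arr16)
    else:
        iio.imwrite(p, arr16)
    sidecar = p.with_suffix(p.suffix + ".json")
    sidecar.write_text(json.dumps({
        "mode": bg.mode,
        "n_frames_used": bg.n_frames_used,
        "source_path": bg.source_path,
    }, indent=2))


def load_background(path: str | Path) -> BackgroundImage:
    p = Path(path)
    img = to_grayscale(iio.imread(p) if p.suffix.lower() not in _STACK_SUFFIXES
                       else tifffile.imread(p))
    sidecar = p.with_suffix(p.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return BackgroundImage(img, meta.get("mode", "unknown"),
                           int(meta.get("n_frames_used", 0)),
                           meta.get("source_path", ""))
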