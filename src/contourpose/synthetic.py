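"""Ground-truth-bearing synthetic scenes for every pipeline stage.

Three generators render grayscale videos of dark limbless bodies on bright
backgrounds, together with the exact programmed truth (midlines, centres,
headings, body lengths, event schedules):

* ``make_crawler`` — a crawling larva: a capsule whose axial length
  oscillates sinusoidally (peristalsis) with programmable relative
  amplitude A* while it advances; scheduled turns bend the body into a C.
* ``make_swimmer`` — a fish-like tapered body moving intermittently:
  thrust events inject forward speed that decays exponentially (glide),
  saccades inject yaw-velocity pulses, and an s-shaped undulation
  travels down the midline.
* ``make_multianimal`` — several bodies with scheduled occlusion
  (crossing) and chaining (end-to-end alignment) episodes.

Two background regimes mimic the common recording situations: ``uniform``
(high-contrast, contact-imaging-like: flat field, contrast 0.7, noise
σ=0.005) and ``gradient`` (backlit-tank-like: 20 % linear illumination
ramp, contrast 0.3, noise σ=0.02).  Identical seeds give bit-identical
frames and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .media_io import FrameSequence

#: background regimes: (base level, relative illumination ramp, contrast,
#: pixel noise sigma)
REGIMES = {
    "uniform": dict(base=0.85, gradient=0.0, contrast=0.7, noise_sigma=0.005),
    "gradient": dict(base=0.80, gradient=0.2, contrast=0.3, noise_sigma=0.02),
}


@dataclass
class SyntheticTruth:
    """Programmed ground truth aligned 1:1 with the rendered frames."""

    midlines: list            # [frame][animal] -> (m, 2) array
    centers: np.ndarray       # (T, n_animals, 2)
    headings: np.ndarray      # (T, n_animals) directed, degrees
    body_lengths: np.ndarray  # (T, n_animals) px (midline arc length)
    schedules: dict = field(default_factory=dict)
    contraction_pct: float = 0.0
    regime: str = "uniform"
    seed: int = 0
    fps: float = 30.0
    background: np.ndarray | None = None  # true empty field

    @property
    def n_animals(self) -> int:
        return self.centers.shape[1]


def _background(shape: tuple[int, int], regime: str) -> np.ndarray:
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown background regime {regime!r}")
    p = REGIMES[regime]
    h, w = shape
    ramp = np.linspace(-0.5, 0.5, w) * p["gradient"]
    return np.clip(p["base"] * (1.0 + ramp)[None, :].repeat(h, axis=0), 0, 1)


def _render(midlines_per_frame, halfwidths_per_frame, shape, regime, seed,
            noise_sigma=None):
    """Render frames: dark anti-aliased bodies over the regime background."""
    p = REGIMES[regime]
    sigma = p["noise_sigma"] if noise_sigma is None else float(noise_sigma)
    bg = _background(shape, regime)
    rng = np.random.default_rng(seed)
    h, w = shape
    frames = np.empty((len(midlines_per_frame), h, w))
    for t, animals in enumerate(midlines_per_frame):
        img = bg.copy()
        for pts, halfw in zip(animals, halfwidths_per_frame[t]):
            hw = np.broadcast_to(np.atleast_1d(halfw), (len(pts),))
            x0 = max(0, int(pts[:, 0].min() - hw.max() - 2))
            x1 = min(w, int(pts[:, 0].max() + hw.max() + 3))
            y0 = max(0, int(pts[:, 1].min() - hw.max() - 2))
            y1 = min(h, int(pts[:, 1].max() + hw.max() + 3))
            if x1 <= x0 or y1 <= y0:
                continue
            gx, gy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
            grid = np.column_stack([gx.ravel(), gy.ravel()])
            dist, idx = cKDTree(pts).query(grid, k=1)
            alpha = np.clip(hw[idx] + 0.5 - dist, 0.0, 1.0)
            alpha = alpha.reshape(y1 - y0, x1 - x0)
            body = np.clip(img[y0:y1, x0:x1] - p["contrast"], 0.02, 1)
            img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - alpha) + body * alpha
        img += rng.normal(0.0, sigma, size=img.shape)
        frames[t] = np.clip(img, 0.0, 1.0)
    return frames, bg


def _taper_halfwidth(n: int, width_px: float, taper_frac: float = 0.25
                     ) -> np.ndarray:
    """Capsule half-width profile tapering to width/4 at both body ends.

    Limbless crawlers narrow toward head and tail; the taper also makes the
    medial axis approach the boundary at the tips, which is what
    contour-based end detection relies on.
    """
    u = np.linspace(0, 1, n)
    g = np.clip(1 - u / taper_frac, 0, 1) + np.clip(1 - (1 - u) / taper_frac,
                                                    0, 1)
    return width_px / 2.0 * (1.0 - 0.5 * g)


def _arc_midline(center, heading_deg, length, curvature, n=120):
    """Constant-curvature arc of given length, centroid at ``center``,
    mean tangent along ``heading_deg``."""
    s = np.linspace(-length / 2, length / 2, n)
    phi = np.radians(heading_deg)
    psi = phi + curvature * s
    ds = s[1] - s[0]
    x = np.cumsum(np.cos(psi)) * ds
    y = np.cumsum(np.sin(psi)) * ds
    pts = np.column_stack([x, y])
    return pts - pts.mean(axis=0) + np.asarray(center)


def _fit_to_frame(all_points: np.ndarray, shape, margin: float):
    """Translation placing the whole space-time track centred in frame."""
    h, w = shape
    lo = all_points.min(axis=0)
    hi = all_points.max(axis=0)
    size = hi - lo
    if size[0] + 2 * margin > w or size[1] + 2 * margin > h:
        raise ConfigurationError(
            f"trajectory extent {size} does not fit a {w}x{h} frame")
    return np.array([w, h]) / 2 - (lo + hi) / 2


def _turn_rate(t: np.ndarray, turn_schedule) -> np.ndarray:
    """Instantaneous heading rate (deg/s) from (t0, t1, delta_deg) windows,
    each with a raised-cosine profile integrating to delta."""
    rate = np.zeros_like(t)
    for t0, t1, delta in turn_schedule or []:
        dur = t1 - t0
        if dur <= 0:
            raise ConfigurationError("turn window must have t1 > t0")
        inwin = (t >= t0) & (t < t1)
        u = (t[inwin] - t0) / dur
        rate[inwin] += delta / dur * (1 - np.cos(2 * np.pi * u))
    return rate


def make_crawler(body_length_px: float = 60.0, amplitude_pct: float = 15.0,
                 period_s: float = 1.0, turn_schedule=None,
                 speed_px_s: float = 20.0, width_px: float = 12.0,
                 frame_shape: tuple[int, int] = (224, 224),
                 regime: str = "uniform", T: int = 200, fps: float = 34.0,
                 noise_sigma: float | None = None,
                 seed: int = 0) -> tuple[FrameSequence, SyntheticTruth]:
    """Crawling-larva scene with programmed peristalsis and turns.

    The axial length oscillates between L_max = body_length_px and
    L_min = L_max * (1 - A*/100), so the programmed contraction amplitude
    is exactly ``amplitude_pct``.  Turns are (t0_s, t1_s, delta_deg)
    windows during which the heading rotates and the body bends into a C.
    """
    if not (0 <= amplitude_pct < 60):
        raise ConfigurationError("amplitude_pct must be in [0, 60)")
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown regime {regime!r}")
    if T < 1 or fps <= 0 or body_length_px <= 0:
        raise ConfigurationError("invalid T/fps/body length")
    rng = np.random.default_rng(seed)
    t = np.arange(T) / fps
    r = amplitude_pct / 100.0
    # body_length_px is the tip-to-tail extent; the rendered capsule's
    # rounded caps add width_px/2 at each end, so the backbone is shorter
    lengths = body_length_px * (1 - r * (0.5 - 0.5 * np.cos(2 * np.pi * t / period_s)))
    if lengths.min() <= width_px + 4:
        raise ConfigurationError("body length must exceed body width")

    phi0 = rng.uniform(0, 360)
    rate = _turn_rate(t, turn_schedule)
    heading = phi0 + np.concatenate([[0], np.cumsum(
        0.5 * (rate[1:] + rate[:-1]))]) / fps
    # body bend: C-curvature proportional to the instantaneous turn rate
    peak_rate = np.abs(rate).max() if np.abs(rate).max() > 0 else 1.0
    curvature = (rate / peak_rate) * (np.pi / 2) / body_length_px \
        if turn_schedule else np.zeros(T)

    hr = np.radians(heading)
    step = speed_px_s / fps
    pos = np.cumsum(np.column_stack([np.cos(hr), np.sin(hr)]) * step, axis=0)

    # tapered capsule: tip caps have radius width/4, so the backbone spans
    # tip-to-tail length minus width/2
    midlines = [[_arc_midline(pos[i], heading[i], lengths[i] - width_px / 2,
                              curvature[i])]
                for i in range(T)]
    shift = _fit_to_frame(np.vstack([m[0] for m in midlines]),
                          frame_shape, margin=width_px + 6)
    for m in midlines:
        m[0] = m[0] + shift
    pos = pos + shift

    hw = _taper_halfwidth(120, width_px)
    halfw = [[hw] for _ in range(T)]
    frames, bg = _render(midlines, halfw, frame_shape, regime, seed,
                         noise_sigma)
    seq = FrameSequence(frames, fps, f"synthetic:crawler:seed={seed}")
    # true tip-to-tail length: backbone arc length + the two tip-cap radii
    true_len = np.array([[float(np.linalg.norm(np.diff(m[0], axis=0),
                                               axis=1).sum()) + width_px / 2]
                         for m in midlines])
    centers = np.array([[m[0].mean(axis=0)] for m in midlines])
    truth = SyntheticTruth(
        midlines=midlines,
        centers=centers,
        headings=heading[:, None] % 360.0,
        body_lengths=true_len,
        schedules={"turns": list(turn_schedule or [])},
        contraction_pct=amplitude_pct,
        regime=regime, seed=seed, fps=fps, background=bg)
    return seq, truth


def _fish_halfwidth(n: int, width_px: float) -> np.ndarray:
    """Tapered width profile: rounded head, widest at ~1/3, thin tail."""
    u = np.linspace(0, 1, n)
    prof = np.sin(np.pi * u ** 0.7) ** 0.8
    return width_px / 2.0 * np.clip(prof, 0.10, 1.0)


def make_swimmer(body_length_px: float = 60.0, width_px: float = 14.0,
                 undulation_amp_px: float = 3.0, undulation_freq_hz: float = 4.0,
                 saccade_schedule=None, thrust_schedule=None,
                 glide_tau_s: float = 0.35, baseline_speed_px_s: float = 0.0,
                 frame_shape: tuple[int, int] = (220, 220),
                 regime: str = "uniform", T: int = 400, fps: float = 200.0,
                 noise_sigma: float | None = None,
                 seed: int = 0) -> tuple[FrameSequence, SyntheticTruth]:
    """Intermittent burst-glide swimmer with programmed saccades/thrusts.

    thrust_schedule: (t_s, peak_px_s) — forward speed jumps by ``peak`` and
    decays with time constant glide_tau_s.  saccade_schedule:
    (t_s, peak_deg_s) — Gaussian yaw-velocity pulses (σ = 40 ms).
    """
    t = np.arange(T) / fps
    for sched in (saccade_schedule or []) + (thrust_schedule or []):
        if not (0 <= sched[0] < T / fps):
            raise ConfigurationError(f"scheduled event at {sched[0]} s "
                                     "outside the video duration")
    speed = np.full(T, float(baseline_speed_px_s))
    for t_k, peak in thrust_schedule or []:
        on = t >= t_k
        speed[on] += peak * np.exp(-(t[on] - t_k) / glide_tau_s)
    yaw_rate = np.zeros(T)
    sig = 0.040
    for t_k, peak in saccade_schedule or []:
        yaw_rate += peak * np.exp(-0.5 * ((t - t_k) / sig) ** 2)

    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0, 360)
    heading = phi0 + np.concatenate([[0], np.cumsum(
        0.5 * (yaw_rate[1:] + yaw_rate[:-1]))]) / fps
    hr = np.radians(heading)
    pos = np.cumsum(np.column_stack([np.cos(hr), np.sin(hr)]) * (speed / fps)[:, None],
                    axis=0)

    m = 120
    u = np.linspace(0, 1, m)
    taper = 0.15 + 0.85 * u  # undulation grows toward the tail
    # fish undulate while propelling themselves, not while gliding: scale
    # the undulation amplitude by normalised locomotor activity
    peak_speed = max(speed.max(), 1e-9)
    if thrust_schedule or baseline_speed_px_s:
        activity = np.clip(speed / peak_speed, 0.05, 1.0)
        # ramp the undulation in and out over ~0.15 s instead of switching
        # abruptly at a thrust onset
        k = max(3, int(0.15 * fps) | 1)
        win = np.hanning(k)
        activity = np.convolve(activity, win / win.sum(), mode="same")
    else:
        activity = np.ones(T)
    midlines = []
    for i in range(T):
        s = (u - 0.5) * body_length_px
        lat = undulation_amp_px * activity[i] * taper * np.sin(
            2 * np.pi * (u - undulation_freq_hz * t[i]))
        # saccade bend: smooth C proportional to yaw rate
        bend = np.radians(yaw_rate[i]) / fps * body_length_px * 1.5
        lat = lat + bend * (u - 0.5) ** 2 * 4
        c, sn = np.cos(hr[i]), np.sin(hr[i])
        axis = np.column_stack([-s * c, -s * sn])  # head at s=-L/2 forward
        normal = np.column_stack([-sn * lat, c * lat])
        pts = pos[i] + axis + normal
        midlines.append([pts - pts.mean(axis=0) + pos[i]])

    shift = _fit_to_frame(np.vstack([mm[0] for mm in midlines]), frame_shape,
                          margin=width_px + 6)
    for mm in midlines:
        mm[0] = mm[0] + shift
    pos = pos + shift

    hw = _fish_halfwidth(m, width_px)
    halfw = [[hw] for _ in range(T)]
    frames, bg = _render(midlines, halfw, frame_shape, regime, seed,
                         noise_sigma)
    seq = FrameSequence(frames, fps, f"synthetic:swimmer:seed={seed}")
    true_len = np.array([[float(np.linalg.norm(np.diff(mm[0], axis=0),
                                               axis=1).sum())]
                         for mm in midlines])
    centers = np.array([[mm[0].mean(axis=0)] for mm in midlines])
    truth = SyntheticTruth(
        midlines=midlines, centers=centers,
        headings=(heading[:, None] + 180.0) % 360.0,  # motion is along -axis
        body_lengths=true_len,
        schedules={"saccades": list(saccade_schedule or []),
                   "thrusts": list(thrust_schedule or []),
                   "speed_px_s": speed, "yaw_rate_deg_s": yaw_rate},
        regime=regime, seed=seed, fps=fps, background=bg)
    return seq, truth


def make_multianimal(n_animals: int = 2, body_length_px: float = 50.0,
                     width_px: float = 11.0, speed_px_s: float = 25.0,
                     chaining_windows=None, occlusion_windows=None,
                     frame_shape: tuple[int, int] = (240, 240),
                     regime: str = "uniform", T: int = 120, fps: float = 34.0,
                     noise_sigma: float | None = None,
                     seed: int = 0) -> tuple[FrameSequence, SyntheticTruth]:
    """Multi-animal scene with scheduled chaining and occlusion episodes.

    Outside scheduled windows the animals follow parallel, well-separated
    straight paths.  During a chaining window (t0_s, t1_s) two animals snap
    end-to-end along a common axis (the "figure-eight" mis-detection case);
    during an occlusion window their paths cross at the scene centre.
    """
    if n_animals < 2:
        raise ConfigurationError("need >= 2 animals")
    h, w = frame_shape
    t = np.arange(T) / fps
    margin = body_length_px / 2 + width_px + 8
    lane_gap = (h - 2 * margin) / (n_animals - 1) if n_animals > 1 else 0
    path_len = speed_px_s * T / fps
    x_start = max(margin, (w - path_len) / 2)

    centers = np.zeros((T, n_animals, 2))
    headings = np.zeros((T, n_animals))
    for k in range(n_animals):
        y_k = margin + k * lane_gap
        centers[:, k, 0] = x_start + speed_px_s * t
        centers[:, k, 1] = y_k
        headings[:, k] = 0.0

    for (t0, t1) in chaining_windows or []:
        inwin = (t >= t0) & (t < t1)
        # animals 0 and 1 align end-to-end through the scene centre
        axis_y = h / 2
        cx = centers[inwin, 0, 0]
        centers[inwin, 0, 1] = axis_y
        centers[inwin, 1, 0] = cx + body_length_px * 0.96
        centers[inwin, 1, 1] = axis_y
        headings[inwin, 0] = 0.0
        headings[inwin, 1] = 0.0
    for (t0, t1) in occlusion_windows or []:
        inwin = (t >= t0) & (t < t1)
        if not inwin.any():
            continue
        # animal 1 sweeps orthogonally across animal 0's path
        tw = (t[inwin] - t0) / max(t1 - t0, 1e-9)
        centers[inwin, 1, 0] = centers[inwin, 0, 0]
        centers[inwin, 1, 1] = centers[inwin, 0, 1] + \
            (0.5 - tw) * 2 * body_length_px
        headings[inwin, 1] = 90.0

    midlines = []
    for i in range(T):
        midlines.append([
            _arc_midline(centers[i, k], headings[i, k],
                         body_length_px - width_px / 2, 0.0)
            for k in range(n_animals)])
    hw = _taper_halfwidth(120, width_px)
    halfw = [[hw] * n_animals for _ in range(T)]
    frames, bg = _render(midlines, halfw, frame_shape, regime, seed,
                         noise_sigma)
    seq = FrameSequence(frames, fps, f"synthetic:multi:seed={seed}")
    true_len = np.array([[float(np.linalg.norm(np.diff(mm, axis=0),
                                               axis=1).sum()) + width_px / 2
                          for mm in midlines[i]] for i in range(T)])
    truth = SyntheticTruth(
        midlines=midlines, centers=centers, headings=headings % 360.0,
        body_lengths=true_len,
        schedules={"chaining": list(chaining_windows or []),
                   "occlusion": list(occlusion_windows or [])},
        regime=regime, seed=seed, fps=fps, background=bg)
    return seq, truth
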