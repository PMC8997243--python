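"""Locomotion statistics from calibrated tracks and pseudo-skeletons.

Covers the quantities used to characterise undulatory locomotion:

* peristaltic contraction amplitude A = (1 - L_min / L_max) x 100 %,
  from the per-frame midline (Dijkstra path) length;
* the signed curvature index c that separates turns (body bent to one
  side) from s-shaped postures, computed from integrals of the rotated
  skeleton's lateral coordinates;
* ego-centric velocities: thrust (along the heading), slip (perpendicular)
  and yaw velocity;
* event detection (saccades as yaw-velocity peaks, thrust strokes as
  forward-speed peaks), event-triggered averages and event frequencies;
* a permutation test on the difference of group medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigurationError, ContractError
from .pose import PseudoSkeleton, resample_skeleton

#: default saccade threshold on |yaw velocity|, deg/s
SACCADE_THRESHOLD_DEG_S = 200.0
#: default thrust-stroke threshold on forward speed, m/s (10 cm/s)
THRUST_THRESHOLD_M_S = 0.10


def smooth_series(x, window: int) -> np.ndarray:
    """Centered moving average (valid region only).

    Extremum-based statistics such as the contraction amplitude are very
    sensitive to single-frame tracking noise; a window much shorter than
    the oscillation of interest (e.g. 5 frames ≈ 0.15 s against a ~1 s
    peristaltic period) suppresses the noise with negligible attenuation
    of the signal.
    """
    x = np.asarray(x, dtype=np.float64)
    if window <= 1:
        return x.copy()
    if window > x.size:
        raise ContractError("smoothing window longer than the series")
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="valid")


def contraction_amplitude(lengths) -> float:
    """Peristaltic contraction amplitude A = (1 - min/max) x 100 %."""
    arr = np.asarray(lengths, dtype=np.float64)
    if arr.size < 2:
        raise ContractError("need >= 2 body-length samples")
    if np.any(arr <= 0):
        raise ContractError("body lengths must be positive")
    return float((1.0 - arr.min() / arr.max()) * 100.0)


def rotate_to_axis(pts: np.ndarray) -> np.ndarray:
    """Rotate/translate a chain so the end-to-end axis is the x-axis.

    The start point maps to the origin and both endpoints end up with zero
    lateral (y) coordinate; the returned array's y column is the lateral
    deviation of the body from its end-to-end chord.
    """
    pts = np.asarray(pts, dtype=np.float64)
    d = pts[-1] - pts[0]
    phi = math.atan2(d[1], d[0])
    c, s = math.cos(-phi), math.sin(-phi)
    rot = np.array([[c, -s], [s, c]])
    return (pts - pts[0]) @ rot.T


def curvature_index(skel: PseudoSkeleton | np.ndarray, n_points: int = 101) -> float:
    """Signed curvature index c of a pseudo-skeleton.

    The skeleton is resampled to ``n_points`` equidistant points and rotated
    so its end-to-end axis is straight; y is the lateral coordinate.  With
    I = ∫y and I_abs = ∫|y| (trapezoidal, over point index),

        c = (I_abs - I) * (-sign(y_mid))

    A straight body gives 0.  A C-bend lying entirely at y < 0 gives
    c = 2*I_abs > 0; an s-shaped posture, whose lateral excursions cancel
    in I but not in I_abs, gives an intermediate value.  If the middle
    lateral coordinate is exactly 0 the sign factor (and hence c) is 0.
    """
    pts = skel.points if isinstance(skel, PseudoSkeleton) else np.asarray(skel)
    if len(pts) < 3:
        raise ContractError("curvature index needs >= 3 points")
    y = rotate_to_axis(resample_skeleton(pts, n_points))[:, 1]
    i_abs = np.trapezoid(np.abs(y))
    i_sig = np.trapezoid(y)
    y_mid = y[len(y) // 2]
    sign = 0.0 if y_mid == 0 else -np.sign(y_mid)
    return float((i_abs - i_sig) * sign)


def curvature_components(skel, n_points: int = 101) -> tuple[float, float]:
    """Alternative symmetric decomposition (turn magnitude, s-shape).

    Not part of the original curvature-index formulation: returns
    (|∫y|, ∫|y| - |∫y|) — the first is large for one-sided bends of either
    polarity, the second for s-shapes.
    """
    pts = skel.points if isinstance(skel, PseudoSkeleton) else np.asarray(skel)
    y = rotate_to_axis(resample_skeleton(pts, n_points))[:, 1]
    i_abs = float(np.trapezoid(np.abs(y)))
    i_sig = float(np.trapezoid(y))
    return abs(i_sig), i_abs - abs(i_sig)


def detect_turns(c_series, threshold: float, min_duration: int = 1,
                 gap_frames: int = 0) -> list[tuple[int, int]]:
    """Intervals (start, stop) where |c| exceeds threshold.

    Runs shorter than ``min_duration`` frames are dropped; runs separated
    by gaps shorter than ``gap_frames`` are merged.  stop is exclusive.
    """
    if threshold <= 0:
        raise ConfigurationError("turn threshold must be > 0")
    above = np.abs(np.asarray(c_series, dtype=np.float64)) > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(int(s), int(e)) for s, e in merged if e - s >= min_duration]


def resolve_headings(orientations_deg, positions, fps: float,
                     speed_eps: float = 0.0) -> np.ndarray:
    """Resolve axial ellipse orientations (mod 180°) to directed headings.

    The 180° ambiguity is resolved by temporal continuity (each frame takes
    the candidate closer to the previous heading, so the heading cannot
    flap while the animal glides or rests), and the overall polarity is
    chosen so the heading aligns with the velocity (non-negative mean dot
    product) over the fast-moving frames — those with speed above
    max(speed_eps, half the median speed).  The result is unwrapped.
    """
    theta = np.asarray(orientations_deg, dtype=np.float64) % 180.0
    pos = np.asarray(positions, dtype=np.float64)
    v = np.gradient(pos, axis=0) * fps
    speed = np.linalg.norm(v, axis=1)

    out = np.empty_like(theta)
    out[0] = theta[0]
    for i in range(1, len(theta)):
        cands = (theta[i], theta[i] + 180.0)
        dist = [abs((h - out[i - 1] + 180) % 360 - 180) for h in cands]
        out[i] = cands[int(np.argmin(dist))]
    out = np.degrees(np.unwrap(np.radians(out)))

    gate = max(speed_eps, 0.5 * float(np.median(speed)))
    fast = speed > gate
    if not fast.any():
        fast = np.ones_like(fast)
    hr = np.radians(out)
    alignment = float(np.sum(v[fast, 0] * np.cos(hr[fast]) +
                             v[fast, 1] * np.sin(hr[fast])))
    if alignment < 0:
        out = out + 180.0
    return out


def ego_velocities(positions, headings_deg, fps: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thrust, slip and yaw velocity from positions and directed headings.

    Derivatives are central differences (one-sided at the ends).  Thrust is
    the velocity component along the heading, slip the perpendicular
    component; thrust² + slip² equals the squared speed identically.
    Yaw velocity is the derivative of the unwrapped heading in deg/s.
    """
    pos = np.asarray(positions, dtype=np.float64)
    h = np.asarray(headings_deg, dtype=np.float64)
    if len(pos) < 2:
        raise ContractError("need >= 2 frames")
    v = np.gradient(pos, axis=0) * fps
    hr = np.radians(h)
    thrust = v[:, 0] * np.cos(hr) + v[:, 1] * np.sin(hr)
    slip = -v[:, 0] * np.sin(hr) + v[:, 1] * np.cos(hr)
    hu = np.degrees(np.unwrap(hr))
    yaw_velocity = np.gradient(hu) * fps
    return thrust, slip, yaw_velocity


def find_event_peaks(series, threshold: float,
                     min_separation_frames: int = 1) -> np.ndarray:
    """Local maxima of |series| strictly above threshold, separated by at
    least ``min_separation_frames`` (the larger peak wins conflicts)."""
    if threshold <= 0:
        raise ConfigurationError("event threshold must be > 0")
    mag = np.abs(np.asarray(series, dtype=np.float64))
    peaks, _ = find_peaks(mag)
    peaks = peaks[mag[peaks] > threshold]
    if len(peaks) == 0:
        return np.array([], dtype=int)
    order = peaks[np.argsort(-mag[peaks], kind="stable")]
    kept: list[int] = []
    for p in order:
        if all(abs(p - k) >= min_separation_frames for k in kept):
            kept.append(int(p))
    return np.array(sorted(kept), dtype=int)


@dataclass
class TriggeredAverage:
    """Event-aligned mean trace with a dispersion band."""

    offsets: np.ndarray   # frame offsets -w..+w
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_events: int

    @property
    def is_empty(self) -> bool:
        return self.n_events == 0


def triggered_average(series, events, window_frames: int,
                      dispersion: str = "std", n_boot: int = 500,
                      seed: int = 0) -> TriggeredAverage:
    """Mean of ``series`` over windows [-w, +w] around each event.

    Events whose window extends past either end of the series are dropped.
    dispersion="std" gives mean ± one standard deviation across windows;
    "bootstrap_ci" gives a 95% bootstrap confidence band of the pointwise
    median.
    """
    s = np.asarray(series, dtype=np.float64)
    w = int(window_frames)
    wins = [s[e - w: e + w + 1] for e in np.asarray(events, dtype=int)
            if e - w >= 0 and e + w + 1 <= len(s)]
    offsets = np.arange(-w, w + 1)
    if not wins:
        z = np.empty(0)
        return TriggeredAverage(offsets, z, z, z, 0)
    mat = np.vstack(wins)
    mean = mat.mean(axis=0)
    if dispersion == "std":
        sd = mat.std(axis=0, ddof=0)
        lo, hi = mean - sd, mean + sd
    elif dispersion == "bootstrap_ci":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(mat), size=(n_boot, len(mat)))
        meds = np.median(mat[idx], axis=1)
        lo = np.percentile(meds, 2.5, axis=0)
        hi = np.percentile(meds, 97.5, axis=0)
    else:
        raise ConfigurationError(f"unknown dispersion {dispersion!r}")
    return TriggeredAverage(offsets, mean, lo, hi, len(mat))


def event_frequency(events, duration_s: float) -> float:
    """Event rate in Hz."""
    if duration_s <= 0:
        raise ConfigurationError("duration must be > 0")
    return len(np.atleast_1d(np.asarray(events))) / duration_s


def permutation_median_test(group_a, group_b, n_permutations: int = 10000,
                            exhaustive: bool | None = None,
                            seed: int = 0) -> float:
    """Two-sided permutation test on the difference of medians.

    The statistic is T = |median(A) - median(B)|; the null distribution is
    built by relabelling the pooled values into groups of the original
    sizes.  With ``exhaustive`` (default: automatic when the number of
    distinct splits is <= 20000) the p-value is the exact proportion of
    splits with T_perm >= T_obs; otherwise p = (#{T_perm >= T_obs} + 1) /
    (n_permutations + 1) over seeded random relabelings.
    """
    a = np.asarray(group_a, dtype=np.float64).ravel()
    b = np.asarray(group_b, dtype=np.float64).ravel()
    if a.size < 1 or b.size < 1:
        raise ContractError("both groups need >= 1 value")
    pool = np.concatenate([a, b])
    if np.allclose(pool, pool[0]):
        return 1.0
    t_obs = abs(np.median(a) - np.median(b))
    n, na = pool.size, a.size
    n_splits = math.comb(n, na)
    if exhaustive is None:
        exhaustive = n_splits <= 20000
    eps = 1e-12
    if exhaustive:
        idx_a, idx_b = _split_indices(n, na)
        t = np.abs(np.median(pool[idx_a], axis=1) -
                   np.median(pool[idx_b], axis=1))
        return float(np.count_nonzero(t >= t_obs - eps) / n_splits)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pool)
        t = abs(np.median(perm[:na]) - np.median(perm[na:]))
        if t >= t_obs - eps:
            count += 1
    return (count + 1) / (n_permutations + 1)


from functools import lru_cache


@lru_cache(maxsize=16)
def _split_indices(n: int, na: int) -> tuple[np.ndarray, np.ndarray]:
    """All C(n, na) group-A index sets and their complements."""
    idx_a = np.array(list(combinations(range(n), na)), dtype=np.intp)
    full = np.arange(n)
    idx_b = np.array([np.setdiff1d(full, row, assume_unique=True)
                      for row in idx_a], dtype=np.intp)
    return idx_a, idx_b


def build_kinematics_table(track: pd.DataFrame, fps: float,
                           scale_m_per_px: float = 1.0) -> pd.DataFrame:
    """Assemble the per-frame kinematics table for one identity.

    ``track`` needs columns x, y, theta_deg (pixel coordinates and axial
    ellipse orientation); optional columns body_length_px, bending_deg and
    curvature are carried through.  Output adds time_s, metric positions,
    directed heading, thrust/slip (m/s) and yaw/yaw velocity (deg, deg/s).
    """
    pos_px = track[["x", "y"]].to_numpy(dtype=float)
    pos_m = pos_px * scale_m_per_px
    headings = resolve_headings(track["theta_deg"].to_numpy(dtype=float),
                                pos_m, fps)
    thrust, slip, yaw_vel = ego_velocities(pos_m, headings, fps)
    out = pd.DataFrame({
        "time_s": np.arange(len(track)) / fps,
        "x_m": pos_m[:, 0],
        "y_m": pos_m[:, 1],
        "heading_deg": headings,
        "thrust_m_s": thrust,
        "slip_m_s": slip,
        "yaw_deg": headings,
        "yaw_velocity_deg_s": yaw_vel,
    })
    for col in ("body_length_px", "bending_deg", "curvature",
                "turn_magnitude"):
        if col in track.columns:
            out[col] = track[col].to_numpy()
    if "body_length_px" in track.columns and scale_m_per_px != 1.0:
        out["body_length_m"] = out["body_length_px"] * scale_m_per_px
    return out
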