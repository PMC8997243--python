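"""Computational load management: duration estimation and LPT balancing.

Batch analyses are embarrassingly parallel at the video level.  Each job's
duration is estimated by timing a test detection on a few sample frames and
extrapolating to the full frame count; jobs are then packed onto cores with
the classic longest-processing-time (LPT) greedy rule: sort by descending
duration, always assign to the currently least-loaded core.  LPT's makespan
is provably within 4/3 of the optimum.
"""

from __future__ import annotations

import heapq
import time
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .hough_ellipse import DetectionParams, detect_frame
from .media_io import FrameSequence, compute_background
from .segmentation import segment_frame


@dataclass
class JobSpec:
    """One schedulable analysis job."""

    config_path: str
    duration_s: float = 0.0
    done: bool = False


def estimate_duration(seq: FrameSequence, params: DetectionParams,
                      threshold: float = 0.25, n_probe: int = 5) -> float:
    """Extrapolate full-video runtime from timed probe-frame detections."""
    n_probe = min(n_probe, len(seq))
    idx = np.linspace(0, len(seq) - 1, n_probe).astype(int)
    bg = compute_background(seq, "max")
    t0 = time.perf_counter()
    for i in idx:
        mask, contours = segment_frame(seq.frames[i], bg, threshold)
        detect_frame(mask, contours, params, frame_index=int(i))
    per_frame = (time.perf_counter() - t0) / n_probe
    return per_frame * len(seq)


def balance_jobs(durations, n_cores: int) -> tuple[list[list[int]], float]:
    """Longest-processing-time greedy assignment of jobs to cores.

    Returns (per-core job index lists, makespan).  Jobs are sorted by
    descending duration and each goes to the currently least-loaded core.
    """
    durations = list(map(float, durations))
    if n_cores < 1:
        raise ConfigurationError("n_cores must be >= 1")
    if any(d <= 0 for d in durations):
        raise ConfigurationError("durations must be positive")
    order = sorted(range(len(durations)), key=lambda i: -durations[i])
    heap = [(0.0, c) for c in range(n_cores)]
    heapq.heapify(heap)
    assignment: list[list[int]] = [[] for _ in range(n_cores)]
    for j in order:
        load, core = heapq.heappop(heap)
        assignment[core].append(j)
        heapq.heappush(heap, (load + durations[j], core))
    makespan = max((sum(durations[j] for j in jobs) for jobs in assignment),
                   default=0.0)
    return assignment, makespan
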