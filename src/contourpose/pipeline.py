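"""End-to-end composition: video → track table → skeletons → kinematics.

``track_video`` runs background estimation, segmentation, per-boundary
ellipse detection, the rule-based and neighbour-based corrections, identity
assignment, and (optionally) midline extraction, returning a tidy per-frame
per-identity table plus the skeleton chains.  ``run_pipeline`` drives the
same flow from a YAML configuration and writes the standard output files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinematics as kin
from .calibration import Calibration, build_calibration
from .errors import ConfigurationError, InputError
from .hough_ellipse import DetectionParams, FrameDetections, detect_frame
from .media_io import FrameSequence, compute_background, open_source
from .pose import PseudoSkeleton, bending_angle, skeletonize_contour
from .segmentation import Roi, segment_frame
from .tracking_correction import (CorrectionConfig, apply_adhoc,
                                  assign_identities, posthoc_rescue)

log = logging.getLogger("contourpose")


@dataclass
class TrackResult:
    """Output bundle of ``track_video``."""

    table: pd.DataFrame
    skeletons: list[PseudoSkeleton]
    detections: list[FrameDetections]
    summary: dict = field(default_factory=dict)


def default_min_area(params: DetectionParams) -> float:
    """Noise-speck suppression area from the size prior."""
    return float(np.pi * (params.min_major / 4.0) ** 2)


def track_video(seq: FrameSequence, params: DetectionParams,
                cfg: CorrectionConfig | None = None,
                threshold: float = 0.25, bg_mode: str = "max",
                roi: Roi | None = None, erosion_radius: int = 1,
                compute_pose: bool = True, n_seeds: int = 100,
                background=None, seed: int = 0) -> TrackResult:
    """Track every frame of a sequence and (optionally) extract midlines.

    ``background`` overrides the temporal-projection estimate (e.g. an
    animal-free reference frame for clips too short for the animal to clear
    its own footprint).
    """
    if cfg is None:
        cfg = CorrectionConfig(n_animals=params.n_animals)
    bg = background if background is not None \
        else compute_background(seq, bg_mode)
    min_area = default_min_area(params)

    per_frame = []
    contours_per_frame = []
    for i in range(len(seq)):
        mask, contours = segment_frame(seq.frames[i], bg, threshold, roi,
                                       erosion_radius, min_area)
        dets = detect_frame(mask, contours, params, frame_index=i,
                            rng_seed=seed + i)
        dets = apply_adhoc(dets, cfg, params)
        per_frame.append(dets)
        contours_per_frame.append(contours)

    # sub-pixel refinement: a detection that owns its boundary outright is
    # re-centred on the contour's moment-equivalent ellipse (accumulator
    # peaks live on a half-pixel grid and jitter frame-to-frame)
    from dataclasses import replace as _replace

    from .segmentation import equivalent_ellipse
    for i, dets in enumerate(per_frame):
        owners: dict[int, int] = {}
        for d in dets.accepted:
            owners[d.contour_index] = owners.get(d.contour_index, 0) + 1
        refined = []
        for d in dets.accepted:
            ci = d.contour_index
            if 0 <= ci < len(contours_per_frame[i]) and owners.get(ci) == 1:
                try:
                    cx, cy, a, b, th = equivalent_ellipse(
                        contours_per_frame[i][ci])
                except Exception:
                    refined.append(d)
                    continue
                if np.hypot(cx - d.center[0], cy - d.center[1]) < d.semi_major:
                    d = _replace(d, center=(cx, cy), semi_major=a,
                                 semi_minor=b, orientation=th)
            refined.append(d)
        dets.accepted = refined

    # neighbour-based rescue of residual deficits
    for i, dets in enumerate(per_frame):
        if dets.unresolved:
            prev = per_frame[i - 1] if i > 0 else None
            nxt = per_frame[i + 1] if i + 1 < len(per_frame) else None
            per_frame[i] = posthoc_rescue(prev, dets, nxt, cfg, params)

    # identity propagation
    rows = []
    skeletons: list[PseudoSkeleton] = []
    next_id = 0
    prev_accepted: list = []
    prev_ids: list[int] = []
    prev_endpoints: dict[int, np.ndarray] = {}
    for i, dets in enumerate(per_frame):
        mapping = assign_identities(prev_accepted, dets.accepted)
        ids = []
        for m in mapping:
            if m >= 0:
                ids.append(prev_ids[m])
            else:
                ids.append(next_id)
                next_id += 1
        for det, ident in zip(dets.accepted, ids):
            row = {
                "frame": i, "id": ident,
                "x": det.center[0], "y": det.center[1],
                "a": det.semi_major, "b": det.semi_minor,
                "theta_deg": det.orientation, "quality": det.quality,
                "problem_code": dets.problem_code,
                "corrected": int(det.quality < 0),
                "body_length_px": np.nan, "bending_deg": np.nan,
                "curvature": np.nan, "turn_magnitude": np.nan,
            }
            if compute_pose and det.contour_index >= 0 and \
                    det.contour_index < len(contours_per_frame[i]):
                contour = contours_per_frame[i][det.contour_index]
                try:
                    skel = skeletonize_contour(contour, n_seeds,
                                               frame_index=i, identity=ident)
                except Exception:
                    skel = None
                if skel is not None:
                    pts = skel.points
                    ep = prev_endpoints.get(ident)
                    if ep is not None and (
                            np.linalg.norm(pts[0] - ep[0]) +
                            np.linalg.norm(pts[-1] - ep[1]) >
                            np.linalg.norm(pts[-1] - ep[0]) +
                            np.linalg.norm(pts[0] - ep[1])):
                        pts = pts[::-1]
                        skel.points = pts
                    prev_endpoints[ident] = np.array([pts[0], pts[-1]])
                    skeletons.append(skel)
                    row["body_length_px"] = skel.length_px
                    if len(pts) >= 3:
                        row["bending_deg"] = bending_angle(skel)
                        row["curvature"] = kin.curvature_index(skel)
                        # symmetric turn magnitude |∫y|: the signed index is
                        # blind to bends lying entirely on the positive side
                        row["turn_magnitude"] = \
                            kin.curvature_components(skel)[0]
            rows.append(row)
        prev_accepted, prev_ids = dets.accepted, ids

    columns = ["frame", "id", "x", "y", "a", "b", "theta_deg", "quality",
               "problem_code", "corrected", "body_length_px", "bending_deg",
               "curvature", "turn_magnitude"]
    table = pd.DataFrame(rows, columns=columns)
    n = len(per_frame)
    complete = sum(1 for d in per_frame if len(d.accepted) == cfg.n_animals)
    corrected_frames = sum(
        1 for d in per_frame
        if d.problem_code != 0 or any(a.quality < 0 for a in d.accepted))
    summary = {
        "n_frames": n,
        "n_complete_frames": complete,
        "detection_rate_pct": 100.0 * complete / max(n, 1),
        "corrected_frame_fraction": corrected_frames / max(n, 1),
        "n_unresolved": sum(1 for d in per_frame if d.unresolved),
        "n_identities": next_id,
    }
    return TrackResult(table, skeletons, per_frame, summary)


def skeletons_to_jsonl(skeletons: list[PseudoSkeleton], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in skeletons:
            fh.write(json.dumps({
                "frame": int(s.frame_index), "id": int(s.identity),
                "length_px": float(s.length_px),
                "points": np.round(s.points, 3).tolist(),
            }) + "\n")


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the whole analysis from a YAML config (or dict).

    Config keys: ``input`` (path + optional fps, or a ``synthetic`` block),
    ``detection`` (min_major, max_major, n_animals, thresholds …),
    ``calibration`` (optional: kind, marks, true_size or scale_m_per_px),
    ``output_dir``.  Writes track.csv, skeletons.jsonl, kinematics.csv and
    summary.json; returns the summary dict.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(outdir or config.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    seq = _load_input(config.get("input", {}))
    det = config.get("detection", {})
    params = DetectionParams(
        min_major=det.get("min_major", 40),
        max_major=det.get("max_major", 80),
        n_animals=det.get("n_animals", 1),
        quality_threshold=det.get("quality_threshold", 0.3))
    cfg = CorrectionConfig(
        n_animals=params.n_animals,
        overlap_frac=det.get("overlap_frac", 0.5),
        chain_factor=det.get("chain_factor", 1.5),
        estimator_weights=tuple(det.get("estimator_weights", (1.0, 0.5, 0.5))))
    res = track_video(
        seq, params, cfg,
        threshold=det.get("threshold", 0.25),
        bg_mode=det.get("bg_mode", "max"),
        erosion_radius=det.get("erosion_radius", 1),
        compute_pose=bool(config.get("pose", {}).get("enabled", True)),
        n_seeds=config.get("pose", {}).get("n_seeds", 100),
        seed=int(config.get("seed", 0)))

    scale = 1.0
    cal_cfg = config.get("calibration")
    if cal_cfg:
        if "scale_m_per_px" in cal_cfg:
            scale = float(cal_cfg["scale_m_per_px"])
        else:
            cal = build_calibration(cal_cfg["kind"], cal_cfg["marks"],
                                    cal_cfg["true_size"])
            scale = cal.scale

    res.table.to_csv(out / "track.csv", index=False)
    skeletons_to_jsonl(res.skeletons, out / "skeletons.jsonl")
    ktabs = []
    for ident, sub in res.table.groupby("id"):
        if len(sub) < 2:
            continue
        kt = kin.build_kinematics_table(sub.reset_index(drop=True), seq.fps,
                                        scale)
        kt.insert(0, "id", ident)
        ktabs.append(kt)
    if ktabs:
        pd.concat(ktabs, ignore_index=True).to_csv(out / "kinematics.csv",
                                                   index=False)
    summary = dict(res.summary)
    summary["runtime_s"] = round(time.time() - t0, 2)
    summary["fps"] = seq.fps
    summary["scale_m_per_px"] = scale
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline done: %s", summary)
    return summary


def _load_input(spec: dict) -> FrameSequence:
    from . import synthetic
    if "synthetic" in spec:
        s = dict(spec["synthetic"])
        kind = s.pop("kind", "crawler")
        maker = {"crawler": synthetic.make_crawler,
                 "swimmer": synthetic.make_swimmer,
                 "multi": synthetic.make_multianimal}.get(kind)
        if maker is None:
            raise ConfigurationError(f"unknown synthetic kind {kind!r}")
        seq, _ = maker(**s)
        return seq
    if "path" not in spec:
        raise InputError("config input needs a 'path' or 'synthetic' block")
    return open_source(spec["path"], spec.get("fps"))
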