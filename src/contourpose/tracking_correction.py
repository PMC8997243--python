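"""Occlusion repair and identity maintenance for multi-animal tracking.

The user states how many animals the scene contains; every frame's raw
ellipse candidates are reconciled against that prior by seven rule-based
corrections (duplicate suppression, sub-threshold fill-up, chain splitting),
then still-unresolved frames are rescued by scoring sub-threshold candidates
against the neighbouring frames with weighted position/surface/contour
similarity.  Identities are propagated frame-to-frame by minimum-cost
bipartite assignment (Hungarian algorithm) on centre distances.

Problem codes (0 = clean frame):

1. too many detections, the surplus all mutually overlapping
2. too many detections, none overlapping
3. both 1 and 2 at once
4. too few detections, none oversized
5. too few detections, at least one oversized ("chaining": two animals
   aligned end-to-end fitted as one double-length ellipse)
6. chaining whose split still leaves a deficit
7. correct count but chaining present

Any detection a rule introduces or modifies has its quality set to -1; the
pre-correction quality is retained separately for deterministic ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ConfigurationError, ContractError
from .hough_ellipse import (DetectionParams, EllipseDetection,
                            FrameDetections, overlap_fraction,
                            ramanujan_perimeter)


@dataclass
class CorrectionConfig:
    """Priors and weights for the correction stages.

    overlap_frac: intersection-over-smaller-area fraction above which two
    ellipses count as "overlaying" one animal.  chain_factor: size ratio
    (vs. the expected single-animal major axis) above which a detection is a
    chain of animals.  estimator_weights: (position, surface, contour)
    weights for post-hoc candidate scoring; a zero weight omits that
    estimator.
    """

    n_animals: int = 1
    overlap_frac: float = 0.5
    chain_factor: float = 1.5
    estimator_weights: tuple[float, float, float] = (1.0, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        if not (0 < self.overlap_frac < 1):
            raise ConfigurationError("overlap_frac must be in (0,1)")
        if self.chain_factor <= 1:
            raise ConfigurationError("chain_factor must be > 1")
        if not any(w > 0 for w in self.estimator_weights):
            raise ConfigurationError("at least one estimator weight must be > 0")


def _overlap_groups(dets: list[EllipseDetection],
                    overlap_frac: float) -> list[list[int]]:
    """Connected components of the pairwise-overlap graph, size >= 2."""
    n = len(dets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = np.array(dets[i].center), np.array(dets[j].center)
            if np.linalg.norm(ci - cj) > dets[i].semi_major + dets[j].semi_major:
                continue
            if overlap_fraction(dets[i], dets[j]) >= overlap_frac:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [g for g in groups.values() if len(g) >= 2]


def _is_oversized(det: EllipseDetection, cfg: CorrectionConfig,
                  expected_major: float) -> bool:
    return 2.0 * det.semi_major >= cfg.chain_factor * expected_major


def classify_problem(dets: FrameDetections, cfg: CorrectionConfig,
                     expected_major: float) -> int:
    """Assign the occlusion problem code (0-7) for one frame."""
    acc = dets.accepted
    count = len(acc)
    n = cfg.n_animals
    oversize = any(_is_oversized(d, cfg, expected_major) for d in acc)
    groups = _overlap_groups(acc, cfg.overlap_frac)
    overlap_excess = sum(len(g) - 1 for g in groups)

    if count == n:
        return 7 if oversize else 0
    if count > n:
        surplus = count - n
        if overlap_excess == 0:
            return 2
        if overlap_excess >= surplus:
            return 1
        return 3
    return 5 if oversize else 4


def split_chain(det: EllipseDetection,
                params: DetectionParams) -> list[EllipseDetection]:
    """Split an oversized "chain" detection into single-animal ellipses.

    k = round(chain major length / expected major length) child ellipses are
    placed evenly along the chain's major axis, each with the expected mean
    major-axis length, the parent's minor axis and orientation, and q = -1.
    """
    expected = params.expected_major
    ratio = 2 * det.semi_major / expected
    if ratio < 1.5 - 1e-9:
        raise ContractError("split_chain called on a non-oversized detection")
    k = max(2, int(round(ratio)))
    th = np.deg2rad(det.orientation)
    axis = np.array([np.cos(th), np.sin(th)])
    c = np.array(det.center)
    # child centres evenly spaced over the parent's major extent
    offsets = (np.arange(k) - (k - 1) / 2) * (2 * det.semi_major / k)
    out = []
    for off in offsets:
        cc = c + off * axis
        out.append(EllipseDetection(
            center=(float(cc[0]), float(cc[1])),
            semi_major=expected / 2,
            semi_minor=det.semi_minor,
            orientation=det.orientation,
            quality=-1.0,
            is_subthreshold=False,
            contour_index=det.contour_index,
            rank_quality=det.rank_quality,
        ))
    return out


def _mark_corrected(det: EllipseDetection) -> EllipseDetection:
    return replace(det, quality=-1.0, is_subthreshold=False)


def apply_adhoc(dets: FrameDetections, cfg: CorrectionConfig,
                params: DetectionParams) -> FrameDetections:
    """Enforce the animal-count prior with the rule-based corrections.

    Rules are applied iteratively, re-classifying after each application,
    until the frame is clean or no rule makes progress.  The recorded
    problem_code is the first non-zero classification (upgraded to 6 when a
    chain split still leaves a deficit that needs sub-threshold fill-up).
    """
    expected = params.expected_major
    accepted = list(dets.accepted)
    pool = sorted(dets.subthreshold, key=lambda d: -d.rank_quality)
    first_code: int | None = None
    did_split = False
    unresolved = False

    for _ in range(10):
        code = classify_problem(
            FrameDetections(dets.frame_index, accepted, pool), cfg, expected)
        if first_code is None and code != 0:
            first_code = code
        if code == 0:
            break
        if code in (1, 3):
            groups = _overlap_groups(accepted, cfg.overlap_frac)
            drop: set[int] = set()
            for g in groups:
                best = max(g, key=lambda i: accepted[i].rank_quality)
                drop.update(i for i in g if i != best)
            accepted = [d for i, d in enumerate(accepted) if i not in drop]
        elif code == 2:
            while len(accepted) > cfg.n_animals:
                worst = min(range(len(accepted)),
                            key=lambda i: accepted[i].rank_quality)
                accepted.pop(worst)
        elif code == 4:
            if did_split and first_code in (5, 7):
                first_code = 6
            while len(accepted) < cfg.n_animals:
                # best remaining candidate not colliding with an accepted one
                pick = next((k for k, c in enumerate(pool)
                             if all(overlap_fraction(c, a) < cfg.overlap_frac
                                    for a in accepted)), None)
                if pick is None:
                    break
                accepted.append(_mark_corrected(pool.pop(pick)))
            if len(accepted) < cfg.n_animals:
                unresolved = True
                break
        elif code in (5, 7):
            new: list[EllipseDetection] = []
            for d in accepted:
                if _is_oversized(d, cfg, expected):
                    new.extend(split_chain(d, params))
                    did_split = True
                else:
                    new.append(d)
            accepted = new
        else:  # pragma: no cover
            break
    else:
        unresolved = len(accepted) != cfg.n_animals

    out = FrameDetections(dets.frame_index, accepted, pool,
                          problem_code=first_code or 0,
                          unresolved=unresolved or
                          len(accepted) < cfg.n_animals)
    return out


def _estimator_scores(cand: EllipseDetection, ref_center: np.ndarray,
                      ref_area: float, ref_perim: float,
                      d0: float) -> tuple[float, float, float]:
    d = float(np.linalg.norm(np.array(cand.center) - ref_center))
    s_pos = 1.0 / (1.0 + d / d0)
    s_surf = min(cand.area, ref_area) / max(cand.area, ref_area)
    p = cand.perimeter
    s_cont = min(p, ref_perim) / max(p, ref_perim)
    return s_pos, s_surf, s_cont


def posthoc_rescue(prev: FrameDetections | None, cur: FrameDetections,
                   nxt: FrameDetections | None, cfg: CorrectionConfig,
                   params: DetectionParams) -> FrameDetections:
    """Fill a residual detection deficit from the sub-threshold pool.

    Each candidate is scored S = Σ wᵢ·sᵢ / Σ wᵢ against a reference built
    from the neighbouring frames' accepted detections (mean of previous and
    next when both exist).  The best-scoring candidate is accepted with
    q = -1.  Ties break on raw Hough quality, then candidate index.
    """
    deficit = cfg.n_animals - len(cur.accepted)
    if deficit <= 0 or not cur.subthreshold:
        return cur

    refs = _reference_detections(prev, cur, nxt)
    if not refs:
        return cur
    w_pos, w_surf, w_cont = cfg.estimator_weights
    wsum = w_pos + w_surf + w_cont
    d0 = params.expected_major

    accepted = list(cur.accepted)
    pool = list(cur.subthreshold)
    for ref_center, ref_area, ref_perim in refs[:deficit]:
        scored = []
        for idx, c in enumerate(pool):
            if any(overlap_fraction(c, a) >= cfg.overlap_frac
                   for a in accepted):
                continue
            s_pos, s_surf, s_cont = _estimator_scores(
                c, ref_center, ref_area, ref_perim, d0)
            s = (w_pos * s_pos + w_surf * s_surf + w_cont * s_cont) / wsum
            scored.append((-s, -c.rank_quality, idx))
        if not scored:
            break
        scored.sort()
        best_idx = scored[0][2]
        accepted.append(_mark_corrected(pool.pop(best_idx)))

    return FrameDetections(cur.frame_index, accepted, pool,
                           problem_code=cur.problem_code,
                           unresolved=len(accepted) < cfg.n_animals)


def _reference_detections(prev, cur, nxt):
    """Reference (centre, area, perimeter) triples for the missing animals."""
    prev_acc = prev.accepted if prev else []
    nxt_acc = nxt.accepted if nxt else []
    base = prev_acc or nxt_acc
    if not base:
        return []
    # neighbours already claimed by current accepted detections are not
    # references for the missing animal(s)
    claimed: set[int] = set()
    if cur.accepted and base:
        cost = np.array([[np.linalg.norm(np.array(b.center) - np.array(a.center))
                          for b in base] for a in cur.accepted])
        rows, cols = linear_sum_assignment(cost)
        claimed = set(int(c) for c in cols)
    missing = [b for i, b in enumerate(base) if i not in claimed]
    if not missing:
        missing = base
    other = nxt_acc if base is prev_acc else prev_acc
    refs = []
    for m in missing:
        center = np.array(m.center, dtype=float)
        area, perim = m.area, m.perimeter
        if other:
            # pair with the nearest counterpart in the other neighbour frame
            o = min(other, key=lambda d: np.linalg.norm(
                np.array(d.center) - center))
            center = 0.5 * (center + np.array(o.center))
            area = 0.5 * (area + o.area)
            perim = 0.5 * (perim + o.perimeter)
        refs.append((center, area, perim))
    return refs


def assign_identities(prev_accepted: list[EllipseDetection],
                      cur_accepted: list[EllipseDetection]) -> list[int]:
    """Minimum-total-centre-distance assignment of current to previous.

    Returns, for each current detection, the index of the matched previous
    detection, or -1 for surplus detections (which get new identities).
    """
    if not prev_accepted or not cur_accepted:
        return [-1] * len(cur_accepted)
    cost = np.array([[np.linalg.norm(np.array(c.center) - np.array(p.center))
                      for p in prev_accepted] for c in cur_accepted])
    rows, cols = linear_sum_assignment(cost)
    out = [-1] * len(cur_accepted)
    for r, c in zip(rows, cols):
        out[int(r)] = int(c)
    return out
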