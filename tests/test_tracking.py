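from itertools import permutations

import numpy as np
import pytest

from contourpose.errors import ConfigurationError, ContractError
from contourpose.hough_ellipse import (DetectionParams, EllipseDetection,
                                       FrameDetections)
from contourpose.tracking_correction import (CorrectionConfig, apply_adhoc,
                                             assign_identities,
                                             classify_problem, posthoc_rescue,
                                             split_chain)

PARAMS = DetectionParams(min_major=40, max_major=80)  # expected major = 60


def det(x, y, a=30.0, b=8.0, theta=0.0, q=0.8, sub=False):
    return EllipseDetection((x, y), a, b, theta, q, is_subthreshold=sub)


def frame(accepted, subthreshold=(), idx=0):
    return FrameDetections(idx, list(accepted), list(subthreshold))


class TestClassifyProblem:
    def test_clean_frame_is_zero(self):
        cfg = CorrectionConfig(n_animals=2)
        dets = frame([det(50, 50), det(150, 150)])
        assert classify_problem(dets, cfg, 60.0) == 0

    def test_surplus_overlapping_is_code_1(self):
        cfg = CorrectionConfig(n_animals=1)
        # two ellipses fitted onto one animal: ~80% mutual overlap
        dets = frame([det(50, 50, q=0.9), det(52, 50, q=0.7)])
        assert classify_problem(dets, cfg, 60.0) == 1

    def test_surplus_disjoint_is_code_2(self):
        cfg = CorrectionConfig(n_animals=2)
        dets = frame([det(40, 40, q=0.9), det(120, 40, q=0.8),
                      det(80, 150, q=0.7)])
        assert classify_problem(dets, cfg, 60.0) == 2

    def test_surplus_mixed_is_code_3(self):
        cfg = CorrectionConfig(n_animals=1)
        dets = frame([det(40, 40, q=0.9), det(42, 40, q=0.7),
                      det(150, 150, q=0.6)])
        assert classify_problem(dets, cfg, 60.0) == 3

    def test_deficit_without_oversize_is_code_4(self):
        cfg = CorrectionConfig(n_animals=2)
        dets = frame([det(40, 40)])
        assert classify_problem(dets, cfg, 60.0) == 4

    def test_deficit_with_oversize_is_chaining_code_5(self):
        cfg = CorrectionConfig(n_animals=2)
        # single detection 1.6x the expected major axis
        dets = frame([det(100, 100, a=0.5 * 1.6 * 60)])
        assert classify_problem(dets, cfg, 60.0) == 5

    def test_correct_count_with_chaining_is_code_7(self):
        cfg = CorrectionConfig(n_animals=2)
        dets = frame([det(60, 60, a=0.5 * 1.7 * 60), det(180, 60)])
        assert classify_problem(dets, cfg, 60.0) == 7

    def test_chain_trigger_is_exactly_1p5x(self):
        cfg = CorrectionConfig(n_animals=2)
        just_below = frame([det(100, 100, a=0.5 * 60 * 1.5 * 0.999)])
        at_boundary = frame([det(100, 100, a=0.5 * 60 * 1.5)])
        assert classify_problem(just_below, cfg, 60.0) == 4
        assert classify_problem(at_boundary, cfg, 60.0) == 5


class TestApplyAdhoc:
    def test_disjoint_surplus_keeps_best_two(self):
        cfg = CorrectionConfig(n_animals=2)
        dets = frame([det(40, 40, q=0.9), det(120, 40, q=0.8),
                      det(80, 150, q=0.7)])
        out = apply_adhoc(dets, cfg, PARAMS)
        assert sorted(d.quality for d in out.accepted) == [0.8, 0.9]
        assert out.problem_code == 2

    def test_overlapping_pair_keeps_best(self):
        cfg = CorrectionConfig(n_animals=1)
        dets = frame([det(50, 50, q=0.85), det(52, 50, q=0.6)])
        out = apply_adhoc(dets, cfg, PARAMS)
        assert len(out.accepted) == 1
        assert out.accepted[0].quality == 0.85
        assert out.problem_code == 1

    def test_deficit_filled_from_subthreshold_with_flag(self):
        cfg = CorrectionConfig(n_animals=2)
        dets = frame([det(40, 40, q=0.9)],
                     [det(150, 150, q=0.4, sub=True),
                      det(160, 40, q=0.2, sub=True)])
        out = apply_adhoc(dets, cfg, PARAMS)
        assert len(out.accepted) == 2
        filled = out.accepted[1]
        assert filled.quality == -1.0          # corrected detections flagged
        assert filled.rank_quality == 0.4      # best sub-threshold chosen
        assert out.problem_code == 4

    def test_no_candidates_leaves_frame_unresolved(self):
        cfg = CorrectionConfig(n_animals=2)
        out = apply_adhoc(frame([det(40, 40)]), cfg, PARAMS)
        assert out.unresolved and len(out.accepted) == 1

    def test_chain_split_resolves_code_5(self):
        cfg = CorrectionConfig(n_animals=2)
        chain = det(100, 100, a=60.0, q=0.7)   # 2x expected major
        out = apply_adhoc(frame([chain]), cfg, PARAMS)
        assert out.problem_code == 5
        assert len(out.accepted) == 2
        assert all(d.quality == -1.0 for d in out.accepted)

    def test_code_7_split_then_trim(self):
        cfg = CorrectionConfig(n_animals=2)
        chain = det(100, 100, a=60.0, q=0.9)
        weak = det(100, 200, q=0.2)
        out = apply_adhoc(frame([chain, weak]), cfg, PARAMS)
        assert out.problem_code == 7
        assert len(out.accepted) == 2
        # the split children (ranked by the chain's q=0.9) outrank the weak
        # genuine detection, which is deleted
        assert all(d.rank_quality == 0.9 for d in out.accepted)


class TestSplitChain:
    def test_double_length_chain_splits_into_two(self):
        chain = det(100.0, 100.0, a=80.0, b=10.0, theta=0.0)
        kids = split_chain(chain, DetectionParams(min_major=60, max_major=100))
        # expected major 80 -> k = round(160/80) = 2, offsets +-40
        assert len(kids) == 2
        xs = sorted(k.center[0] for k in kids)
        assert xs == [pytest.approx(60.0), pytest.approx(140.0)]
        assert all(k.center[1] == pytest.approx(100.0) for k in kids)
        assert all(k.semi_major == pytest.approx(40.0) for k in kids)
        assert all(k.quality == -1.0 for k in kids)

    def test_boundary_ratio_rounds_to_two(self):
        chain = det(0, 0, a=0.5 * 1.5 * 60)
        kids = split_chain(chain, PARAMS)
        assert len(kids) == 2

    def test_oriented_chain_children_along_axis(self):
        chain = det(50.0, 50.0, a=60.0, theta=90.0)
        kids = split_chain(chain, PARAMS)
        assert all(k.center[0] == pytest.approx(50.0, abs=1e-9) for k in kids)

    def test_precondition_enforced(self):
        with pytest.raises(ContractError):
            split_chain(det(0, 0, a=30.0), PARAMS)


class TestPosthocRescue:
    def _cur(self, cands):
        return FrameDetections(1, [], list(cands), problem_code=4,
                               unresolved=True)

    def test_position_estimator_selects_nearest(self):
        cfg = CorrectionConfig(n_animals=1, estimator_weights=(1, 0, 0))
        prev = frame([det(100, 100)], idx=0)
        nxt = frame([det(104, 100)], idx=2)
        cur = self._cur([det(102, 110, q=0.3, sub=True),
                         det(140, 100, q=0.5, sub=True)])
        out = posthoc_rescue(prev, cur, nxt, cfg, PARAMS)
        assert len(out.accepted) == 1
        assert out.accepted[0].center == (102, 110)
        assert out.accepted[0].quality == -1.0

    def test_surface_estimator_selects_similar_area(self):
        cfg = CorrectionConfig(n_animals=1, estimator_weights=(0, 1, 0))
        prev = frame([det(100, 100, a=10, b=3.5)], idx=0)  # reference ~110pi
        small = det(300, 300, a=10, b=3.18, q=0.1, sub=True)   # area ~100
        big = det(20, 20, a=20, b=6.37, q=0.9, sub=True)       # area ~400
        out = posthoc_rescue(prev, self._cur([small, big]), None, cfg, PARAMS)
        assert out.accepted[0].center == (300, 300)

    def test_tie_breaks_on_raw_quality(self):
        cfg = CorrectionConfig(n_animals=1, estimator_weights=(1, 0, 0))
        prev = frame([det(100, 100)], idx=0)
        # equidistant candidates -> exact score tie
        c1 = det(110, 100, q=0.2, sub=True)
        c2 = det(90, 100, q=0.6, sub=True)
        out = posthoc_rescue(prev, self._cur([c1, c2]), None, cfg, PARAMS)
        assert out.accepted[0].center == (90, 100)

    def test_no_candidates_stays_unresolved(self):
        cfg = CorrectionConfig(n_animals=1)
        out = posthoc_rescue(frame([det(0, 0)]), self._cur([]), None, cfg,
                             PARAMS)
        assert out.unresolved


class TestAssignIdentities:
    def test_obvious_optimum(self):
        prev = [det(0, 0), det(100, 0)]
        cur = [det(1, 0), det(101, 0)]
        assert assign_identities(prev, cur) == [0, 1]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        from scipy.optimize import linear_sum_assignment
        for _ in range(100):
            n = int(rng.integers(2, 7))
            cost = rng.uniform(0, 100, (n, n))
            rows, cols = linear_sum_assignment(cost)
            hungarian = cost[rows, cols].sum()
            brute = min(sum(cost[i, p[i]] for i in range(n))
                        for p in permutations(range(n)))
            assert hungarian == pytest.approx(brute)

    def test_assignment_by_centre_distance_is_optimal(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            prev = [det(*rng.uniform(0, 200, 2)) for _ in range(n)]
            cur = [det(*rng.uniform(0, 200, 2)) for _ in range(n)]
            mapping = assign_identities(prev, cur)
            total = sum(np.hypot(cur[i].center[0] - prev[m].center[0],
                                 cur[i].center[1] - prev[m].center[1])
                        for i, m in enumerate(mapping))
            brute = min(sum(np.hypot(cur[i].center[0] - prev[p[i]].center[0],
                                     cur[i].center[1] - prev[p[i]].center[1])
                            for i in range(n))
                        for p in permutations(range(n)))
            assert total == pytest.approx(brute)

    def test_surplus_gets_new_identity(self):
        prev = [det(0, 0), det(100, 0)]
        cur = [det(1, 0), det(99, 0), det(200, 200)]
        mapping = assign_identities(prev, cur)
        assert sorted(mapping) == [-1, 0, 1]
        assert mapping[2] == -1


class TestCorrectionConfig:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            CorrectionConfig(n_animals=0)
        with pytest.raises(ConfigurationError):
            CorrectionConfig(overlap_frac=1.5)
        with pytest.raises(ConfigurationError):
            CorrectionConfig(chain_factor=0.9)
        with pytest.raises(ConfigurationError):
            CorrectionConfig(estimator_weights=(0, 0, 0))
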