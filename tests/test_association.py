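import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentrack.association import (CascadeConfig, ConfigurationError, Detection,
                                  run_cascade, solve_assignment,
                                  split_by_confidence, stage1_iou_match,
                                  stage2_euclid_match, stage3_fused_match)
from pentrack.geometry import BoundingBox
from reference_eval import brute_force_assignment


def det(l, t, w, h, conf, emb=None, frame=1):
    return Detection(BoundingBox(l, t, w, h), conf, emb, frame)


class TestSplit:
    def test_thresholds_partition_detections(self):
        cfg = CascadeConfig(tau_high=0.6, tau_low=0.1)
        dets = [det(0, 0, 5, 5, c) for c in (0.9, 0.3, 0.05)]
        high, low = split_by_confidence(dets, cfg)
        assert high == [0] and low == [1]  # 0.05 discarded

    def test_boundary_confidence_goes_high(self):
        cfg = CascadeConfig(tau_high=0.6, tau_low=0.1)
        high, low = split_by_confidence([det(0, 0, 5, 5, 0.6)], cfg)
        assert high == [0] and low == []

    def test_all_high(self):
        cfg = CascadeConfig(tau_high=0.6, tau_low=0.1)
        high, low = split_by_confidence([det(0, 0, 5, 5, 0.9)] * 3, cfg)
        assert len(high) == 3 and not low

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            CascadeConfig(tau_high=0.1, tau_low=0.6)


class TestSolveAssignment:
    def test_empty_matrices(self):
        r = solve_assignment(np.zeros((0, 3)), gate=1.0)
        assert r.matches == () and r.unmatched_cols == (0, 1, 2)
        r = solve_assignment(np.zeros((2, 0)), gate=1.0)
        assert r.matches == () and r.unmatched_rows == (0, 1)

    def test_diagonal_dominance(self):
        r = solve_assignment(np.array([[0.1, 0.9], [0.9, 0.1]]), gate=1.0)
        assert set(r.matches) == {(0, 0), (1, 1)}

    def test_gate_excludes_pairs(self):
        r = solve_assignment(np.array([[0.4, 0.9], [0.9, 0.9]]), gate=0.5)
        assert r.matches == ((0, 0),)
        assert r.unmatched_rows == (1,) and r.unmatched_cols == (1,)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100)
    def test_equals_brute_force_on_random_matrices(self, seed):
        """Optimality: matches the exhaustive permutation minimum."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 7), rng.integers(1, 7)
        cost = rng.uniform(0, 1, (n, m))
        gate = float(rng.uniform(0.3, 1.0))
        result = solve_assignment(cost, gate)
        expected = brute_force_assignment(cost.tolist(), gate)
        assert len(result.matches) == len(expected)
        assert sum(cost[r, c] for r, c in result.matches) == pytest.approx(
            sum(cost[r, c] for r, c in expected), abs=1e-9)


class TestStages:
    def test_stage1_matches_identical_box(self):
        preds = [BoundingBox(0, 0, 10, 10), BoundingBox(200, 200, 10, 10)]
        dets = [BoundingBox(0, 0, 10, 10)]
        r = stage1_iou_match(preds, dets, CascadeConfig())
        assert r.matches == ((0, 0),)

    def test_stage1_gates_out_zero_iou(self):
        preds = [BoundingBox(0, 0, 10, 10)]
        dets = [BoundingBox(100, 100, 10, 10)]
        r = stage1_iou_match(preds, dets, CascadeConfig())
        assert r.matches == ()

    @given(seed=st.integers(0, 2000))
    def test_stage1_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        preds = [BoundingBox(*rng.uniform(0, 40, 2), *rng.uniform(5, 30, 2))
                 for _ in range(3)]
        dets = [BoundingBox(*rng.uniform(0, 40, 2), *rng.uniform(5, 30, 2))
                for _ in range(3)]
        cfg = CascadeConfig()
        r = stage1_iou_match(preds, dets, cfg)
        from pentrack.geometry import iou_matrix
        cost = (1.0 - iou_matrix(preds, dets)).tolist()
        expected = brute_force_assignment(cost, 1.0 - cfg.iou_gate_stage1)
        total = sum(cost[i][j] for i, j in r.matches)
        assert len(r.matches) == len(expected)
        assert total == pytest.approx(
            sum(cost[i][j] for i, j in expected), abs=1e-9)

    def test_stage2_prefers_near_track(self):
        preds = [BoundingBox(0, 0, 10, 10), BoundingBox(500, 500, 10, 10)]
        dets = [BoundingBox(3, 0, 10, 10)]
        cfg = CascadeConfig(dist_gate_stage2=50.0)
        r = stage2_euclid_match(preds, dets, cfg)
        assert r.matches == ((0, 0),)

    def test_stage2_gate_excludes_far_pairs(self):
        preds = [BoundingBox(0, 0, 10, 10)]
        dets = [BoundingBox(500, 500, 10, 10)]
        r = stage2_euclid_match(preds, dets, CascadeConfig(dist_gate_stage2=50.0))
        assert r.matches == ()

    def test_stage3_lambda_one_degenerates_to_iou(self):
        e1, e2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        preds = [BoundingBox(0, 0, 10, 10)]
        dets = [BoundingBox(2, 0, 10, 10)]
        pure = stage3_fused_match(preds, [e1], dets, [e2],
                                  CascadeConfig(fuse_lambda=1.0))
        iou_only = stage3_fused_match(preds, [None], dets, [None],
                                      CascadeConfig(fuse_lambda=1.0))
        assert pure.matches == iou_only.matches == ((0, 0),)

    def test_stage3_embedding_breaks_iou_tie(self):
        """Equal-IoU tracks: the appearance-similar one wins for lambda < 1."""
        d = BoundingBox(10, 0, 10, 10)
        preds = [BoundingBox(5, 0, 10, 10), BoundingBox(15, 0, 10, 10)]
        e_match = np.array([1.0, 0.0])
        e_other = np.array([0.0, 1.0])
        r = stage3_fused_match(preds, [e_other, e_match], [d], [e_match],
                               CascadeConfig(fuse_lambda=0.5))
        assert r.matches == ((1, 0),)


class TestCascade:
    def test_no_detections_leaves_all_unmatched(self):
        preds = [BoundingBox(0, 0, 10, 10)]
        r = run_cascade(preds, [None], [], CascadeConfig())
        assert r.matches == () and r.unmatched_tracks == (0,)

    def test_perfect_overlap_all_matched_in_stage1(self):
        preds = [BoundingBox(0, 0, 10, 10), BoundingBox(50, 50, 10, 10)]
        dets = [det(0, 0, 10, 10, 0.9), det(50, 50, 10, 10, 0.9)]
        r = run_cascade(preds, [None, None], dets, CascadeConfig())
        assert set(r.matches) == {(0, 0), (1, 1)}
        assert all(r.stage_of_match[m] == 1 for m in r.matches)

    def test_partition_of_inputs(self):
        rng = np.random.default_rng(3)
        preds = [BoundingBox(*rng.uniform(0, 200, 2), *rng.uniform(10, 40, 2))
                 for _ in range(5)]
        dets = [det(*rng.uniform(0, 200, 2), *rng.uniform(10, 40, 2),
                    float(rng.uniform(0, 1))) for _ in range(6)]
        r = run_cascade(preds, [None] * 5, dets, CascadeConfig())
        matched_t = [m[0] for m in r.matches]
        assert sorted(matched_t + list(r.unmatched_tracks)) == list(range(5))
        matched_d = [m[1] for m in r.matches]
        assert len(set(matched_d)) == len(matched_d)

    def test_stage2_recovers_zero_iou_near_center_pair(self):
        """Disjoint boxes with close centers match only when stage 2 runs."""
        pred = BoundingBox(0, 0, 10, 10)          # center (5, 5)
        d = det(11, 0, 10, 10, 0.9)               # center (16, 5): IoU = 0
        with_s2 = run_cascade([pred], [None], [d],
                              CascadeConfig(dist_gate_stage2=50.0))
        without_s2 = run_cascade([pred], [None], [d],
                                 CascadeConfig(dist_gate_stage2=50.0,
                                               enable_stage2=False))
        assert with_s2.matches == ((0, 0),)
        assert with_s2.stage_of_match[(0, 0)] == 2
        assert without_s2.matches == ()
        assert len(without_s2.unmatched_tracks) == 1

    @given(seed=st.integers(0, 500))
    def test_lowering_tau_low_never_loses_tracks(self, seed):
        """Admitting more low-confidence detections can only help."""
        rng = np.random.default_rng(seed)
        preds = [BoundingBox(*rng.uniform(0, 300, 2), *rng.uniform(20, 50, 2))
                 for _ in range(4)]
        dets = [det(p.left + rng.uniform(-5, 5), p.top + rng.uniform(-5, 5),
                    p.width, p.height, float(rng.uniform(0.05, 1.0)))
                for p in preds]
        hi = run_cascade(preds, [None] * 4, dets, CascadeConfig(tau_low=0.4))
        lo = run_cascade(preds, [None] * 4, dets, CascadeConfig(tau_low=0.05))
        assert len(lo.unmatched_tracks) <= len(hi.unmatched_tracks)

    def test_unmatched_low_detections_never_reported_for_birth(self):
        dets = [det(0, 0, 10, 10, 0.3)]
        r = run_cascade([], [], dets, CascadeConfig())
        assert r.unmatched_high == ()
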