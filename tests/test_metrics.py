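import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import boxes_to_tuples, track_scenario
from pentrack import simdata
from pentrack.geometry import BoundingBox
from pentrack.metrics import (UndefinedMetricError, clear_match, evaluate,
                              hota, idf1, identity_counts, mota, motp, mt_ml)
from reference_eval import ref_clear, ref_hota, ref_idf1

B = BoundingBox


def shifted(gt, dx=0.0, rename=None):
    """Copy ground truth as a hypothesis, optionally shifted / relabeled."""
    out = {}
    for t, fb in gt.items():
        out[t] = {}
        for i, b in fb.items():
            j = rename.get(i, i) if rename else i
            out[t][j] = B(b.left + dx, b.top, b.width, b.height)
    return out


def two_object_gt(n_frames=10):
    return {t: {1: B(0, 0, 10, 10), 2: B(100, 0, 10, 10)}
            for t in range(1, n_frames + 1)}


class TestClearMatch:
    def test_perfect_hypotheses(self):
        gt = two_object_gt()
        log = clear_match(gt, shifted(gt))
        assert log.fp == log.fn == log.idsw == 0
        assert log.num_matches == 20

    def test_empty_hypotheses(self):
        gt = two_object_gt()
        log = clear_match(gt, {})
        assert log.fn == 20 and log.fp == 0

    def test_id_swap_counts_two_switches(self):
        """Hypothesis ids swapped at frame 6 -> one switch per object."""
        gt = two_object_gt(10)
        hyp = {}
        for t in range(1, 11):
            ids = (1, 2) if t <= 5 else (2, 1)
            hyp[t] = {ids[0]: B(0, 0, 10, 10), ids[1]: B(100, 0, 10, 10)}
        log = clear_match(gt, hyp)
        assert log.idsw == 2
        assert log.fp == log.fn == 0

    def test_persistence_beats_greedy_overlap(self):
        """An established pair survives while it still clears the threshold,
        even when a new hypothesis overlaps the object more."""
        gt = {1: {1: B(0, 0, 10, 10)}, 2: {1: B(0, 0, 10, 10)}}
        hyp = {1: {7: B(1, 0, 10, 10)},
               2: {7: B(3, 0, 10, 10), 8: B(0, 0, 10, 10)}}
        log = clear_match(gt, hyp)
        assert [m[1] for m in log.matches[2]] == [7]
        assert log.idsw == 0

    def test_conservation_per_frame(self):
        gt = two_object_gt()
        hyp = shifted(gt, dx=2.0)
        del hyp[3][1]
        log = clear_match(gt, hyp)
        for t in log.frames:
            assert len(log.matches[t]) + log.fn_t[t] == len(gt.get(t, {}))
            assert len(log.matches[t]) + log.fp_t[t] == len(hyp.get(t, {}))


class TestMota:
    def test_perfect_is_one(self):
        gt = two_object_gt()
        assert mota(clear_match(gt, shifted(gt))) == 1.0

    def test_formula_values(self):
        # FN=1, FP=1, IDSW=0, GT=10 -> 0.8 (direct evaluation)
        gt = {t: {1: B(0, 0, 10, 10)} for t in range(1, 11)}
        hyp = {t: {1: B(0, 0, 10, 10)} for t in range(1, 10)}
        hyp[10] = {1: B(500, 500, 10, 10)}
        log = clear_match(gt, hyp)
        assert (log.fn, log.fp, log.idsw) == (1, 1, 0)
        assert mota(log) == pytest.approx(0.8)

    def test_can_go_negative(self):
        # FN=GT=5 and FP=10 -> 1 - 15/5 = -2
        gt = {t: {1: B(0, 0, 10, 10)} for t in range(1, 6)}
        hyp = {t: {1: B(500, 500, 5, 5), 2: B(600, 600, 5, 5)}
               for t in range(1, 6)}
        log = clear_match(gt, hyp)
        assert mota(log) == pytest.approx(-2.0)

    def test_undefined_without_gt(self):
        with pytest.raises(UndefinedMetricError):
            mota(clear_match({}, {1: {1: B(0, 0, 5, 5)}}))


class TestMotp:
    def test_perfect_overlap(self):
        gt = two_object_gt()
        assert motp(clear_match(gt, shifted(gt))) == pytest.approx(1.0)

    def test_mean_of_matched_ious(self):
        # two matches with IoU 0.6 and ~0.8 averaged
        gt = {1: {1: B(0, 0, 10, 10), 2: B(100, 0, 10, 10)}}
        hyp = {1: {1: B(2.5, 0, 10, 10), 2: B(101, 0, 10, 10)}}
        log = clear_match(gt, hyp)
        expected = (0.6 + 9 / 11) / 2
        assert motp(log) == pytest.approx(expected)

    def test_distance_variant(self):
        gt = {1: {1: B(0, 0, 100, 100)}}
        hyp = {1: {1: B(3, 4, 100, 100)}}
        log = clear_match(gt, hyp)
        assert motp(log, as_distance=True) == pytest.approx(5.0)

    def test_undefined_without_matches(self):
        gt = {1: {1: B(0, 0, 10, 10)}}
        with pytest.raises(UndefinedMetricError):
            motp(clear_match(gt, {}))


class TestIdf1:
    def test_perfect_tracking(self):
        gt = two_object_gt()
        assert idf1(gt, shifted(gt, rename={1: 7, 2: 9})) == 1.0

    def test_split_trajectory_is_half(self):
        """One object tracked as two 5-frame ids: IDTP=IDFP=IDFN=5 -> 0.5."""
        gt = {t: {1: B(0, 0, 10, 10)} for t in range(1, 11)}
        hyp = {t: {(1 if t <= 5 else 2): B(0, 0, 10, 10)}
               for t in range(1, 11)}
        c = identity_counts(gt, hyp)
        assert (c.IDTP, c.IDFP, c.IDFN) == (5, 5, 5)
        assert idf1(gt, hyp) == pytest.approx(0.5)

    def test_empty_hypotheses_zero(self):
        gt = two_object_gt()
        assert idf1(gt, {}) == 0.0

    def test_relabeling_invariance(self):
        gt = two_object_gt()
        hyp = shifted(gt, dx=1.0)
        relabeled = shifted(gt, dx=1.0, rename={1: 42, 2: 17})
        assert idf1(gt, hyp) == pytest.approx(idf1(gt, relabeled))


class TestHota:
    def test_perfect_tracking_is_one(self):
        gt = two_object_gt()
        score, comps = hota(gt, shifted(gt))
        assert score == pytest.approx(1.0)
        assert np.allclose(comps.det_a, 1.0) and np.allclose(comps.ass_a, 1.0)

    def test_empty_hypotheses_zero(self):
        gt = two_object_gt()
        score, _ = hota(gt, {})
        assert score == 0.0

    def test_half_coverage_hand_value(self):
        """Perfect boxes in 5 of 10 frames: DetA=0.5, AssA=0.5, HOTA=0.5."""
        gt = {t: {1: B(0, 0, 10, 10)} for t in range(1, 11)}
        hyp = {t: {1: B(0, 0, 10, 10)} for t in range(1, 6)}
        score, comps = hota(gt, hyp)
        assert np.allclose(comps.det_a, 0.5)
        assert np.allclose(comps.ass_a, 0.5)
        assert score == pytest.approx(0.5)

    def test_no_sqrt_variant_is_product(self):
        gt = {t: {1: B(0, 0, 10, 10)} for t in range(1, 11)}
        hyp = {t: {1: B(0, 0, 10, 10)} for t in range(1, 6)}
        score, _ = hota(gt, hyp, use_sqrt=False)
        assert score == pytest.approx(0.25)

    def test_matches_naive_reference_on_small_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            gt, hyp = {}, {}
            for t in range(1, 13):
                gt[t] = {i: B(*rng.uniform(0, 80, 2), *rng.uniform(10, 30, 2))
                         for i in (1, 2)}
                hyp[t] = {}
                for i in (1, 2):
                    if rng.random() < 0.8:
                        b = gt[t][i]
                        j = i if rng.random() < 0.9 else 3 - i
                        hyp[t][j] = B(b.left + rng.normal(0, 3),
                                      b.top + rng.normal(0, 3),
                                      b.width, b.height)
            score, _ = hota(gt, hyp)
            expected = ref_hota(boxes_to_tuples(gt), boxes_to_tuples(hyp))
            assert score == pytest.approx(expected, abs=1e-9)


class TestMtMl:
    def test_fully_tracked(self):
        gt = two_object_gt()
        log = clear_match(gt, shifted(gt))
        assert mt_ml(log) == (2, 0)

    def test_empty_hypotheses_all_lost(self):
        gt = two_object_gt()
        log = clear_match(gt, {})
        assert mt_ml(log) == (0, 2)

    def test_half_tracked_in_neither(self):
        gt = {t: {1: B(0, 0, 10, 10)} for t in range(1, 11)}
        hyp = {t: {1: B(0, 0, 10, 10)} for t in range(1, 6)}
        log = clear_match(gt, hyp)
        assert mt_ml(log) == (0, 0)


class TestOracleAgreement:
    """The full suite against the independent naive reference evaluator."""

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=8, deadline=None)
    def test_clear_suite_matches_reference_on_tracked_scenarios(self, seed):
        cfg = dataclasses.replace(
            simdata.day_night_presets(seed)["day"], n_identities=4,
            n_frames=40, pen_width=640.0, pen_height=480.0,
            detector_miss_base=0.1, fp_rate=0.3)
        gt, hyp = track_scenario(cfg)
        ref = ref_clear(boxes_to_tuples(gt), boxes_to_tuples(hyp))
        log = clear_match(gt, hyp)
        assert log.fp == ref["FP"] and log.fn == ref["FN"]
        assert log.idsw == ref["IDSW"]
        assert mota(log) == pytest.approx(ref["MOTA"], abs=1e-6)
        if log.num_matches:
            assert motp(log) == pytest.approx(ref["MOTP"], abs=1e-6)
        assert mt_ml(log) == (ref["MT"], ref["ML"])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=8, deadline=None)
    def test_idf1_matches_reference(self, seed):
        cfg = dataclasses.replace(
            simdata.day_night_presets(seed)["day"], n_identities=3,
            n_frames=40, pen_width=640.0, pen_height=480.0)
        gt, hyp = track_scenario(cfg)
        expected, _ = ref_idf1(boxes_to_tuples(gt), boxes_to_tuples(hyp))
        assert idf1(gt, hyp) == pytest.approx(expected, abs=1e-6)


def test_evaluate_report_is_consistent():
    gt = two_object_gt()
    rep = evaluate(gt, shifted(gt))
    d = rep.as_dict()
    assert d["MOTA"] == 1.0 and d["IDF1"] == 1.0 and d["IDS"] == 0
    assert d["GT"] == 20
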