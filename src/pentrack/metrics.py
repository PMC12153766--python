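"""Multi-object tracking evaluation: CLEAR-MOT, identity metrics and HOTA.

Inputs are frame-indexed box sets: ``{frame: {identity: BoundingBox}}`` for
both ground truth and hypotheses.  The module computes

* the CLEAR correspondence protocol (:func:`clear_match`) and from it
  MOTA = 1 - (FN + FP + IDSW) / GT, MOTP, and mostly-tracked /
  mostly-lost trajectory counts;
* IDF1 = 2 IDTP / (2 IDTP + IDFP + IDFN) from the optimal global bijection
  between ground-truth and hypothesis identities;
* HOTA, the mean over 19 IoU thresholds alpha in {0.05, ..., 0.95} of
  sqrt(DetA_alpha * AssA_alpha).

CLEAR matching keeps correspondences alive across frames: a pair matched in
frame t-1 stays matched in frame t whenever its IoU still clears the
threshold; only the remainder is re-matched by minimum ``1 - IoU``
assignment.  An identity switch is logged when a ground-truth identity's
matched hypothesis id differs from its most recent previous match, even
across a gap.

MOTP is reported as the mean IoU of matched pairs (higher is better); the
``as_distance`` variant instead averages center distance in pixels, the
literal distance-ratio reading of the metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import solve_assignment
from .geometry import BoundingBox, iou_matrix, center_distance_matrix

FrameBoxes = dict[int, dict[int, BoundingBox]]

HOTA_ALPHAS = np.arange(0.05, 0.96, 0.05)  # 19 thresholds


class UndefinedMetricError(ValueError):
    """The metric's denominator is empty (no ground truth / no matches)."""


@dataclass
class FrameEventLog:
    """Per-frame CLEAR matching outcomes and their sequence totals."""

    iou_threshold: float
    frames: list[int] = field(default_factory=list)
    # per frame: list of (gt_id, hyp_id, iou, center_distance)
    matches: dict[int, list[tuple[int, int, float, float]]] = field(default_factory=dict)
    fp_t: dict[int, int] = field(default_factory=dict)
    fn_t: dict[int, int] = field(default_factory=dict)
    idsw_t: dict[int, int] = field(default_factory=dict)
    num_gt_boxes: int = 0
    num_hyp_boxes: int = 0
    # per gt identity: frames present / frames matched
    gt_frames_present: dict[int, int] = field(default_factory=dict)
    gt_frames_matched: dict[int, int] = field(default_factory=dict)

    @property
    def fp(self) -> int:
        return sum(self.fp_t.values())

    @property
    def fn(self) -> int:
        return sum(self.fn_t.values())

    @property
    def idsw(self) -> int:
        return sum(self.idsw_t.values())

    @property
    def num_matches(self) -> int:
        return sum(len(m) for m in self.matches.values())


def _check_frames(frames: FrameBoxes, what: str) -> None:
    for t, boxes in frames.items():
        if not isinstance(boxes, dict):
            raise TypeError(f"{what} frame {t} must map identity -> box")


def clear_match(gt_frames: FrameBoxes, hyp_frames: FrameBoxes,
                iou_threshold: float = 0.5) -> FrameEventLog:
    """Run the CLEAR correspondence protocol over a whole sequence."""
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    _check_frames(gt_frames, "ground-truth")
    _check_frames(hyp_frames, "hypothesis")
    log = FrameEventLog(iou_threshold=iou_threshold)
    all_frames = sorted(set(gt_frames) | set(hyp_frames))
    prev_pairing: dict[int, int] = {}    # gt_id -> hyp_id matched in t-1
    last_match: dict[int, int] = {}      # gt_id -> most recent hyp_id ever
    for t in all_frames:
        gt = gt_frames.get(t, {})
        hyp = hyp_frames.get(t, {})
        gt_ids = sorted(gt)
        hyp_ids = sorted(hyp)
        log.frames.append(t)
        log.num_gt_boxes += len(gt_ids)
        log.num_hyp_boxes += len(hyp_ids)
        for g in gt_ids:
            log.gt_frames_present[g] = log.gt_frames_present.get(g, 0) + 1

        ious = iou_matrix([gt[g] for g in gt_ids], [hyp[h] for h in hyp_ids])
        pairs: list[tuple[int, int]] = []
        # 1. persist surviving correspondences
        used_g: set[int] = set()
        used_h: set[int] = set()
        for g, h in prev_pairing.items():
            if g in gt and h in hyp:
                gi, hi = gt_ids.index(g), hyp_ids.index(h)
                if ious[gi, hi] >= iou_threshold:
                    pairs.append((gi, hi))
                    used_g.add(gi)
                    used_h.add(hi)
        # 2. match the remainder by minimum 1 - IoU
        free_g = [i for i in range(len(gt_ids)) if i not in used_g]
        free_h = [j for j in range(len(hyp_ids)) if j not in used_h]
        if free_g and free_h:
            sub = 1.0 - ious[np.ix_(free_g, free_h)]
            res = solve_assignment(sub, 1.0 - iou_threshold)
            for ri, cj in res.matches:
                pairs.append((free_g[ri], free_h[cj]))

        frame_matches: list[tuple[int, int, float, float]] = []
        idsw = 0
        new_pairing: dict[int, int] = {}
        for gi, hi in sorted(pairs):
            g, h = gt_ids[gi], hyp_ids[hi]
            d = float(center_distance_matrix([gt[g]], [hyp[h]])[0, 0])
            frame_matches.append((g, h, float(ious[gi, hi]), d))
            if g in last_match and last_match[g] != h:
                idsw += 1
            last_match[g] = h
            new_pairing[g] = h
            log.gt_frames_matched[g] = log.gt_frames_matched.get(g, 0) + 1
        log.matches[t] = frame_matches
        log.fn_t[t] = len(gt_ids) - len(pairs)
        log.fp_t[t] = len(hyp_ids) - len(pairs)
        log.idsw_t[t] = idsw
        prev_pairing = new_pairing
    return log


def mota(log: FrameEventLog) -> float:
    """Multi-object tracking accuracy: ``1 - (FN + FP + IDSW) / GT``."""
    if log.num_gt_boxes == 0:
        raise UndefinedMetricError("MOTA undefined with no ground-truth boxes")
    return 1.0 - (log.fn + log.fp + log.idsw) / log.num_gt_boxes


def motp(log: FrameEventLog, as_distance: bool = False) -> float:
    """Mean localization quality of matched pairs.

    Default: mean IoU (higher is better).  ``as_distance=True`` returns the
    mean center distance in pixels instead (lower is better).
    """
    n = log.num_matches
    if n == 0:
        raise UndefinedMetricError("MOTP undefined with no matched pairs")
    idx = 3 if as_distance else 2
    total = sum(m[idx] for ms in log.matches.values() for m in ms)
    return total / n


def mt_ml(log: FrameEventLog, mt_threshold: float = 0.8,
          ml_threshold: float = 0.2) -> tuple[int, int]:
    """Mostly-tracked / mostly-lost ground-truth trajectory counts.

    A trajectory is MT when matched in >= 80% of its frames and ML when
    matched in <= 20%.
    """
    mt = ml = 0
    for g, present in log.gt_frames_present.items():
        ratio = log.gt_frames_matched.get(g, 0) / present
        if ratio >= mt_threshold:
            mt += 1
        elif ratio <= ml_threshold:
            ml += 1
    return mt, ml


@dataclass(frozen=True)
class IdentityCounts:
    IDTP: int
    IDFP: int
    IDFN: int


def identity_counts(gt_frames: FrameBoxes, hyp_frames: FrameBoxes,
                    iou_threshold: float = 0.5) -> IdentityCounts:
    """Identity TP/FP/FN under the optimal global identity bijection.

    For every (gt identity, hypothesis identity) pair, count the frames
    where both are present and their boxes overlap at least
    ``iou_threshold``.  The bijection maximizing the summed counts defines
    IDTP; all remaining gt boxes are IDFN and remaining hypothesis boxes
    IDFP.
    """
    _check_frames(gt_frames, "ground-truth")
    _check_frames(hyp_frames, "hypothesis")
    gt_ids = sorted({g for boxes in gt_frames.values() for g in boxes})
    hyp_ids = sorted({h for boxes in hyp_frames.values() for h in boxes})
    gt_total = sum(len(b) for b in gt_frames.values())
    hyp_total = sum(len(b) for b in hyp_frames.values())
    overlap = np.zeros((len(gt_ids), len(hyp_ids)))
    g_index = {g: i for i, g in enumerate(gt_ids)}
    h_index = {h: j for j, h in enumerate(hyp_ids)}
    for t in sorted(set(gt_frames) & set(hyp_frames)):
        gt = gt_frames[t]
        hyp = hyp_frames[t]
        gs = sorted(gt)
        hs = sorted(hyp)
        ious = iou_matrix([gt[g] for g in gs], [hyp[h] for h in hs])
        hits = ious >= iou_threshold
        for gi, g in enumerate(gs):
            for hi, h in enumerate(hs):
                if hits[gi, hi]:
                    overlap[g_index[g], h_index[h]] += 1
    if overlap.size:
        res = solve_assignment(-overlap, gate=0.0)  # maximize summed overlap
        idtp = int(sum(overlap[r, c] for r, c in res.matches))
    else:
        idtp = 0
    return IdentityCounts(IDTP=idtp, IDFP=hyp_total - idtp, IDFN=gt_total - idtp)


def idf1(gt_frames: FrameBoxes, hyp_frames: FrameBoxes,
         iou_threshold: float = 0.5) -> float:
    """Identity F1: ``2 IDTP / (2 IDTP + IDFP + IDFN)``."""
    c = identity_counts(gt_frames, hyp_frames, iou_threshold)
    denom = 2 * c.IDTP + c.IDFP + c.IDFN
    if denom == 0:
        raise UndefinedMetricError("IDF1 undefined with no boxes at all")
    return 2 * c.IDTP / denom


@dataclass(frozen=True)
class HotaComponents:
    """Per-threshold detection and association accuracies."""

    alphas: np.ndarray        # the 19 IoU thresholds
    det_a: np.ndarray         # DetA_alpha in [0, 1]
    ass_a: np.ndarray         # AssA_alpha in [0, 1]

    def scores(self, use_sqrt: bool = True) -> np.ndarray:
        prod = self.det_a * self.ass_a
        return np.sqrt(prod) if use_sqrt else prod


def hota(gt_frames: FrameBoxes, hyp_frames: FrameBoxes,
         use_sqrt: bool = True) -> tuple[float, HotaComponents]:
    """Higher-order tracking accuracy averaged over 19 IoU thresholds.

    Per threshold alpha, frames are matched by a Hungarian assignment whose
    score favors pairs with high global spatio-temporal alignment (the
    standard two-pass protocol), giving TP/FN/FP counts and, for every TP,
    the association accuracy of its identity pair.  The per-threshold score
    is ``sqrt(DetA * AssA)`` (``use_sqrt=False`` gives the plain product),
    and the final value is the mean over thresholds.
    """
    _check_frames(gt_frames, "ground-truth")
    _check_frames(hyp_frames, "hypothesis")
    gt_ids = sorted({g for boxes in gt_frames.values() for g in boxes})
    hyp_ids = sorted({h for boxes in hyp_frames.values() for h in boxes})
    n_gt_boxes = sum(len(b) for b in gt_frames.values())
    n_hyp_boxes = sum(len(b) for b in hyp_frames.values())
    if n_gt_boxes == 0 and n_hyp_boxes == 0:
        raise UndefinedMetricError("HOTA undefined on empty inputs")
    g_index = {g: i for i, g in enumerate(gt_ids)}
    h_index = {h: j for j, h in enumerate(hyp_ids)}
    all_frames = sorted(set(gt_frames) | set(hyp_frames))

    # pass 1: global alignment score between every identity pair
    potential = np.zeros((len(gt_ids), len(hyp_ids)))
    gt_count = np.zeros(len(gt_ids))
    hyp_count = np.zeros(len(hyp_ids))
    per_frame: list[tuple[list[int], list[int], np.ndarray]] = []
    for t in all_frames:
        gs = sorted(gt_frames.get(t, {}))
        hs = sorted(hyp_frames.get(t, {}))
        sim = iou_matrix([gt_frames[t][g] for g in gs] if gs else [],
                         [hyp_frames[t][h] for h in hs] if hs else [])
        per_frame.append((gs, hs, sim))
        gi = [g_index[g] for g in gs]
        hi = [h_index[h] for h in hs]
        if gi:
            gt_count[gi] += 1
        if hi:
            hyp_count[hi] += 1
        if gi and hi:
            denom = sim.sum(0)[None, :] + sim.sum(1)[:, None] - sim
            frac = np.zeros_like(sim)
            mask = denom > 1e-12
            frac[mask] = sim[mask] / denom[mask]
            potential[np.ix_(gi, hi)] += frac
    if len(gt_ids) and len(hyp_ids):
        align = potential / (gt_count[:, None] + hyp_count[None, :] - potential)
    else:
        align = np.zeros((len(gt_ids), len(hyp_ids)))

    # pass 2: per-frame matching (alignment-weighted IoU), counts per alpha
    n_a = len(HOTA_ALPHAS)
    tp = np.zeros(n_a)
    match_count = [np.zeros((len(gt_ids), len(hyp_ids))) for _ in range(n_a)]
    eps = np.finfo(float).eps
    for gs, hs, sim in per_frame:
        if not gs or not hs:
            continue
        gi = np.array([g_index[g] for g in gs])
        hi = np.array([h_index[h] for h in hs])
        score = align[np.ix_(gi, hi)] * sim
        rows, cols = _lsa_max(score)
        for a, alpha in enumerate(HOTA_ALPHAS):
            ok = sim[rows, cols] >= alpha - eps
            tp[a] += int(ok.sum())
            match_count[a][gi[rows[ok]], hi[cols[ok]]] += 1

    det_a = np.zeros(n_a)
    ass_a = np.zeros(n_a)
    for a in range(n_a):
        fn = n_gt_boxes - tp[a]
        fp = n_hyp_boxes - tp[a]
        det_a[a] = tp[a] / max(tp[a] + fn + fp, eps)
        if tp[a] > 0:
            mc = match_count[a]
            pair_ass = mc / (gt_count[:, None] + hyp_count[None, :] - mc)
            ass_a[a] = float((mc * pair_ass).sum() / tp[a])
    comps = HotaComponents(HOTA_ALPHAS.copy(), det_a, ass_a)
    return float(comps.scores(use_sqrt).mean()), comps


def _lsa_max(score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy.optimize import linear_sum_assignment
    rows, cols = linear_sum_assignment(-score)
    return rows, cols


@dataclass(frozen=True)
class MetricReport:
    """Full evaluation summary for one sequence."""

    mota: float
    motp: float
    idf1: float
    hota: float
    mt: int
    ml: int
    fp: int
    fn: int
    idsw: int
    num_gt: int

    def as_dict(self) -> dict[str, float | int]:
        return {
            "MOTA": self.mota, "MOTP": self.motp, "IDF1": self.idf1,
            "HOTA": self.hota, "MT": self.mt, "ML": self.ml,
            "FP": self.fp, "FN": self.fn, "IDS": self.idsw,
            "GT": self.num_gt,
        }


def evaluate(gt_frames: FrameBoxes, hyp_frames: FrameBoxes,
             iou_threshold: float = 0.5, motp_as_distance: bool = False,
             hota_sqrt: bool = True) -> MetricReport:
    """Compute the full metric suite for one sequence."""
    log = clear_match(gt_frames, hyp_frames, iou_threshold)
    mt, ml = mt_ml(log)
    hota_val, _ = hota(gt_frames, hyp_frames, use_sqrt=hota_sqrt)
    try:
        motp_val = motp(log, as_distance=motp_as_distance)
    except UndefinedMetricError:
        motp_val = float("nan")
    return MetricReport(
        mota=mota(log), motp=motp_val,
        idf1=idf1(gt_frames, hyp_frames, iou_threshold),
        hota=hota_val, mt=mt, ml=ml,
        fp=log.fp, fn=log.fn, idsw=log.idsw, num_gt=log.num_gt_boxes)
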