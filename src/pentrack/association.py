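"""Three-stage detection-to-track association cascade.

Detections are first split by confidence into a high group
(``conf >= tau_high``), a low group (``tau_low <= conf < tau_high``) and a
discarded remainder.  The cascade then runs:

1. **IoU stage** — high-confidence detections vs. all live tracks, cost
   ``1 - IoU`` on Kalman-predicted boxes, gated so pairs below a minimum
   overlap are ineligible.
2. **Center-distance stage** — the stage-1 leftovers re-associated on raw
   pixel Euclidean distance between box centers.  This recovers pairs whose
   boxes barely overlap (typical under partial occlusion) but whose
   predicted and detected centers are close.
3. **Fused stage** — remaining tracks vs. *low*-confidence detections, cost
   a convex combination of ``1 - IoU`` and (clipped) embedding cosine
   distance, so a weak occluded detection can still be claimed by the track
   whose appearance it matches.

Each stage solves a gated minimum-cost bipartite assignment (Hungarian
algorithm).  Unmatched low-confidence detections are discarded and never
start new tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import (BoundingBox, center_distance_matrix,
                       cosine_distance_matrix, iou_matrix)

# penalty placed on gated-out pairs; large enough that the solver always
# prefers any number of eligible matches over one ineligible one
_BIG = 1e9


class ConfigurationError(ValueError):
    """Cascade configuration violates its invariants."""


@dataclass(frozen=True)
class Detection:
    """One detector output at one frame."""

    box: BoundingBox
    confidence: float
    embedding: np.ndarray | None = None
    frame_index: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.frame_index < 1:
            raise ValueError(f"frame_index must be >= 1, got {self.frame_index}")
        if self.embedding is not None:
            emb = np.asarray(self.embedding, float)
            if emb.ndim != 1 or not np.all(np.isfinite(emb)):
                raise ValueError("embedding must be a finite 1-D vector")
            object.__setattr__(self, "embedding", emb)


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of one bipartite matching: matched pairs plus leftovers.

    Rows are track indices, columns detection indices; every input index
    appears exactly once across the three fields.
    """

    matches: tuple[tuple[int, int], ...]
    unmatched_rows: tuple[int, ...]
    unmatched_cols: tuple[int, ...]


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and gates of the three-stage cascade.

    ``dist_gate_stage2=None`` selects the adaptive default: half the mean
    diagonal of the candidate tracks' predicted boxes, which keeps the gate
    scale-aware without depending on image size.
    """

    tau_high: float = 0.6
    tau_low: float = 0.1
    iou_gate_stage1: float = 0.3
    dist_gate_stage2: float | None = None
    fuse_lambda: float = 0.5
    fused_gate_stage3: float = 0.5
    enable_stage2: bool = True
    enable_stage3: bool = True
    stage2_include_low: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_low < self.tau_high <= 1.0:
            raise ConfigurationError(
                f"need 0 <= tau_low < tau_high <= 1, got "
                f"tau_low={self.tau_low}, tau_high={self.tau_high}")
        if not 0.0 <= self.iou_gate_stage1 <= 1.0:
            raise ConfigurationError("iou_gate_stage1 must lie in [0, 1]")
        if self.dist_gate_stage2 is not None and not (
                np.isfinite(self.dist_gate_stage2) and self.dist_gate_stage2 >= 0):
            raise ConfigurationError("dist_gate_stage2 must be finite and >= 0")
        if not 0.0 <= self.fuse_lambda <= 1.0:
            raise ConfigurationError("fuse_lambda must lie in [0, 1]")
        if not (np.isfinite(self.fused_gate_stage3) and self.fused_gate_stage3 >= 0):
            raise ConfigurationError("fused_gate_stage3 must be finite and >= 0")


def split_by_confidence(dets: list[Detection], cfg: CascadeConfig
                        ) -> tuple[list[int], list[int]]:
    """Partition detection indices into (high, low); the rest are discarded.

    High: ``conf >= tau_high``; low: ``tau_low <= conf < tau_high``.
    """
    high = [i for i, d in enumerate(dets) if d.confidence >= cfg.tau_high]
    low = [i for i, d in enumerate(dets)
           if cfg.tau_low <= d.confidence < cfg.tau_high]
    return high, low


def solve_assignment(cost: np.ndarray, gate: float) -> AssignmentResult:
    """Gated minimum-cost one-to-one assignment.

    Pairs with ``cost > gate`` are ineligible.  Among eligible pairs the
    returned assignment has maximum cardinality and, at that cardinality,
    minimum total cost (ineligible entries are replaced by a penalty that
    dominates any sum of eligible costs before solving).
    """
    cost = np.asarray(cost, float)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    n_rows, n_cols = cost.shape
    if n_rows == 0 or n_cols == 0:
        return AssignmentResult((), tuple(range(n_rows)), tuple(range(n_cols)))
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    padded = np.where(cost <= gate, cost, _BIG)
    rows, cols = linear_sum_assignment(padded)
    matches = tuple((int(r), int(c)) for r, c in zip(rows, cols)
                    if cost[r, c] <= gate)
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    return AssignmentResult(
        matches,
        tuple(r for r in range(n_rows) if r not in matched_r),
        tuple(c for c in range(n_cols) if c not in matched_c))


def stage1_iou_match(pred_boxes: list[BoundingBox], det_boxes: list[BoundingBox],
                     cfg: CascadeConfig) -> AssignmentResult:
    """High-confidence matching on ``1 - IoU`` between predictions and detections."""
    cost = 1.0 - iou_matrix(pred_boxes, det_boxes)
    return solve_assignment(cost, 1.0 - cfg.iou_gate_stage1)


def stage2_gate(pred_boxes: list[BoundingBox], cfg: CascadeConfig) -> float:
    """Resolve the stage-2 distance gate (adaptive: half mean box diagonal)."""
    if cfg.dist_gate_stage2 is not None:
        return cfg.dist_gate_stage2
    if not pred_boxes:
        return 0.0
    return 0.5 * float(np.mean([b.diagonal for b in pred_boxes]))


def stage2_euclid_match(pred_boxes: list[BoundingBox], det_boxes: list[BoundingBox],
                        cfg: CascadeConfig) -> AssignmentResult:
    """Re-association of stage-1 leftovers on raw center distance in pixels."""
    cost = center_distance_matrix(pred_boxes, det_boxes)
    return solve_assignment(cost, stage2_gate(pred_boxes, cfg))


def fused_cost_matrix(pred_boxes: list[BoundingBox],
                      track_embeddings: list[np.ndarray | None],
                      det_boxes: list[BoundingBox],
                      det_embeddings: list[np.ndarray | None],
                      fuse_lambda: float) -> np.ndarray:
    """``lam * (1 - IoU) + (1 - lam) * min(cosine_distance, 1)``.

    The cosine term is clipped to [0, 1] so both terms share a scale.  Pairs
    where either side lacks an embedding fall back to the pure IoU cost.
    """
    iou_cost = 1.0 - iou_matrix(pred_boxes, det_boxes)
    cost = np.array(iou_cost, float)
    for i, temb in enumerate(track_embeddings):
        if temb is None:
            continue
        for j, demb in enumerate(det_embeddings):
            if demb is None:
                continue
            app = min(float(cosine_distance_matrix(temb[None, :], demb[None, :])[0, 0]), 1.0)
            cost[i, j] = fuse_lambda * iou_cost[i, j] + (1.0 - fuse_lambda) * app
    return cost


def stage3_fused_match(pred_boxes: list[BoundingBox],
                       track_embeddings: list[np.ndarray | None],
                       det_boxes: list[BoundingBox],
                       det_embeddings: list[np.ndarray | None],
                       cfg: CascadeConfig) -> AssignmentResult:
    """Low-confidence matching on the fused IoU + appearance cost."""
    cost = fused_cost_matrix(pred_boxes, track_embeddings, det_boxes,
                             det_embeddings, cfg.fuse_lambda)
    return solve_assignment(cost, cfg.fused_gate_stage3)


@dataclass(frozen=True)
class CascadeResult:
    """Aggregate outcome of the full cascade on one frame.

    ``matches`` maps track indices to detection indices *into the original
    detection list*; ``unmatched_high`` are the high-confidence detections
    eligible to start new tracks.
    """

    matches: tuple[tuple[int, int], ...]
    unmatched_tracks: tuple[int, ...]
    unmatched_high: tuple[int, ...]
    stage_of_match: dict[tuple[int, int], int] = field(default_factory=dict)


def run_cascade(pred_boxes: list[BoundingBox],
                track_embeddings: list[np.ndarray | None],
                dets: list[Detection],
                cfg: CascadeConfig) -> CascadeResult:
    """Run the full three-stage cascade for one frame.

    ``pred_boxes[i]`` is track *i*'s Kalman-predicted box for this frame and
    ``track_embeddings[i]`` its appearance template (or ``None``).  Returns
    index-based matches; unmatched low-confidence detections are discarded.
    """
    if len(pred_boxes) != len(track_embeddings):
        raise ValueError("one embedding slot per track required")
    high_idx, low_idx = split_by_confidence(dets, cfg)
    if cfg.stage2_include_low:
        stage2_extra = list(low_idx)
    else:
        stage2_extra = []

    matches: list[tuple[int, int]] = []
    stage_of: dict[tuple[int, int], int] = {}
    track_ids = list(range(len(pred_boxes)))

    # stage 1: high detections, IoU
    r1 = stage1_iou_match([pred_boxes[t] for t in track_ids],
                          [dets[j].box for j in high_idx], cfg)
    for ti, dj in r1.matches:
        pair = (track_ids[ti], high_idx[dj])
        matches.append(pair)
        stage_of[pair] = 1
    rem_tracks = [track_ids[i] for i in r1.unmatched_rows]
    rem_high = [high_idx[j] for j in r1.unmatched_cols]

    # stage 2: leftovers, center distance
    if cfg.enable_stage2:
        cand_dets = rem_high + stage2_extra
        r2 = stage2_euclid_match([pred_boxes[t] for t in rem_tracks],
                                 [dets[j].box for j in cand_dets], cfg)
        for ti, dj in r2.matches:
            pair = (rem_tracks[ti], cand_dets[dj])
            matches.append(pair)
            stage_of[pair] = 2
        matched_d = {cand_dets[dj] for _, dj in r2.matches}
        rem_tracks = [rem_tracks[i] for i in r2.unmatched_rows]
        rem_high = [j for j in rem_high if j not in matched_d]
        stage2_extra = [j for j in stage2_extra if j not in matched_d]

    # stage 3: remaining tracks vs low detections, fused cost
    if cfg.enable_stage3:
        cand_low = [j for j in low_idx if j in set(stage2_extra)] \
            if cfg.stage2_include_low else list(low_idx)
        r3 = stage3_fused_match(
            [pred_boxes[t] for t in rem_tracks],
            [track_embeddings[t] for t in rem_tracks],
            [dets[j].box for j in cand_low],
            [dets[j].embedding for j in cand_low], cfg)
        for ti, dj in r3.matches:
            pair = (rem_tracks[ti], cand_low[dj])
            matches.append(pair)
            stage_of[pair] = 3
        rem_tracks = [rem_tracks[i] for i in r3.unmatched_rows]

    return CascadeResult(tuple(sorted(matches)), tuple(rem_tracks),
                         tuple(rem_high), stage_of)


def cascade_config_with(cfg: CascadeConfig, **overrides) -> CascadeConfig:
    """Return a copy of ``cfg`` with the given fields replaced."""
    return replace(cfg, **overrides)
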