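"""Synthetic pen scenarios: ground-truth trajectories + a detector emulator.

The generator emulates a fixed top-down camera over a rectangular pen
holding 2-20 animals.  Each identity follows a reflected correlated random
walk (a persistent heading with Gaussian turning noise, reflecting off the
pen walls) with a fixed per-identity box size drawn once.  Occlusion
episodes — intervals where one animal's box overlaps another's — are
injected by briefly steering a "chaser" toward a randomly chosen partner at
a configurable rate; an animal's visibility at a frame is one minus the
largest fraction of its own box covered by any other animal.

On top of the ground truth, a detector emulator produces the per-frame
detection stream: boxes are dropped with a miss probability interpolating
between a base rate and an (occluded) higher rate as visibility falls,
survivors are jittered and given confidences centered on a visibility
dependent mean, uniform false positives are added, and every detection
carries a unit-norm embedding built from the identity's prototype vector
plus visibility-dependent Gaussian noise (false positives get random
embeddings).

Two presets, ``day`` and ``night``, mirror the two detector-quality regimes
of farm recordings: daytime footage with a reliable detector, and denser
nighttime footage with frequent misses, low confidences and noisy
appearance features.

All randomness flows through one ``numpy`` generator seeded from the
scenario config, so a scenario is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .association import Detection
from .geometry import BoundingBox

FrameBoxes = dict[int, dict[int, BoundingBox]]


class PackingError(ValueError):
    """The pen cannot hold the requested number of animals."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic pen world and its detector emulator.

    Distances are in pixels, rates per frame unless stated otherwise;
    ``occlusion_rate`` is the expected number of overlap episodes per 100
    frames across the whole pen.
    """

    n_identities: int = 6
    pen_width: float = 1280.0
    pen_height: float = 720.0
    n_frames: int = 200
    speed_scale: float = 4.0
    direction_persistence: float = 0.9
    occlusion_rate: float = 4.0
    detector_miss_base: float = 0.03
    detector_miss_occluded: float = 0.4
    fp_rate: float = 0.1
    box_jitter_std: float = 1.0
    confidence_mean_visible: float = 0.85
    confidence_mean_occluded: float = 0.4
    embedding_dim: int = 16
    embedding_noise_std: float = 0.1
    embedding_noise_occluded_std: float = 0.3
    seed: int = 0
    box_size_range: tuple[float, float] = (70.0, 110.0)
    box_aspect_range: tuple[float, float] = (0.6, 1.6)

    def __post_init__(self) -> None:
        if not 2 <= self.n_identities <= 20:
            raise ValueError("n_identities must lie in [2, 20]")
        for name in ("detector_miss_base", "detector_miss_occluded",
                     "direction_persistence", "confidence_mean_visible",
                     "confidence_mean_occluded"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.detector_miss_occluded < self.detector_miss_base:
            raise ValueError("detector_miss_occluded must be >= detector_miss_base")
        if self.embedding_noise_occluded_std < self.embedding_noise_std:
            raise ValueError(
                "embedding_noise_occluded_std must be >= embedding_noise_std")
        if self.n_frames < 1 or self.embedding_dim < 1:
            raise ValueError("n_frames and embedding_dim must be >= 1")
        max_box = self.box_size_range[1]
        if self.n_identities * max_box * max_box > self.pen_width * self.pen_height:
            raise PackingError(
                f"pen {self.pen_width}x{self.pen_height} cannot hold "
                f"{self.n_identities} boxes of size up to {max_box}")


@dataclass(frozen=True)
class GroundTruthSet:
    """Per-frame, per-identity boxes and visibility fractions (1 = unoccluded)."""

    boxes: FrameBoxes
    visibility: dict[int, dict[int, float]]
    config: ScenarioConfig


def _fractional_overlap(a: BoundingBox, b: BoundingBox) -> float:
    """Fraction of a's area covered by b."""
    return a.intersection_area(b) / a.area


def simulate_ground_truth(cfg: ScenarioConfig) -> GroundTruthSet:
    """Generate reflected correlated-random-walk trajectories in the pen.

    Identities are 1..n; every identity is present in every frame (animals
    never leave the pen) and boxes are clamped inside the pen bounds.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_identities
    # fixed per-identity box sizes
    widths = rng.uniform(*cfg.box_size_range, size=n)
    aspects = rng.uniform(*cfg.box_aspect_range, size=n)
    heights = widths / aspects
    # spawn on a jittered grid to avoid initial overlap where possible
    cells = math.ceil(math.sqrt(n))
    cw, ch = cfg.pen_width / cells, cfg.pen_height / cells
    order = rng.permutation(cells * cells)[:n]
    pos = np.empty((n, 2))
    for i, cell in enumerate(order):
        r, c = divmod(int(cell), cells)
        pos[i] = (c * cw + cw / 2 + rng.uniform(-cw / 8, cw / 8),
                  r * ch + ch / 2 + rng.uniform(-ch / 8, ch / 8))
    heading = rng.uniform(0, 2 * np.pi, size=n)
    speed = cfg.speed_scale * rng.uniform(0.6, 1.4, size=n)
    turn_std = (1.0 - cfg.direction_persistence) * np.pi

    # occlusion steering: Poisson episode starts at occlusion_rate / 100
    # per frame; during an episode the chaser heads straight at its target.
    episode_rate = cfg.occlusion_rate / 100.0
    episode_len_mean = 12.0
    chase: dict[int, tuple[int, int]] = {}  # chaser -> (target, frames left)

    boxes: FrameBoxes = {}
    visibility: dict[int, dict[int, float]] = {}
    half_w, half_h = widths / 2, heights / 2
    for t in range(1, cfg.n_frames + 1):
        # episode bookkeeping
        if rng.random() < episode_rate and n >= 2:
            chaser = int(rng.integers(n))
            target = int(rng.integers(n - 1))
            if target >= chaser:
                target += 1
            length = max(4, int(rng.exponential(episode_len_mean)))
            chase[chaser] = (target, length)
        for i in list(chase):
            tgt, left = chase[i]
            if left <= 0:
                del chase[i]
            else:
                chase[i] = (tgt, left - 1)

        heading = heading + rng.normal(0.0, turn_std, size=n)
        for i, (tgt, _) in chase.items():
            heading[i] = math.atan2(pos[tgt, 1] - pos[i, 1],
                                    pos[tgt, 0] - pos[i, 0])
        step = np.stack([np.cos(heading), np.sin(heading)], axis=1) * speed[:, None]
        # chasers close in faster so overlap actually happens
        for i in chase:
            step[i] *= 2.0
        pos = pos + step
        # reflect at the walls (keep the whole box inside the pen)
        for i in range(n):
            lo_x, hi_x = half_w[i], cfg.pen_width - half_w[i]
            lo_y, hi_y = half_h[i], cfg.pen_height - half_h[i]
            if pos[i, 0] < lo_x or pos[i, 0] > hi_x:
                pos[i, 0] = np.clip(2 * lo_x - pos[i, 0] if pos[i, 0] < lo_x
                                    else 2 * hi_x - pos[i, 0], lo_x, hi_x)
                heading[i] = math.pi - heading[i]
            if pos[i, 1] < lo_y or pos[i, 1] > hi_y:
                pos[i, 1] = np.clip(2 * lo_y - pos[i, 1] if pos[i, 1] < lo_y
                                    else 2 * hi_y - pos[i, 1], lo_y, hi_y)
                heading[i] = -heading[i]

        frame_boxes = {
            i + 1: BoundingBox(pos[i, 0] - half_w[i], pos[i, 1] - half_h[i],
                               widths[i], heights[i])
            for i in range(n)
        }
        frame_vis = {}
        for ident, box in frame_boxes.items():
            worst = 0.0
            for other, obox in frame_boxes.items():
                if other != ident:
                    worst = max(worst, _fractional_overlap(box, obox))
            frame_vis[ident] = 1.0 - min(worst, 1.0)
        boxes[t] = frame_boxes
        visibility[t] = frame_vis
    return GroundTruthSet(boxes=boxes, visibility=visibility, config=cfg)


def count_overlap_episodes(gt: GroundTruthSet,
                           overlap_threshold: float = 0.15) -> int:
    """Count maximal frame runs during which a specific pair overlaps.

    A pair (i, j) is "overlapping" at a frame when either box covers at
    least ``overlap_threshold`` of the other's area; each maximal
    consecutive run of overlapping frames for a pair counts as one episode.
    """
    frames = sorted(gt.boxes)
    active: set[tuple[int, int]] = set()
    episodes = 0
    for t in frames:
        fb = gt.boxes[t]
        ids = sorted(fb)
        now: set[tuple[int, int]] = set()
        for a_pos, i in enumerate(ids):
            for j in ids[a_pos + 1:]:
                ov = max(_fractional_overlap(fb[i], fb[j]),
                         _fractional_overlap(fb[j], fb[i]))
                if ov >= overlap_threshold:
                    now.add((i, j))
        episodes += len(now - active)
        active = now
    return episodes


def emulate_detector(gt: GroundTruthSet,
                     cfg: ScenarioConfig | None = None) -> dict[int, list[Detection]]:
    """Turn ground truth into a noisy detection stream with embeddings.

    Every surviving box carries a unit embedding drawn around its identity's
    prototype; miss probability, confidence and embedding noise all degrade
    with falling visibility.  False positives are placed uniformly in the
    pen with low confidence and random embeddings.
    """
    cfg = cfg or gt.config
    rng = np.random.default_rng(cfg.seed + 1)  # independent of the GT stream
    n = cfg.n_identities
    prototypes = rng.standard_normal((n + 1, cfg.embedding_dim))
    prototypes /= np.linalg.norm(prototypes, axis=1, keepdims=True)

    stream: dict[int, list[Detection]] = {}
    for t in sorted(gt.boxes):
        dets: list[Detection] = []
        for ident in sorted(gt.boxes[t]):
            box = gt.boxes[t][ident]
            vis = gt.visibility[t][ident]
            occ = 1.0 - vis
            p_miss = cfg.detector_miss_base + occ * (
                cfg.detector_miss_occluded - cfg.detector_miss_base)
            if rng.random() < p_miss:
                continue
            jitter = rng.normal(0.0, cfg.box_jitter_std, size=4) \
                if cfg.box_jitter_std > 0 else np.zeros(4)
            w = max(box.width + jitter[2], 2.0)
            h = max(box.height + jitter[3], 2.0)
            jittered = BoundingBox(box.left + jitter[0], box.top + jitter[1], w, h)
            conf_mean = (vis * cfg.confidence_mean_visible
                         + occ * cfg.confidence_mean_occluded)
            conf_sigma = 0.05
            conf = float(np.clip(rng.normal(conf_mean, conf_sigma)
                                 if conf_sigma > 0 else conf_mean, 0.0, 1.0))
            noise_std = (vis * cfg.embedding_noise_std
                         + occ * cfg.embedding_noise_occluded_std)
            emb = prototypes[ident - 1] + rng.normal(
                0.0, noise_std, size=cfg.embedding_dim)
            emb = emb / np.linalg.norm(emb)
            dets.append(Detection(box=jittered, confidence=conf,
                                  embedding=emb, frame_index=t))
        n_fp = rng.poisson(cfg.fp_rate)
        for _ in range(n_fp):
            w = rng.uniform(*cfg.box_size_range)
            h = w / rng.uniform(*cfg.box_aspect_range)
            left = rng.uniform(0, max(cfg.pen_width - w, 1.0))
            top = rng.uniform(0, max(cfg.pen_height - h, 1.0))
            conf = float(np.clip(rng.normal(0.3, 0.1), 0.05, 1.0))
            emb = rng.standard_normal(cfg.embedding_dim)
            emb = emb / np.linalg.norm(emb)
            dets.append(Detection(box=BoundingBox(left, top, w, h),
                                  confidence=conf, embedding=emb, frame_index=t))
        stream[t] = dets
    return stream


def noise_free(cfg: ScenarioConfig) -> ScenarioConfig:
    """Copy of ``cfg`` with every detector noise source switched off."""
    return replace(cfg, detector_miss_base=0.0, detector_miss_occluded=0.0,
                   fp_rate=0.0, box_jitter_std=0.0,
                   embedding_noise_std=0.0, embedding_noise_occluded_std=0.0)


def day_night_presets(seed: int = 0) -> dict[str, ScenarioConfig]:
    """The two detector-quality regimes: reliable day, degraded dense night."""
    day = ScenarioConfig(
        n_identities=6, n_frames=300, speed_scale=4.0,
        occlusion_rate=3.0,
        detector_miss_base=0.02, detector_miss_occluded=0.35,
        fp_rate=0.1, box_jitter_std=1.0,
        confidence_mean_visible=0.88, confidence_mean_occluded=0.45,
        embedding_noise_std=0.08, embedding_noise_occluded_std=0.25,
        seed=seed)
    night = ScenarioConfig(
        n_identities=10, n_frames=300, speed_scale=4.0,
        occlusion_rate=8.0,
        detector_miss_base=0.12, detector_miss_occluded=0.6,
        fp_rate=0.5, box_jitter_std=2.5,
        confidence_mean_visible=0.62, confidence_mean_occluded=0.32,
        embedding_noise_std=0.25, embedding_noise_occluded_std=0.5,
        seed=seed)
    return {"day": day, "night": night}
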