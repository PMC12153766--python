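"""Track lifecycle and the per-frame tracking loop.

A :class:`Track` is one identity: Kalman motion state, an exponentially
smoothed appearance template, and a lifecycle status
``tentative -> confirmed -> lost -> removed``.  New tracks are born only
from unmatched high-confidence detections, confirmed after ``n_init``
consecutive hits, coast through misses via Kalman prediction (so occluded
tracks stay eligible in every cascade stage) and are removed after
``max_age`` consecutive missed frames.  Track ids are assigned in birth
order starting at 1 and never reused.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import kalman
from .association import CascadeConfig, Detection, run_cascade
from .geometry import BoundingBox


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    LOST = "lost"
    REMOVED = "removed"


class SequencingError(ValueError):
    """Frames were presented out of order."""


@dataclass(frozen=True)
class TrackerConfig:
    """Lifecycle and smoothing parameters of the tracking loop.

    ``max_age`` is in frames (30 = one second at the standard 30 fps);
    ``n_init`` consecutive hits confirm a track (1 = instant confirmation);
    ``ema_alpha`` is the weight kept on the old appearance template at each
    update.
    """

    max_age: int = 30
    n_init: int = 3
    ema_alpha: float = 0.9
    cascade: CascadeConfig = field(default_factory=CascadeConfig)

    def __post_init__(self) -> None:
        if self.max_age < 1 or self.n_init < 1:
            raise ValueError("max_age and n_init must be >= 1")
        if not 0.0 <= self.ema_alpha <= 1.0:
            raise ValueError("ema_alpha must lie in [0, 1]")


@dataclass
class Track:
    """One tracked identity and its mutable state."""

    track_id: int
    motion: kalman.MotionState
    status: TrackStatus = TrackStatus.TENTATIVE
    embedding_template: np.ndarray | None = None
    frames_since_update: int = 0
    hits: int = 1

    def predicted_box(self) -> BoundingBox:
        return kalman.state_to_box(self.motion)


def update_embedding(track: Track, det: Detection, alpha: float) -> None:
    """Blend the detection embedding into the track template (EMA).

    ``template <- normalize(alpha * template + (1 - alpha) * e)``; the first
    embedding ever seen is copied verbatim (unit-normalized).
    """
    if det.embedding is None:
        return
    e = np.asarray(det.embedding, float)
    e = e / np.linalg.norm(e)
    if track.embedding_template is None:
        track.embedding_template = e
        return
    if track.embedding_template.shape != e.shape:
        raise ValueError("embedding dimension mismatch with track template")
    blended = alpha * track.embedding_template + (1.0 - alpha) * e
    norm = np.linalg.norm(blended)
    if norm > 0:
        track.embedding_template = blended / norm


@dataclass(frozen=True)
class OutputRow:
    """One emitted tracking result: a confirmed identity at one frame."""

    frame_index: int
    track_id: int
    box: BoundingBox
    confidence: float


class Tracker:
    """Online multi-object tracker driven by the association cascade."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def _live_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.status is not TrackStatus.REMOVED]

    def step(self, dets: list[Detection], frame_index: int) -> list[OutputRow]:
        """Advance one frame: predict, associate, update lifecycles.

        Returns the result rows for confirmed tracks matched this frame.
        """
        if self._last_frame is not None and frame_index <= self._last_frame:
            raise SequencingError(
                f"frame {frame_index} not after frame {self._last_frame}")
        if any(d.frame_index != frame_index for d in dets):
            raise SequencingError("detections carry a different frame_index")
        self._last_frame = frame_index
        cfg = self.config

        live = self._live_tracks()
        for t in live:
            if t.frames_since_update > 0:
                # coasting tracks keep translating but stop changing shape,
                # otherwise extrapolated aspect/height can go negative
                mean = t.motion.mean.copy()
                mean[6:8] = 0.0
                t.motion = kalman.MotionState(mean, t.motion.covariance)
            t.motion = kalman.kf_predict(t.motion)

        result = run_cascade([t.predicted_box() for t in live],
                             [t.embedding_template for t in live],
                             dets, cfg.cascade)

        rows: list[OutputRow] = []
        matched_track_idx = set()
        for ti, dj in result.matches:
            matched_track_idx.add(ti)
            track, det = live[ti], dets[dj]
            track.motion = kalman.kf_update(track.motion, det.box)
            update_embedding(track, det, cfg.ema_alpha)
            track.frames_since_update = 0
            track.hits += 1
            if track.status is TrackStatus.TENTATIVE and track.hits >= cfg.n_init:
                track.status = TrackStatus.CONFIRMED
            elif track.status is TrackStatus.LOST:
                track.status = TrackStatus.CONFIRMED
            if track.status is TrackStatus.CONFIRMED:
                rows.append(OutputRow(frame_index, track.track_id,
                                      kalman.state_to_box(track.motion),
                                      det.confidence))

        for ti, track in enumerate(live):
            if ti in matched_track_idx:
                continue
            track.frames_since_update += 1
            if track.status is TrackStatus.TENTATIVE:
                # an unconfirmed track that misses a frame is dropped
                track.status = TrackStatus.REMOVED
            else:
                track.status = TrackStatus.LOST
                if track.frames_since_update > cfg.max_age:
                    track.status = TrackStatus.REMOVED

        for dj in result.unmatched_high:
            det = dets[dj]
            track = Track(track_id=self._next_id,
                          motion=kalman.kf_initiate(det.box))
            self._next_id += 1
            update_embedding(track, det, cfg.ema_alpha)
            if cfg.n_init <= 1:
                track.status = TrackStatus.CONFIRMED
                rows.append(OutputRow(frame_index, track.track_id,
                                      det.box, det.confidence))
            self.tracks.append(track)

        rows.sort(key=lambda r: r.track_id)
        return rows


def run_sequence(det_stream: dict[int, list[Detection]],
                 config: TrackerConfig | None = None) -> list[OutputRow]:
    """Track a whole sequence; ``det_stream`` maps frame index to detections.

    Frames are processed in increasing index order; frames absent from the
    mapping are treated as empty (no detections).
    """
    tracker = Tracker(config)
    rows: list[OutputRow] = []
    if not det_stream:
        return rows
    for frame in range(min(det_stream), max(det_stream) + 1):
        rows.extend(tracker.step(det_stream.get(frame, []), frame))
    return rows
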