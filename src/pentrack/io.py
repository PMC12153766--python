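"""MOTChallenge-format readers and writers plus run configuration.

The on-disk dialect is the 10-column MOTChallenge text format::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

with 1-based frame indices and ``-1`` placeholders for the last three
columns (and for the id column of raw detection files).  Embeddings travel
in a plain-text sidecar table ``frame, ordinal, v_1 ... v_D`` aligned
row-for-row with the detection file.  All writes are atomic
(temp-then-rename), so an interrupted run never leaves a truncated file.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .association import CascadeConfig, Detection
from .geometry import BoundingBox
from .metrics import FrameBoxes
from .tracker import OutputRow, TrackerConfig


class MotParseError(ValueError):
    """A MOT file line could not be parsed; the message names the line."""


@dataclass(frozen=True)
class MotRecord:
    frame: int
    id: int
    bb_left: float
    bb_top: float
    bb_width: float
    bb_height: float
    conf: float

    def box(self) -> BoundingBox:
        return BoundingBox(self.bb_left, self.bb_top, self.bb_width, self.bb_height)


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_mot(path: str | Path, kind: str = "det") -> dict[int, list[MotRecord]]:
    """Read a MOT file into frame-indexed, sorted record lists.

    ``kind``: ``gt`` and ``result`` require positive ids; ``det`` tolerates
    ``id = -1``.  Malformed lines raise :class:`MotParseError` naming the
    offending line number.
    """
    if kind not in {"gt", "det", "result"}:
        raise ValueError(f"unknown kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames: dict[int, list[MotRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MotParseError(
                    f"{path}:{lineno}: expected >= 7 comma-separated fields, "
                    f"got {len(parts)}")
            try:
                frame = int(float(parts[0]))
                ident = int(float(parts[1]))
                l, t, w, h, conf = (float(p) for p in parts[2:7])
            except ValueError as exc:
                raise MotParseError(f"{path}:{lineno}: non-numeric field "
                                    f"({exc})") from None
            if frame < 1:
                raise MotParseError(f"{path}:{lineno}: frame must be >= 1")
            if kind in {"gt", "result"} and ident < 1:
                raise MotParseError(
                    f"{path}:{lineno}: {kind} files require id >= 1, got {ident}")
            if w <= 0 or h <= 0:
                raise MotParseError(
                    f"{path}:{lineno}: non-positive box size {w}x{h}")
            frames.setdefault(frame, []).append(
                MotRecord(frame, ident, l, t, w, h, conf))
    for recs in frames.values():
        recs.sort(key=lambda r: (r.id, r.bb_left, r.bb_top))
    return frames


def write_mot(path: str | Path, records: list[MotRecord]) -> None:
    lines = [
        f"{r.frame},{r.id},{r.bb_left:.4f},{r.bb_top:.4f},"
        f"{r.bb_width:.4f},{r.bb_height:.4f},{r.conf:.4f},-1,-1,-1"
        for r in sorted(records, key=lambda r: (r.frame, r.id))
    ]
    _atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))


def frames_to_boxes(frames: dict[int, list[MotRecord]]) -> FrameBoxes:
    """Convert records to the ``{frame: {id: box}}`` form the metrics use.

    Duplicate ids within one frame are an input error.
    """
    out: FrameBoxes = {}
    for t, recs in frames.items():
        fb: dict[int, BoundingBox] = {}
        for r in recs:
            if r.id in fb:
                raise MotParseError(f"duplicate id {r.id} in frame {t}")
            fb[r.id] = r.box()
        out[t] = fb
    return out


def rows_to_records(rows: list[OutputRow]) -> list[MotRecord]:
    return [MotRecord(r.frame_index, r.track_id, r.box.left, r.box.top,
                      r.box.width, r.box.height, r.confidence) for r in rows]


def write_gt(path: str | Path, gt_boxes: FrameBoxes) -> None:
    recs = [MotRecord(t, ident, b.left, b.top, b.width, b.height, 1.0)
            for t, fb in gt_boxes.items() for ident, b in fb.items()]
    write_mot(path, recs)


def write_detections(det_path: str | Path, emb_path: str | Path | None,
                     stream: dict[int, list[Detection]]) -> None:
    """Write a detection stream and (optionally) its embedding sidecar."""
    recs = []
    emb_lines = []
    for t in sorted(stream):
        for ordinal, d in enumerate(stream[t]):
            recs.append(MotRecord(t, -1, d.box.left, d.box.top,
                                  d.box.width, d.box.height, d.confidence))
            if emb_path is not None:
                if d.embedding is None:
                    raise ValueError(
                        f"frame {t} detection {ordinal} lacks an embedding")
                vals = ",".join(f"{v:.8f}" for v in d.embedding)
                emb_lines.append(f"{t},{ordinal},{vals}")
    # write in the same (frame, ordinal) order the sidecar uses
    lines = [
        f"{r.frame},{r.id},{r.bb_left:.4f},{r.bb_top:.4f},"
        f"{r.bb_width:.4f},{r.bb_height:.4f},{r.conf:.4f},-1,-1,-1"
        for r in recs
    ]
    _atomic_write(det_path, "\n".join(lines) + ("\n" if lines else ""))
    if emb_path is not None:
        _atomic_write(emb_path, "\n".join(emb_lines) + ("\n" if emb_lines else ""))


class AlignmentError(ValueError):
    """Embedding sidecar does not align with the detection file."""


def read_embeddings(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    """Read an embedding sidecar keyed by (frame, detection ordinal)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table: dict[tuple[int, int], np.ndarray] = {}
    dim: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 3:
                raise MotParseError(
                    f"{path}:{lineno}: expected frame, ordinal, values")
            try:
                frame, ordinal = int(float(parts[0])), int(float(parts[1]))
                vals = np.array([float(p) for p in parts[2:]])
            except ValueError as exc:
                raise MotParseError(f"{path}:{lineno}: non-numeric field "
                                    f"({exc})") from None
            if dim is None:
                dim = vals.size
            elif vals.size != dim:
                raise AlignmentError(
                    f"{path}:{lineno}: dimension {vals.size} != {dim}")
            table[(frame, ordinal)] = vals
    return table


def read_detection_stream(det_path: str | Path,
                          emb_path: str | Path | None = None
                          ) -> dict[int, list[Detection]]:
    """Read detections (plus optional sidecar) into the tracker's input form.

    With a sidecar, every detection row must have exactly one embedding row
    and vice versa; any mismatch raises :class:`AlignmentError`.
    """
    frames = read_mot(det_path, kind="det")
    table = read_embeddings(emb_path) if emb_path is not None else None
    stream: dict[int, list[Detection]] = {}
    n_rows = 0
    for t in sorted(frames):
        dets = []
        for ordinal, r in enumerate(frames[t]):
            emb = None
            if table is not None:
                key = (t, ordinal)
                if key not in table:
                    raise AlignmentError(
                        f"no embedding row for frame {t} detection {ordinal}")
                emb = table[key]
            conf = float(np.clip(r.conf, 0.0, 1.0))
            dets.append(Detection(box=r.box(), confidence=conf,
                                  embedding=emb, frame_index=t))
            n_rows += 1
        stream[t] = dets
    if table is not None and len(table) != n_rows:
        raise AlignmentError(
            f"sidecar has {len(table)} rows, detection file has {n_rows}")
    return stream


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """Full run configuration; every field has a default, so {} is valid."""

    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    metrics_iou_threshold: float = 0.5
    motp_as_distance: bool = False
    hota_sqrt: bool = True
    seed: int = 0


def load_run_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file (sections: cascade, tracker, metrics).

    Missing keys fall back to defaults; keyword overrides (CLI flags) win
    over the file.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    cascade_kw = dict(data.get("cascade", {}))
    tracker_kw = dict(data.get("tracker", {}))
    metrics_kw = dict(data.get("metrics", {}))
    cascade_kw.update({k: v for k, v in overrides.items()
                       if k in {f.name for f in dataclasses.fields(CascadeConfig)}
                       and v is not None})
    tracker_kw.update({k: v for k, v in overrides.items()
                       if k in {"max_age", "n_init", "ema_alpha"} and v is not None})
    cascade = CascadeConfig(**cascade_kw)
    tracker = TrackerConfig(cascade=cascade, **tracker_kw)
    return RunConfig(
        tracker=tracker,
        metrics_iou_threshold=metrics_kw.get("iou_threshold", 0.5),
        motp_as_distance=bool(overrides.get(
            "motp_as_distance", metrics_kw.get("motp_as_distance", False))),
        hota_sqrt=bool(overrides.get(
            "hota_sqrt", metrics_kw.get("hota_sqrt", True))),
        seed=int(overrides.get("seed", data.get("seed", 0)) or 0))


def describe_config(cfg: RunConfig) -> str:
    """Full resolved configuration as YAML, for replay logging."""
    return yaml.safe_dump({
        "cascade": dataclasses.asdict(cfg.tracker.cascade),
        "tracker": {"max_age": cfg.tracker.max_age,
                    "n_init": cfg.tracker.n_init,
                    "ema_alpha": cfg.tracker.ema_alpha},
        "metrics": {"iou_threshold": cfg.metrics_iou_threshold,
                    "motp_as_distance": cfg.motp_as_distance,
                    "hota_sqrt": cfg.hota_sqrt},
        "seed": cfg.seed,
    }, sort_keys=True)
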