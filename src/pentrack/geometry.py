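"""Bounding-box algebra and pairwise association costs.

Boxes are axis-aligned pixel rectangles stored in MOTChallenge order
``(left, top, width, height)``, denoting the half-open rectangle
``[left, left+width) x [top, top+height)`` in image coordinates (origin
top-left, x rightward, y downward).  All overlap arithmetic is done on
continuous real-valued areas: after Kalman prediction boxes are sub-pixel,
so no pixel snapping is applied.  Rectangles that merely touch along an
edge have zero intersection area and therefore IoU 0.

Three pairwise distances are defined here and consumed by the association
cascade and the evaluation metrics:

* ``iou`` — intersection area over union area, in [0, 1];
* ``center_distance`` — Euclidean distance between box centers, in pixels;
* ``cosine_distance`` — ``1 - cos(e1, e2)`` between embedding vectors,
  in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidBoxError(ValueError):
    """A bounding box has non-positive width or height."""


class DegenerateEmbeddingError(ValueError):
    """An embedding vector has zero norm or mismatched dimension."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle in (left, top, width, height) form."""

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.left) and np.isfinite(self.top)
                and np.isfinite(self.width) and np.isfinite(self.height)):
            raise InvalidBoxError(f"non-finite box {self!r}")
        if self.width <= 0 or self.height <= 0:
            raise InvalidBoxError(
                f"box must have positive width and height, got "
                f"width={self.width}, height={self.height}")

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    @property
    def diagonal(self) -> float:
        """Length of the box diagonal in pixels."""
        return float(np.hypot(self.width, self.height))

    def as_ltwh(self) -> np.ndarray:
        return np.array([self.left, self.top, self.width, self.height], float)

    def intersection_area(self, other: "BoundingBox") -> float:
        iw = min(self.right, other.right) - max(self.left, other.left)
        ih = min(self.bottom, other.bottom) - max(self.top, other.top)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint, 1 for identical."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return min(inter / union, 1.0)


def center_distance(det: BoundingBox, pred: BoundingBox) -> float:
    """Euclidean distance in pixels between the two box centers."""
    (xd, yd), (xp, yp) = det.center, pred.center
    return float(np.hypot(xp - xd, yp - yd))


def cosine_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """``1 - cos(e1, e2)``: 0 parallel, 1 orthogonal, 2 anti-parallel.

    Raises :class:`DegenerateEmbeddingError` for zero-norm vectors or a
    dimension mismatch.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise DegenerateEmbeddingError(
            f"embedding dimension mismatch: {e1.shape} vs {e2.shape}")
    n1 = np.linalg.norm(e1)
    n2 = np.linalg.norm(e2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateEmbeddingError("zero-norm embedding")
    return float(1.0 - np.dot(e1, e2) / (n1 * n2))


# ---------------------------------------------------------------------------
# vectorized cost matrices (used by the cascade and the metrics)

def _ltwh_array(boxes: list[BoundingBox]) -> np.ndarray:
    if not boxes:
        return np.zeros((0, 4))
    return np.stack([b.as_ltwh() for b in boxes])


def iou_matrix(boxes_a: list[BoundingBox], boxes_b: list[BoundingBox]) -> np.ndarray:
    """Pairwise IoU, shape (len(a), len(b))."""
    a = _ltwh_array(boxes_a)
    b = _ltwh_array(boxes_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    ax1, ay1 = a[:, 0], a[:, 1]
    ax2, ay2 = a[:, 0] + a[:, 2], a[:, 1] + a[:, 3]
    bx1, by1 = b[:, 0], b[:, 1]
    bx2, by2 = b[:, 0] + b[:, 2], b[:, 1] + b[:, 3]
    iw = np.minimum(ax2[:, None], bx2[None, :]) - np.maximum(ax1[:, None], bx1[None, :])
    ih = np.minimum(ay2[:, None], by2[None, :]) - np.maximum(ay1[:, None], by1[None, :])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[:, 2] * a[:, 3])[:, None]
    area_b = (b[:, 2] * b[:, 3])[None, :]
    return np.minimum(inter / (area_a + area_b - inter), 1.0)


def center_distance_matrix(boxes_a: list[BoundingBox],
                           boxes_b: list[BoundingBox]) -> np.ndarray:
    """Pairwise center Euclidean distance in pixels, shape (len(a), len(b))."""
    a = _ltwh_array(boxes_a)
    b = _ltwh_array(boxes_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    ca = a[:, :2] + a[:, 2:] / 2.0
    cb = b[:, :2] + b[:, 2:] / 2.0
    diff = ca[:, None, :] - cb[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def cosine_distance_matrix(emb_a: np.ndarray, emb_b: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - cos`` between rows of two embedding matrices."""
    emb_a = np.atleast_2d(np.asarray(emb_a, float))
    emb_b = np.atleast_2d(np.asarray(emb_b, float))
    if emb_a.shape[0] == 0 or emb_b.shape[0] == 0:
        return np.zeros((emb_a.shape[0], emb_b.shape[0]))
    if emb_a.shape[1] != emb_b.shape[1]:
        raise DegenerateEmbeddingError(
            f"embedding dimension mismatch: {emb_a.shape[1]} vs {emb_b.shape[1]}")
    na = np.linalg.norm(emb_a, axis=1)
    nb = np.linalg.norm(emb_b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise DegenerateEmbeddingError("zero-norm embedding")
    return 1.0 - (emb_a @ emb_b.T) / np.outer(na, nb)
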