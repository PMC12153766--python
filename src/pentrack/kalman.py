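"""Constant-velocity Kalman filter over bounding-box state.

State is the 8-vector ``(cx, cy, a, h, vcx, vcy, va, vh)``: box center,
aspect ratio ``a = width / height``, height, and their per-frame velocities.
The measurement is the first four components.  This is the parameterization
of the SORT/ByteTrack tracker family; process and measurement noise are
scaled by the box height with the conventional standard-deviation weights
1/20 (position) and 1/160 (velocity), overridable per filter.

The filter is exact for noiseless constant-velocity targets: after a short
burn-in the predicted center converges to the true center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BoundingBox, InvalidBoxError

_NDIM = 4
_DT = 1.0  # one video frame per step


class InvalidStateError(ValueError):
    """Motion state violates its invariants (non-PSD covariance, h <= 0...)."""


@dataclass(frozen=True)
class MotionState:
    """Gaussian belief over the 8-dim box motion state."""

    mean: np.ndarray        # shape (8,)
    covariance: np.ndarray  # shape (8, 8), symmetric PSD

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, float)
        cov = np.asarray(self.covariance, float)
        if mean.shape != (8,) or cov.shape != (8, 8):
            raise InvalidStateError(
                f"expected mean (8,) and covariance (8,8), got "
                f"{mean.shape} and {cov.shape}")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)


def _check_state(s: MotionState) -> None:
    cov = s.covariance
    if not np.allclose(cov, cov.T, atol=1e-9):
        raise InvalidStateError("covariance not symmetric")
    if np.min(np.linalg.eigvalsh(cov)) < -1e-9:
        raise InvalidStateError("covariance not positive semidefinite")
    if not np.all(np.isfinite(s.mean)):
        raise InvalidStateError("non-finite state mean")


@dataclass(frozen=True)
class KalmanParams:
    """Noise scales of the constant-velocity filter (ByteTrack defaults)."""

    std_weight_position: float = 1.0 / 20.0
    std_weight_velocity: float = 1.0 / 160.0

    # state transition: x' = F x with unit-coupled velocities
    motion_mat: np.ndarray = field(
        default_factory=lambda: np.block(
            [[np.eye(_NDIM), _DT * np.eye(_NDIM)],
             [np.zeros((_NDIM, _NDIM)), np.eye(_NDIM)]]),
        repr=False)
    update_mat: np.ndarray = field(
        default_factory=lambda: np.hstack([np.eye(_NDIM), np.zeros((_NDIM, _NDIM))]),
        repr=False)


DEFAULT_PARAMS = KalmanParams()


def box_to_measurement(box: BoundingBox) -> np.ndarray:
    """(left, top, w, h) box -> (cx, cy, aspect, h) measurement."""
    cx, cy = box.center
    return np.array([cx, cy, box.width / box.height, box.height], float)


def state_to_box(s: MotionState) -> BoundingBox:
    """Inverse of the box -> (center, aspect, height) parameterization."""
    cx, cy, a, h = s.mean[:4]
    if h <= 0 or a <= 0:
        raise InvalidStateError(f"non-positive aspect/height in state: a={a}, h={h}")
    w = a * h
    return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)


def kf_initiate(box: BoundingBox, params: KalmanParams = DEFAULT_PARAMS) -> MotionState:
    """Start a track belief from a single detection; velocities zero.

    The initial covariance is diagonal and scaled by box height, following
    the SORT-family convention.
    """
    mean = np.concatenate([box_to_measurement(box), np.zeros(_NDIM)])
    h = box.height
    wp = params.std_weight_position
    # velocity is unobserved at initiation: a diffuse prior (std = h/2) lets
    # the first few updates pin it down quickly
    std = np.array([
        2 * wp * h, 2 * wp * h, 1e-2, 2 * wp * h,
        0.5 * h, 0.5 * h, 1e-5, 0.5 * h,
    ])
    return MotionState(mean, np.diag(std ** 2))


def kf_predict(s: MotionState, params: KalmanParams = DEFAULT_PARAMS) -> MotionState:
    """Advance the belief one frame under constant velocity."""
    _check_state(s)
    h = s.mean[3]
    wp, wv = params.std_weight_position, params.std_weight_velocity
    std = np.array([wp * h, wp * h, 1e-2, wp * h,
                    wv * h, wv * h, 1e-5, wv * h])
    Q = np.diag(std ** 2)
    F = params.motion_mat
    mean = F @ s.mean
    cov = F @ s.covariance @ F.T + Q
    cov = (cov + cov.T) / 2.0
    return MotionState(mean, cov)


def kf_project(s: MotionState, params: KalmanParams = DEFAULT_PARAMS
               ) -> tuple[np.ndarray, np.ndarray]:
    """Project the state belief into measurement space (mean, covariance)."""
    h = s.mean[3]
    wp = params.std_weight_position
    std = np.array([wp * h, wp * h, 1e-1, wp * h])
    R = np.diag(std ** 2)
    H = params.update_mat
    return H @ s.mean, H @ s.covariance @ H.T + R


def kf_update(s: MotionState, box: BoundingBox,
              params: KalmanParams = DEFAULT_PARAMS) -> MotionState:
    """Condition the belief on an observed box (standard Kalman update)."""
    _check_state(s)
    z = box_to_measurement(box)
    proj_mean, S = kf_project(s, params)
    H = params.update_mat
    # gain via Cholesky solve; S is PD by construction (R > 0)
    chol = np.linalg.cholesky(S)
    K = np.linalg.solve(
        chol.T, np.linalg.solve(chol, (s.covariance @ H.T).T)).T
    innovation = z - proj_mean
    mean = s.mean + K @ innovation
    cov = s.covariance - K @ S @ K.T
    cov = (cov + cov.T) / 2.0
    if mean[3] <= 0:
        raise InvalidStateError("posterior height non-positive")
    return MotionState(mean, cov)
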