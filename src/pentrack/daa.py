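"""Domain-aware attention: softmax-weighted channel attention branches.

The operator adapts a feature map to its acquisition "domain" (e.g. day vs.
night lighting) by blending three effective squeeze-and-excitation (ESE)
channel-attention branches.  For an input feature map ``F`` of shape
``(C, H, W)``:

1. global average pooling gives a channel descriptor ``g`` (length C);
2. a 3xC fully connected layer followed by a softmax yields three domain
   weights on the probability simplex;
3. each ESE branch applies its own CxC fully connected layer (plus bias) to
   ``g``, producing three C-dim channel responses — an ESE block is a single
   fully connected layer on the pooled vector, with no channel reduction;
4. the domain weights form a convex combination of the three responses, and
   each input channel is scaled by the sigmoid of its combined response.

The operator is inference-only: parameters are supplied, never trained here.
Because the sigmoid lies strictly inside (0, 1), the output is an
elementwise shrinkage of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

N_DOMAINS = 3


class ShapeMismatchError(ValueError):
    """Parameter shapes inconsistent with the feature map."""


@dataclass(frozen=True)
class DAAParams:
    """Learned weights of the attention operator for channel count C.

    ``domain_fc``: (3, C) matrix producing the domain logits;
    ``ese_weights``: (3, C, C) stacked branch matrices;
    ``ese_biases``: (3, C) stacked branch bias vectors.
    """

    domain_fc: np.ndarray
    ese_weights: np.ndarray
    ese_biases: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.domain_fc, float)
        w = np.asarray(self.ese_weights, float)
        b = np.asarray(self.ese_biases, float)
        if d.ndim != 2 or d.shape[0] != N_DOMAINS:
            raise ShapeMismatchError(f"domain_fc must be (3, C), got {d.shape}")
        c = d.shape[1]
        if w.shape != (N_DOMAINS, c, c):
            raise ShapeMismatchError(
                f"ese_weights must be (3, {c}, {c}), got {w.shape}")
        if b.shape != (N_DOMAINS, c):
            raise ShapeMismatchError(f"ese_biases must be (3, {c}), got {b.shape}")
        for arr in (d, w, b):
            if not np.all(np.isfinite(arr)):
                raise ShapeMismatchError("non-finite parameter values")
        object.__setattr__(self, "domain_fc", d)
        object.__setattr__(self, "ese_weights", w)
        object.__setattr__(self, "ese_biases", b)

    @property
    def n_channels(self) -> int:
        return self.domain_fc.shape[1]


def random_params(n_channels: int, rng: np.random.Generator,
                  scale: float = 0.1) -> DAAParams:
    """Gaussian random parameters, useful for tests and demonstrations."""
    return DAAParams(
        domain_fc=scale * rng.standard_normal((N_DOMAINS, n_channels)),
        ese_weights=scale * rng.standard_normal((N_DOMAINS, n_channels, n_channels)),
        ese_biases=scale * rng.standard_normal((N_DOMAINS, n_channels)))


def _check_map(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, float)
    if F.ndim != 3 or min(F.shape) < 1:
        raise ShapeMismatchError(f"feature map must be (C, H, W), got {F.shape}")
    if not np.all(np.isfinite(F)):
        raise ShapeMismatchError("non-finite feature map")
    return F


def global_avg_pool(F: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean: (C, H, W) -> (C,)."""
    return _check_map(F).mean(axis=(1, 2))


def ese_branch(F: np.ndarray, fc: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """One branch's pre-activation channel response: ``fc @ pool(F) + bias``."""
    g = global_avg_pool(F)
    fc = np.asarray(fc, float)
    bias = np.asarray(bias, float)
    if fc.shape != (g.size, g.size) or bias.shape != (g.size,):
        raise ShapeMismatchError(
            f"branch expects fc ({g.size},{g.size}) and bias ({g.size},), "
            f"got {fc.shape} and {bias.shape}")
    return fc @ g + bias


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax (max subtraction)."""
    z = np.asarray(logits, float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def domain_weights(F: np.ndarray, p: DAAParams) -> np.ndarray:
    """Softmax domain weights from the pooled channel descriptor; sums to 1."""
    g = global_avg_pool(F)
    if g.size != p.n_channels:
        raise ShapeMismatchError(
            f"feature map has {g.size} channels, parameters expect {p.n_channels}")
    return softmax(p.domain_fc @ g)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow for large |x|
    x = np.asarray(x, float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def daa_forward(F: np.ndarray, p: DAAParams) -> np.ndarray:
    """Apply the full attention operator to a (C, H, W) feature map.

    Returns a feature map of identical shape whose channel ``c`` is the
    input channel multiplied by ``sigmoid(s[c])``, where ``s`` is the
    domain-weighted convex combination of the three branch responses.
    """
    F = _check_map(F)
    w = domain_weights(F, p)
    branch_stack = np.stack([
        ese_branch(F, p.ese_weights[k], p.ese_biases[k])
        for k in range(N_DOMAINS)])                      # (3, C)
    combined = w @ branch_stack                          # (C,)
    return F * sigmoid(combined)[:, None, None]


def save_params(path: str | Path, p: DAAParams) -> None:
    """Write parameters to an ``.npz`` array container."""
    np.savez(path, domain_fc=p.domain_fc, ese_weights=p.ese_weights,
             ese_biases=p.ese_biases)


def load_params(path: str | Path) -> DAAParams:
    """Load parameters from ``.npz``; shapes are validated on construction."""
    with np.load(path) as data:
        return DAAParams(domain_fc=data["domain_fc"],
                         ese_weights=data["ese_weights"],
                         ese_biases=data["ese_biases"])
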