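"""Compound segmentation objective: soft Dice loss plus cross-entropy.

The Dice term is computed per batch sample and averaged:

    L_dice = -(2/K) * sum_k  (sum_i u_ik v_ik) / (sum_i u_ik + sum_i v_ik)

with ``u`` the per-pixel softmax output and ``v`` the one-hot target, both
of shape pixels x classes (optionally with a leading batch axis). The class
sum runs over all K classes, background included. The printed form has no
smoothing term; a small epsilon is added to the denominator only, so that a
class absent from both prediction and target contributes 0 instead of 0/0.

Cross-entropy is the mean per-pixel -sum_k v log u with probabilities
clipped away from zero. The total loss is the equally-weighted (1:1) sum of
the two terms; deep supervision combines the total loss across decoder
scales with normalised weights.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor

DICE_EPS = 1e-5
CE_CLIP = 1e-7


def _lift_pair(u, v) -> tuple[Tensor, Tensor]:
    u = u if isinstance(u, Tensor) else Tensor(np.asarray(u, dtype=float))
    v = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=float))
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs v {v.shape}")
    if u.ndim == 2:
        u, v = u.reshape(1, *u.shape), v.reshape(1, *v.shape)
    if u.ndim != 3:
        raise ValueError("expected (pixels, classes) or (batch, pixels, classes)")
    rowsum = u.data.sum(axis=-1)
    if not np.allclose(rowsum, 1.0, atol=1e-3):
        raise ValueError("prediction rows must sum to 1 (softmax output expected)")
    return u, v


def dice_loss(u, v, eps: float = DICE_EPS) -> Tensor:
    """Batch-averaged soft Dice loss in [-1, 0] (lower is better)."""
    u, v = _lift_pair(u, v)
    k = u.shape[-1]
    num = (u * v).sum(axis=1)                      # (B, K)
    den = u.sum(axis=1) + v.sum(axis=1) + eps      # (B, K)
    per_sample = (num / den).sum(axis=1) * (-2.0 / k)
    return per_sample.mean()


def cross_entropy(u, v, clip: float = CE_CLIP) -> Tensor:
    """Mean per-pixel categorical cross-entropy on probabilities."""
    u, v = _lift_pair(u, v)
    logu = u.clip(clip, 1.0).log()
    return -(v * logu).sum(axis=-1).mean()


def total_loss(u, v, eps: float = DICE_EPS, clip: float = CE_CLIP) -> Tensor:
    """Dice + cross-entropy at equal (1:1) weight."""
    return dice_loss(u, v, eps=eps) + cross_entropy(u, v, clip=clip)


def deep_supervision_loss(pairs, weights=None) -> Tensor:
    """Weighted total loss over per-scale (prediction, target) pairs.

    ``pairs`` is ordered highest resolution first. ``weights`` defaults to
    halving with downsampling (1, 1/2, 1/4, ...) and is normalised to sum
    to 1.
    """
    pairs = list(pairs)
    if weights is None:
        weights = halving_weights(len(pairs))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(pairs):
        raise ValueError(f"{len(weights)} weights for {len(pairs)} scales")
    weights = weights / weights.sum()
    out = None
    for w, (u, v) in zip(weights, pairs):
        if w == 0:
            continue
        term = total_loss(u, v) * float(w)
        out = term if out is None else out + term
    return out


def halving_weights(n_scales: int) -> np.ndarray:
    """Deep-supervision weights halving per scale, normalised to sum to 1."""
    w = 0.5 ** np.arange(n_scales)
    return w / w.sum()


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Integer label array -> one-hot float array with a trailing class axis."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float32)
    np.put_along_axis(out, labels[..., None].astype(int), 1.0, axis=-1)
    return out
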