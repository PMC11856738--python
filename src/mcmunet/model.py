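"""MCM-UNet: encoder-decoder segmentation network with multi-scale context
modeling and a first-in-first-out dataset-level feature memory bank.

The backbone is a 2D nnU-Net-style encoder-decoder: two conv-norm-nonlinearity
blocks per resolution stage, strided-conv downsampling, transposed-conv
upsampling, instance normalisation and a leaky rectifier, with channel counts
doubling from ``base_channels`` up to ``max_channels``. A 1x1 class-projection
head sits at every decoder scale; the full-resolution head is the main output
and the others provide deep supervision.

Two additions form the method:

* **Context modeling (CM) block** at decoder skip connections. From the
  per-scale class probabilities D (the deep-supervision head, softmaxed) and
  the stage features f_sf (HW x C), it forms per-class region representations
  R_l as spatially-normalised probability-weighted averages of f_sf,
  redistributes them per position into f_seg, computes attention
  W = row-softmax(f_sf f_seg^T / C), aggregates R_sf = W f_sf, and merges
  R_sf back by channel concatenation + 1x1 compression.

* **Memory bank** at the deepest (bottleneck) features. A fixed-capacity
  FIFO queue of dataset-level feature maps f_dl; the three entries most
  cosine-similar to the current features (on spatially pooled channel
  descriptors) are concatenated with f_sf and compressed 4C -> C by a learned
  1x1 transform. The fused result (batch mean, detached) is pushed once per
  training batch; the oldest entry is popped when capacity is exceeded. The
  bank is frozen at inference.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .nn import Conv2d, ConvNormAct, ConvTranspose2d, Module, Tensor, concat


@dataclass
class NetworkConfig:
    """Architecture and ablation switches.

    ``n_cm_modules`` counts CM insertions from the deepest decoder step
    upward; the final (full-resolution) decoder step never carries one, so
    at most ``n_stages - 2`` fit. The defaults (6 CM modules, bank of 64)
    are the best-performing setting of the published ablation: 8 resolution
    stages for 512x512 slices (deepest features 4x4) give 7 decoder steps,
    of which the 6 non-final ones each carry a CM module.
    """

    n_stages: int = 8
    base_channels: int = 32
    max_channels: int = 320
    n_cm_modules: int = 6
    bank_capacity: int = 64
    use_cm: bool = True
    use_mb: bool = True
    n_classes: int = 2
    in_channels: int = 1
    attn_scale: str = "C"  # divide attention logits by C (as published) or "sqrtC"
    seed: int = 0

    def __post_init__(self):
        if self.n_stages < 2:
            raise ValueError("need at least 2 resolution stages")
        if self.n_cm_modules > self.n_stages - 2:
            raise ValueError(
                "n_cm_modules cannot exceed the number of non-final decoder steps")
        if self.use_mb and self.bank_capacity < 3:
            raise ValueError("memory bank capacity must be >= 3")
        if self.attn_scale not in ("C", "sqrtC"):
            raise ValueError("attn_scale must be 'C' or 'sqrtC'")

    @property
    def stage_channels(self) -> list[int]:
        return [min(self.base_channels * 2**i, self.max_channels)
                for i in range(self.n_stages)]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Functional CM-module operations (feature maps as (..., HW, C) tensors)
# ---------------------------------------------------------------------------

def _lift3(t) -> tuple[Tensor, bool]:
    t = t if isinstance(t, Tensor) else Tensor(np.asarray(t, dtype=float))
    if t.ndim == 2:
        return t.reshape(1, *t.shape), True
    if t.ndim == 3:
        return t, False
    raise ValueError("expected (HW, C) or (batch, HW, C)")


def region_context(fsf, probs, eps: float = 1e-8) -> Tensor:
    """Class-region representations redistributed per position (f_seg).

    ``fsf``: features (HW, C); ``probs``: per-position class distribution
    (HW, L). R_l is the spatially-normalised probability-weighted average of
    ``fsf``; the output at each position is sum_l probs_l * R_l.
    """
    fsf, squeezed = _lift3(fsf)
    probs, _ = _lift3(probs)
    if fsf.shape[-2] != probs.shape[-2]:
        raise ValueError(f"HW mismatch: fsf {fsf.shape} vs probs {probs.shape}")
    mass = probs.sum(axis=-2, keepdims=True) + eps      # (N, 1, L)
    d_norm = probs / mass                                # spatial normalisation
    r = d_norm.swapaxes(-1, -2) @ fsf                    # (N, L, C)
    fseg = probs @ r                                     # (N, HW, C)
    return fseg.reshape(*fseg.shape[1:]) if squeezed else fseg


def attention_similarity(fsf, fseg, scale: str = "C") -> Tensor:
    """Row-softmax similarity W = softmax(f_sf f_seg^T / C): (HW, HW)."""
    fsf, squeezed = _lift3(fsf)
    fseg, _ = _lift3(fseg)
    if fsf.shape != fseg.shape:
        raise ValueError(f"shape mismatch: fsf {fsf.shape} vs fseg {fseg.shape}")
    if not (np.isfinite(fsf.data).all() and np.isfinite(fseg.data).all()):
        raise ValueError("non-finite values in attention inputs")
    c = fsf.shape[-1]
    denom = float(c) if scale == "C" else float(np.sqrt(c))
    w = ((fsf @ fseg.swapaxes(-1, -2)) * (1.0 / denom)).softmax(axis=-1)
    return w.reshape(*w.shape[1:]) if squeezed else w


def aggregate_context(w, fsf) -> Tensor:
    """Similarity-aggregated image-level representation R_sf = W f_sf."""
    w, squeezed = _lift3(w)
    fsf, _ = _lift3(fsf)
    if w.shape[-1] != fsf.shape[-2]:
        raise ValueError(f"shape mismatch: W {w.shape} vs fsf {fsf.shape}")
    r = w @ fsf
    return r.reshape(*r.shape[1:]) if squeezed else r


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class CMBlock(Module):
    """Context-modeling block at one decoder scale.

    Takes stage features (N, C, H, W) and the deep-supervision logits at the
    same scale, computes the attention-aggregated context R_sf and merges it
    back by concatenation + 1x1 channel compression. Output shape equals
    input shape.
    """

    def __init__(self, channels: int, rng: np.random.Generator, attn_scale: str = "C"):
        self.channels = channels
        self.attn_scale = attn_scale
        self.compress = Conv2d(2 * channels, channels, 1, rng)

    def __call__(self, fsf: Tensor, logits: Tensor) -> Tensor:
        n, c, h, w = fsf.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        probs = logits.softmax(axis=1)                       # Nor over classes
        flat = fsf.reshape(n, c, h * w).swapaxes(1, 2)       # (N, HW, C)
        pflat = probs.reshape(n, probs.shape[1], h * w).swapaxes(1, 2)
        fseg = region_context(flat, pflat)
        attn = attention_similarity(flat, fseg, scale=self.attn_scale)
        rsf = aggregate_context(attn, flat)
        rsf_map = rsf.swapaxes(1, 2).reshape(n, c, h, w)
        return self.compress(concat([rsf_map, fsf], axis=1))

    def init_passthrough(self) -> None:
        """Set the compression to return the f_sf half unchanged (testing aid)."""
        w = np.zeros_like(self.compress.w.data)
        for c in range(self.channels):
            w[c, self.channels + c, 0, 0] = 1.0
        self.compress.w.data = w
        self.compress.b.data[:] = 0.0


class MemoryBank:
    """Fixed-capacity FIFO store of dataset-level feature maps.

    Entries are plain arrays of shape (C, H, W), stored detached from any
    gradient history. Pushing beyond capacity pops the oldest entry.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.entries: deque[np.ndarray] = deque()

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def entry_shape(self):
        return self.entries[0].shape if self.entries else None

    def push(self, entry: np.ndarray) -> None:
        entry = np.asarray(entry)
        if self.entries and entry.shape != self.entries[0].shape:
            raise ValueError(
                f"entry shape {entry.shape} != bank entry shape {self.entries[0].shape}")
        self.entries.append(entry.copy())
        if len(self.entries) > self.capacity:
            self.entries.popleft()

    def descriptors(self) -> np.ndarray:
        """Spatially average-pooled channel descriptors, one row per entry."""
        return np.stack([e.mean(axis=(1, 2)) for e in self.entries])


def bank_query(fsf, bank: MemoryBank, k: int = 3) -> list[int]:
    """Indices of the <=k bank entries most cosine-similar to ``fsf``.

    Similarity is cosine between spatially average-pooled channel
    descriptors; ties are broken toward the lower (older) bank index.
    """
    if len(bank) == 0:
        return []
    data = fsf.data if isinstance(fsf, Tensor) else np.asarray(fsf)
    if data.ndim != 3:
        raise ValueError("expected a single (C, H, W) feature map")
    q = data.mean(axis=(1, 2)).astype(np.float64)
    d = bank.descriptors().astype(np.float64)
    qn = q / (np.linalg.norm(q) + 1e-12)
    dn = d / (np.linalg.norm(d, axis=1, keepdims=True) + 1e-12)
    # per-row dot products: identical entries get bitwise-identical scores,
    # so the stable argsort breaks ties toward the lower (older) index
    sims = np.array([np.dot(row, qn) for row in dn])
    order = np.argsort(-sims, kind="stable")
    return [int(i) for i in order[: min(k, len(bank))]]


class BankFusion(Module):
    """Learned fusion delta: concat(3 selected entries, f_sf) -> 1x1 -> C."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.delta = Conv2d(4 * channels, channels, 1, rng)

    def __call__(self, fsf: Tensor, bank: MemoryBank, train_mode: bool = False) -> Tensor:
        n, c, h, w = fsf.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        if len(bank) and bank.entry_shape != (c, h, w):
            raise ValueError(f"bank entry shape {bank.entry_shape} != features {(c, h, w)}")
        slots = []
        for j in range(3):
            per_sample = []
            for s in range(n):
                idx = bank_query(Tensor(fsf.data[s]), bank)
                per_sample.append(bank.entries[idx[j]] if j < len(idx) else fsf.data[s])
            slots.append(Tensor(np.stack(per_sample)))
        fused = self.delta(concat(slots + [fsf], axis=1))
        if train_mode:
            bank.push(fused.data.mean(axis=0))
        return fused

    def init_average(self) -> None:
        """Set delta to average the four concatenated blocks (testing aid)."""
        w = np.zeros_like(self.delta.w.data)
        for c in range(self.channels):
            for j in range(4):
                w[c, j * self.channels + c, 0, 0] = 0.25
        self.delta.w.data = w
        self.delta.b.data[:] = 0.0


class Backbone(Module):
    """Plain 2D encoder-decoder with per-scale class-projection heads."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        ch = cfg.stage_channels
        n = cfg.n_stages
        self.cfg = cfg
        self.enc = []
        cin = cfg.in_channels
        for i in range(n):
            stride = 1 if i == 0 else 2
            self.enc.append([ConvNormAct(cin, ch[i], rng, stride=stride),
                             ConvNormAct(ch[i], ch[i], rng)])
            cin = ch[i]
        self.up = []
        self.dec = []
        self.heads = []
        for i in range(n - 2, -1, -1):
            self.up.append(ConvTranspose2d(ch[i + 1], ch[i], 2, rng))
            self.dec.append([ConvNormAct(2 * ch[i], ch[i], rng),
                             ConvNormAct(ch[i], ch[i], rng)])
            self.heads.append(Conv2d(ch[i], cfg.n_classes, 1, rng))

    def encode(self, x: Tensor) -> list[Tensor]:
        skips = []
        h = x
        for blocks in self.enc:
            for b in blocks:
                h = b(h)
            skips.append(h)
        return skips


class MCMUNet(Module):
    """The full network; ``use_cm`` / ``use_mb`` toggle the two additions.

    Parameter initialisation draws from independent random streams for the
    backbone, the CM blocks and the bank fusion, so disabling either addition
    leaves the backbone's parameters (and its outputs) bit-identical.
    """

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        ss = np.random.SeedSequence([cfg.seed, 0x6D636D])
        rng_bb, rng_cm, rng_mb = [np.random.default_rng(s) for s in ss.spawn(3)]
        self.backbone = Backbone(cfg, rng_bb)
        ch = cfg.stage_channels
        self.cm_blocks = None
        if cfg.use_cm:
            # decoder step d (0 = deepest) refines stage index n_stages-2-d
            self.cm_blocks = [CMBlock(ch[cfg.n_stages - 2 - d], rng_cm, cfg.attn_scale)
                              for d in range(cfg.n_cm_modules)]
        self.bank_fusion = BankFusion(ch[cfg.n_stages - 1], rng_mb) if cfg.use_mb else None
        self.bank = MemoryBank(cfg.bank_capacity) if cfg.use_mb else None

    def forward(self, x, train_mode: bool = False) -> list[Tensor]:
        """Run the network; returns per-scale class probability maps,
        highest resolution (the main output) first.

        In ``train_mode`` with the memory bank enabled, one fused entry
        (batch mean, detached) is pushed into the bank.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (N, {self.cfg.in_channels}, H, W), got {x.shape}")
        skips = self.backbone.encode(x)
        h = skips[-1]
        if self.cfg.use_mb:
            h = self.bank_fusion(h, self.bank, train_mode=train_mode)
        probs: list[Tensor] = []
        for d, i in enumerate(range(self.cfg.n_stages - 2, -1, -1)):
            h = self.backbone.up[d](h)
            h = concat([h, skips[i]], axis=1)
            for b in self.backbone.dec[d]:
                h = b(h)
            if not np.isfinite(h.data).all():
                raise FloatingPointError(f"non-finite activations at decoder step {d}")
            logits = self.backbone.heads[d](h)
            probs.append(logits.softmax(axis=1))
            if self.cfg.use_cm and d < self.cfg.n_cm_modules and i != 0:
                h = self.cm_blocks[d](h, logits)
        return probs[::-1]

    __call__ = forward
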